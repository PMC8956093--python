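"""Leave-one-subject-out evaluation, metrics, and timing sensitivity.

Per-class precision, recall and F1 follow the standard confusion-matrix
definitions; metrics with an empty denominator are reported as absent
(``None``), never as zero. The cross-validation protocol holds one
participant out per fold, repeats random under-sampling of the no-slip
class 10 times within each fold, tunes the SVM regularisation constant on
an 80:20 train/validation split, and never lets the held-out participant
influence normalisation, selection or tuning. Reported scores are averaged
over repeats within a fold and then over folds.

Because the printed "average" row of a per-class table can be computed two
ways — the arithmetic mean of the three per-class F1s, or the harmonic mean
of the averaged precision and recall — the report exposes both variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classify import (
    HEEL_CLASSES,
    TOE_CLASSES,
    TrainedSlipModel,
    fit_taxonomy_classifier,
    undersample,
)
from .config import DEFAULT_CONFIG, PipelineConfig
from .features import (
    HEEL_CLASSIFIER_FEATURES,
    TOE_CLASSIFIER_FEATURES,
    compute_features_from_events,
    features_to_frame,
)


def metrics(tp: int, fp: int, fn: int) -> dict:
    """Precision, recall and F1 from confusion counts.

    Undefined metrics (zero denominator) are returned as ``None``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Confusion counts and metrics per fold x repeat x taxonomy x class."""

    rows: pd.DataFrame
    skipped_folds: list[str] = field(default_factory=list)
    best_c: pd.DataFrame | None = None

    def class_summary(self, taxonomy: str) -> pd.DataFrame:
        """Per-class scores averaged over repeats then folds, plus an
        Average row (arithmetic mean of the per-class values) and the
        alternative harmonic-mean-of-averages F1."""
        sub = self.rows[self.rows.taxonomy == taxonomy]
        per_fold = (
            sub.groupby(["class", "fold"])[["precision", "recall", "f1"]]
            .mean()
            .groupby("class")
            .mean()
        )
        classes = [c for c in (TOE_CLASSES if taxonomy == "toe" else HEEL_CLASSES)
                   if c in per_fold.index]
        per_fold = per_fold.loc[classes]
        avg = per_fold.mean()
        out = per_fold.copy()
        out.loc["Average"] = avg
        out.loc["Average (harmonic F1)"] = [
            avg.precision, avg.recall, f1_from_pr(avg.precision, avg.recall)
        ]
        return out

    def overall_summary(self) -> dict:
        """Binary slip-detection precision/recall/F1 (averaged over repeats
        then folds)."""
        sub = self.rows[self.rows.taxonomy == "overall"]
        per_fold = sub.groupby("fold")[["precision", "recall", "f1"]].mean()
        return per_fold.mean().to_dict()


def _confusion_rows(y_true, y_pred, classes, fold, repeat, taxonomy):
    rows = []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        m = metrics(tp, fp, fn)
        rows.append(
            {"fold": fold, "repeat": repeat, "taxonomy": taxonomy, "class": c,
             "tp": tp, "fp": fp, "fn": fn, **m}
        )
    return rows


def _stratified_split(df, label_col, val_fraction, rng_seed):
    """80:20 split stratified by class x participant, falling back to class
    only where strata are too small for a stratified split."""
    key = df[label_col].astype(str) + "|" + df["participant"].astype(str)
    counts = key.value_counts()
    small = counts[counts < 2].index
    key = key.where(~key.isin(small), df[label_col].astype(str))
    counts = key.value_counts()
    if (counts < 2).any():
        key = df[label_col].astype(str)
    train_idx, val_idx = train_test_split(
        df.index, test_size=val_fraction, stratify=key, random_state=rng_seed % (2**31)
    )
    return df.loc[train_idx], df.loc[val_idx]


def losocv(
    dataset: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-subject-out cross-validation of both slip classifiers.

    ``dataset`` needs columns ``participant``, ``f1``..``f36``,
    ``toe_class`` and ``heel_class``. One fold per participant; within each
    fold the no-slip class is under-sampled ``undersample_repeats`` times
    and C is tuned on a stratified 80:20 split. The held-out participant's
    steps (full, imbalanced) are scored per repeat; the report also carries
    the overall binary slip decision (the inclusive-or of both taxonomies).
    """
    cc = config.classifier
    participants = sorted(dataset["participant"].unique())
    if len(participants) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 participants")
    taxonomies = {
        "toe": (TOE_CLASSES, "NTS", TOE_CLASSIFIER_FEATURES, "toe_class"),
        "heel": (HEEL_CLASSES, "NHS", HEEL_CLASSIFIER_FEATURES, "heel_class"),
    }
    all_rows: list[dict] = []
    best_c_rows: list[dict] = []
    skipped: list[str] = []
    for fold_idx, part in enumerate(participants):
        test = dataset[dataset.participant == part]
        train_all = dataset[dataset.participant != part]
        if len(test) == 0:
            skipped.append(str(part))
            continue
        fold_seed = seed + 1000 * fold_idx
        true_slip = (test["toe_class"] != "NTS") | (test["heel_class"] != "NHS")
        for r in range(cc.undersample_repeats):
            pred_slip = np.zeros(len(test), dtype=bool)
            for tax, (classes, no_slip, feats, col) in taxonomies.items():
                cols = [f"f{i}" for i in feats]
                labels = train_all[col].to_numpy()
                idx = undersample(labels, no_slip, fold_seed, r)
                sub = train_all.iloc[idx]
                tr, va = _stratified_split(
                    sub, col, cc.validation_fraction, fold_seed + r
                )
                model, norm, best_c = fit_taxonomy_classifier(
                    tr[cols].to_numpy(float), tr[col].to_numpy(),
                    va[cols].to_numpy(float), va[col].to_numpy(),
                    classes, no_slip, cc, seed=fold_seed + r,
                )
                y_pred = model.predict(norm.apply(test[cols].to_numpy(float)))
                y_true = test[col].to_numpy()
                all_rows.extend(
                    _confusion_rows(y_true, y_pred, classes, part, r, tax)
                )
                pred_slip |= y_pred != no_slip
                best_c_rows.append(
                    {"fold": part, "repeat": r, "taxonomy": tax, "C": best_c}
                )
            tp = int(np.sum(pred_slip & true_slip))
            fp = int(np.sum(pred_slip & ~true_slip))
            fn = int(np.sum(~pred_slip & true_slip))
            all_rows.append(
                {"fold": part, "repeat": r, "taxonomy": "overall", "class": "slip",
                 "tp": tp, "fp": fp, "fn": fn, **metrics(tp, fp, fn)}
            )
    return EvalReport(
        rows=pd.DataFrame(all_rows), skipped_folds=skipped,
        best_c=pd.DataFrame(best_c_rows),
    )


def sensitivity_analysis(
    model: TrainedSlipModel,
    steps: list[tuple],
    offsets: range = range(-15, 16),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Effect of event-timing errors on classifier performance.

    ``steps`` is a list of ``(stride, label, next_T_heel_off)`` with ground
    truth labels. Toe-off and heel-contact timings are shifted independently
    by each offset, features are re-extracted from the shifted events, and
    the macro-F1 of each classifier is recomputed; ``delta_*`` columns give
    the change relative to offset 0. Steps whose shifted event violates the
    within-stride ordering are excluded for that offset and counted.
    """
    out_rows = []
    for event in ("toe_off", "heel_contact"):
        baseline: dict[str, float] = {}
        for off in sorted(offsets, key=abs):
            fvs, labels = [], []
            excluded = 0
            for stride, label, next_tho in steps:
                to = stride.toe_off + (off if event == "toe_off" else 0)
                hc = stride.heel_contact + (off if event == "heel_contact" else 0)
                if not stride.start < to < hc < min(stride.end, stride.kin_full.n_frames - 1):
                    excluded += 1
                    continue
                fvs.append(
                    compute_features_from_events(
                        stride.kin_full, stride.start, stride.end, to, hc,
                        next_tho, config, stride.stride_id,
                    )
                )
                labels.append(label)
            frame = features_to_frame(fvs)
            pred = model.predict_frame(frame)
            toe_true = np.asarray([l.toe_class for l in labels])
            heel_true = np.asarray([l.heel_class for l in labels])
            f1s = {}
            for tax, classes, y_true, y_pred in (
                ("toe", TOE_CLASSES, toe_true, pred["toe_class"].to_numpy()),
                ("heel", HEEL_CLASSES, heel_true, pred["heel_class"].to_numpy()),
            ):
                vals = [
                    m["f1"]
                    for c in classes
                    for m in [metrics(
                        int(np.sum((y_pred == c) & (y_true == c))),
                        int(np.sum((y_pred == c) & (y_true != c))),
                        int(np.sum((y_pred != c) & (y_true == c))),
                    )]
                    if m["f1"] is not None
                ]
                f1s[tax] = float(np.mean(vals)) if vals else float("nan")
            if off == 0:
                baseline = dict(f1s)
            out_rows.append(
                {"event": event, "offset": off,
                 "toe_f1": f1s["toe"], "heel_f1": f1s["heel"],
                 "n_excluded": excluded}
            )
        for row in out_rows:
            if row["event"] == event and "delta_toe_f1" not in row:
                row["delta_toe_f1"] = row["toe_f1"] - baseline["toe"]
                row["delta_heel_f1"] = row["heel_f1"] - baseline["heel"]
    return pd.DataFrame(out_rows).sort_values(["event", "offset"]).reset_index(drop=True)
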