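"""The 36-feature inventory, anchors, curvature, and feature selection."""

import numpy as np
import pandas as pd
import pytest
import sympy
from scipy import integrate, stats

from icegait.config import PipelineConfig
from icegait.events import StrideSegment
from icegait.features import (
    HEEL_CLASSIFIER_FEATURES,
    TOE_CLASSIFIER_FEATURES,
    compute_features_from_events,
    curvature,
    find_anchors,
    histogram_overlap_selection,
    peak_inventory,
)

from conftest import make_kinematics, step_with_features

FS = 150.0


class TestCurvature:
    def test_linear_velocity_has_zero_curvature(self):
        v = 0.3 * np.arange(100) + 2.0
        assert all(curvature(v, t) == pytest.approx(0.0, abs=1e-12) for t in range(1, 99))

    def test_quadratic_vertex_equals_second_derivative(self):
        t0 = 50
        v = 0.01 * (np.arange(100) - t0) ** 2
        assert curvature(v, t0) == pytest.approx(0.02)

    def test_matches_symbolic_oracle_on_smooth_signal(self):
        """kappa computed from the sampled polynomial agrees to 1e-6 with a
        symbolic evaluation of the same curvature definition (per-frame
        central differences), and approximates the continuous curvature of
        the generating polynomial."""
        x = sympy.Symbol("x")
        expr = sympy.Rational(1, 1000) * x**3 - sympy.Rational(3, 100) * x**2 + x
        # symbolic oracle of the per-frame-difference definition, exact
        d1s = (expr.subs(x, x + 1) - expr.subs(x, x - 1)) / 2
        d2s = expr.subs(x, x + 1) - 2 * expr + expr.subs(x, x - 1)
        kappa_discrete = d2s / (1 + d1s**2) ** sympy.Rational(3, 2)
        # continuous curvature of the same polynomial
        d1, d2 = sympy.diff(expr, x), sympy.diff(expr, x, 2)
        kappa_cont = d2 / (1 + d1**2) ** sympy.Rational(3, 2)
        v = np.array([float(expr.subs(x, i)) for i in range(60)])
        for t in [1, 10, 25, 40, 58]:
            assert curvature(v, t) == pytest.approx(
                float(kappa_discrete.subs(x, t)), abs=1e-6
            )
            assert curvature(v, t) == pytest.approx(
                float(kappa_cont.subs(x, t)), abs=1e-4
            )

    def test_boundary_frame_rejected(self):
        v = np.arange(10.0)
        with pytest.raises(IndexError):
            curvature(v, 0)
        with pytest.raises(IndexError):
            curvature(v, 9)


class TestPeakInventory:
    def test_half_sine_lobe_area(self):
        """Single positive half-sine, amplitude A duration D: one peak with
        area 2AD/pi (analytic integral), trapezoidal within 2%."""
        A, D = 0.8, 0.4
        n = int(D * FS)
        t = np.arange(600) / FS
        sig = np.zeros(600)
        sig[100 : 100 + n] = A * np.sin(np.pi * np.arange(n) / n)
        inv = peak_inventory(sig, FS, 0.0, (0, 599), "positive")
        assert inv.count == 1
        assert inv.areas[0] == pytest.approx(2 * A * D / np.pi, rel=0.02)
        assert inv.widths_s[0] == pytest.approx(D, abs=2 / FS)

    def test_monotone_signal_has_no_peaks(self):
        sig = np.linspace(0, 1, 400)
        assert peak_inventory(sig, FS, 0.0, (0, 399), "positive").count == 0
        assert peak_inventory(sig, FS, 0.0, (0, 399), "negative").count == 0

    def test_min_separation_keeps_larger_peak(self):
        """Two peaks 5 ms apart under a 7 ms separation keep only the
        larger (sampled at 1 kHz so 5 ms is resolvable; at 150 Hz a 7 ms
        separation admits every local extremum)."""
        fs = 1000.0
        sig = np.zeros(100)
        sig[48:53] = [0.5, 1.0, 0.5, 0.2, 0.5]
        sig[53:58] = [0.9, 0.5, 0.2, 0.1, 0.0]
        inv = peak_inventory(sig, fs, 7.0, (0, 99), "positive", min_prominence=0.0)
        assert inv.count == 1
        assert inv.frames[0] == 49
        # at 150 Hz the same rule keeps all local extrema (7 ms ~ 1 frame)
        inv150 = peak_inventory(sig, FS, 7.0, (0, 99), "positive", min_prominence=0.0)
        assert inv150.count == 2

    def test_negative_polarity_mirrors_positive(self):
        rng = np.random.default_rng(3)
        sig = np.convolve(rng.normal(0, 1, 500), np.ones(25) / 25, mode="same")
        pos = peak_inventory(sig, FS, 0.0, (0, 499), "positive")
        neg = peak_inventory(-sig, FS, 0.0, (0, 499), "negative")
        np.testing.assert_array_equal(pos.frames, neg.frames)
        np.testing.assert_allclose(pos.areas, -neg.areas, atol=1e-12)
        np.testing.assert_allclose(pos.heights, -neg.heights, atol=1e-12)


class TestAnchors:
    def test_monotone_velocity_maxes_at_last_frame(self):
        n = 600
        kin = make_kinematics(
            n=n,
            heel_ap_vel=np.linspace(0, 2, n),
            heel_acc=np.full(n, 2.0),
            heel_vert_vel=np.zeros(n),
        )
        stride = StrideSegment(kin_full=kin, start=10, end=500, toe_off=200, heel_contact=400)
        anchors = find_anchors(stride)
        assert anchors["T_max_velocity"] == 500

    def test_velocity_never_slow_means_no_heel_off_anchor(self):
        n = 600
        kin = make_kinematics(
            n=n, heel_ap_vel=np.full(n, 1.5), heel_acc=np.full(n, 2.0)
        )
        stride = StrideSegment(kin_full=kin, start=10, end=500, toe_off=200, heel_contact=400)
        assert find_anchors(stride)["T_heel_off"] is None

    def test_heel_off_is_last_slow_frame_before_acceleration(self):
        """The anchor sits where the heel is still slow but already
        accelerating, at the onset of the swing lobe."""
        stride, fv, truth = step_with_features("normal", 0.0)
        t_ho = fv.anchors["T_heel_off"]
        t_mv = fv.anchors["T_max_velocity"]
        assert t_ho is not None and stride.start < t_ho < stride.toe_off
        assert t_ho < t_mv
        v = stride.kin_full.heel_ap_vel
        assert abs(v[t_ho]) < 0.1
        assert v[t_ho + 5] > v[t_ho]  # accelerating out of stance


class TestFeatureVector:
    def test_normal_step_signature(self):
        _, fv, _ = step_with_features("normal", 0.0)
        assert fv.values[11] == 0  # no AP-velocity peaks after contact
        assert fv.values[17] == 1  # full stop after contact
        assert fv.values[26] == 0

    def test_forward_heel_slip_lobe_area(self):
        _, fv, truth = step_with_features("FHS", 0.05)
        assert fv.values[11] >= 1
        assert fv.values[13] == pytest.approx(0.05, rel=0.02)
        assert fv.values[17] == 0

    def test_backward_toe_slip_signature(self):
        _, fv, _ = step_with_features("BTS", 0.03)
        assert fv.values[26] >= 1
        assert fv.values[29] > 0
        assert fv.values[28] < 0

    def test_all_36_present_with_typed_values(self):
        _, fv, _ = step_with_features("BHS", 0.04, noise_sd=0.0005)
        assert set(fv.values) == set(range(1, 37))
        for fid in (1, 2, 3, 11, 18, 19, 20, 21, 26, 30):
            assert fv.values[fid] == int(fv.values[fid]) and fv.values[fid] >= 0
        assert fv.values[17] in (0.0, 1.0)

    def test_time_translation_invariance(self):
        """Padding the trial front with quiet frames and shifting all event
        indices leaves every feature unchanged."""
        stride, fv, _ = step_with_features("FHS", 0.04)
        kin = stride.kin_full
        pad = 50

        def shift(arr):
            lead = np.repeat(arr[:1], pad, axis=0)
            return np.concatenate([lead, arr], axis=0)

        from icegait.preprocess import FootKinematics

        kin2 = FootKinematics(
            heel_pos=shift(kin.heel_pos), toe_pos=shift(kin.toe_pos),
            heel_vel=shift(kin.heel_vel), toe_vel=shift(kin.toe_vel),
            heel_acc=shift(kin.heel_acc),
            foot_angle=shift(kin.foot_angle),
            foot_angular_vel=shift(kin.foot_angular_vel),
            sample_rate=kin.sample_rate,
        )
        fv2 = compute_features_from_events(
            kin2, stride.start + pad, stride.end + pad,
            stride.toe_off + pad, stride.heel_contact + pad,
        )
        fv1 = compute_features_from_events(
            kin, stride.start, stride.end, stride.toe_off, stride.heel_contact
        )
        for fid in range(1, 37):
            assert fv2.values[fid] == pytest.approx(fv1.values[fid], abs=1e-9), fid

    def test_ap_sign_flip_maps_backward_onto_forward_toe_features(self):
        """Negating the toe AP velocity turns the backward-slip peak
        features (26, 28) into the forward-slip ones (21, 23)."""
        stride, fv, _ = step_with_features("BTS", 0.04)
        kin = stride.kin_full
        from icegait.preprocess import FootKinematics

        toe_vel = kin.toe_vel.copy()
        toe_vel[:, 0] *= -1
        kin2 = FootKinematics(
            heel_pos=kin.heel_pos, toe_pos=kin.toe_pos,
            heel_vel=kin.heel_vel, toe_vel=toe_vel, heel_acc=kin.heel_acc,
            foot_angle=kin.foot_angle, foot_angular_vel=kin.foot_angular_vel,
            sample_rate=kin.sample_rate,
        )
        flipped = compute_features_from_events(
            kin2, stride.start, stride.end, stride.toe_off, stride.heel_contact
        )
        assert flipped.values[21] == fv.values[26]
        assert flipped.values[23] == pytest.approx(-fv.values[28])
        assert flipped.values[26] == fv.values[21]

    def test_event_ordering_validated(self):
        stride, _, _ = step_with_features("normal", 0.0)
        with pytest.raises(ValueError):
            compute_features_from_events(
                stride.kin_full, stride.start, stride.end,
                stride.heel_contact, stride.toe_off,
            )


class TestFeatureSelection:
    @staticmethod
    def frame(values_by_class):
        rows, labels = [], []
        for cls, vals in values_by_class.items():
            for v in vals:
                rows.append({f"f{i}": v if i == 1 else 0.0 for i in range(1, 37)})
                labels.append(cls)
        return pd.DataFrame(rows), np.asarray(labels)

    def test_identical_distributions_discarded(self):
        vals = list(np.linspace(0, 1, 200))
        df, labels = self.frame({"A": vals, "B": vals})
        rep = histogram_overlap_selection(df, labels, bins=50)
        row = rep.table[rep.table.feature_id == 1]
        assert row.overlap.iloc[0] == pytest.approx(1.0)
        assert not rep.kept[1]

    def test_disjoint_supports_kept(self):
        df, labels = self.frame(
            {"A": list(np.linspace(0, 1, 100)), "B": list(np.linspace(5, 6, 100))}
        )
        rep = histogram_overlap_selection(df, labels, bins=50)
        assert rep.table[rep.table.feature_id == 1].overlap.iloc[0] == 0.0
        assert rep.kept[1]

    def test_gaussian_overlap_matches_quadrature_oracle(self):
        """Two known Gaussians: the histogram overlap approximates
        integral of min(pdf1, pdf2), within binning error."""
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 4000)
        b = rng.normal(1.5, 1.0, 4000)
        df, labels = self.frame({"A": list(a), "B": list(b)})
        rep = histogram_overlap_selection(df, labels, bins=50)
        got = rep.table[rep.table.feature_id == 1].overlap.iloc[0]
        expected, _ = integrate.quad(
            lambda x: min(stats.norm.pdf(x, 0, 1), stats.norm.pdf(x, 1.5, 1)),
            -8, 10,
        )
        assert got == pytest.approx(expected, abs=0.05)

    def test_small_class_pairs_skipped_and_reported(self):
        df, labels = self.frame({"A": list(np.arange(50.0)), "B": [1.0]})
        rep = histogram_overlap_selection(df, labels, bins=10)
        assert ("A", "B") in rep.skipped_pairs

    def test_signature_features_survive_selection_on_separated_classes(self, small_dataset):
        """The selected features that carry the generator's class signatures
        (pre-toe-off AP peaks for the toe classifier, post-contact AP lobes
        for the heel classifier) must not be discarded by the overlap rule.
        Selected features tied to signals the generator keeps class-neutral
        (e.g. toe vertical velocity) legitimately fail selection here."""
        table, _ = small_dataset
        must_survive = {
            "toe_class": (20, 21, 22, 23, 26, 27, 28, 29),
            "heel_class": (5, 7, 8, 11, 12, 13, 16, 17),
        }
        for ids, col in (
            (TOE_CLASSIFIER_FEATURES, "toe_class"),
            (HEEL_CLASSIFIER_FEATURES, "heel_class"),
        ):
            rep = histogram_overlap_selection(
                table, table[col].to_numpy(), bins=50, feature_ids=ids
            )
            dropped = [i for i in must_survive[col] if not rep.kept[i]]
            assert dropped == []

    def test_degenerate_inputs_rejected(self):
        df, labels = self.frame({"A": [1.0, 2.0]})
        with pytest.raises(ValueError):
            histogram_overlap_selection(df, labels)
        df2, labels2 = self.frame({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        with pytest.raises(ValueError):
            histogram_overlap_selection(df2, labels2, bins=1)
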