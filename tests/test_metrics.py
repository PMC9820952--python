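import numpy as np
import pytest
from scipy.spatial.distance import cdist

from masseg.metrics import (AhdResult, DscBreakdown, ahd, ahd_breakdown, dsc,
                            dsc_breakdown, evaluate_cases, revision_fraction,
                            two_class_dsc_mean)
from masseg.volume_io import LabelMap


def brute_dsc(a, m):
    """Independent oracle: explicit set arithmetic on voxel index sets."""
    sa = {tuple(v) for v in np.argwhere(a)}
    sm = {tuple(v) for v in np.argwhere(m)}
    if not sa and not sm:
        return 1.0
    return 2 * len(sa & sm) / (len(sa) + len(sm))


def brute_ahd_directed(a, m, spacing):
    """Independent oracle: all-pairs Euclidean distances."""
    pa = np.argwhere(a) * np.asarray(spacing)
    pm = np.argwhere(m) * np.asarray(spacing)
    return float(cdist(pa, pm).min(axis=1).mean())


def _mask(rng, shape=(6, 6, 6), p=0.3):
    return rng.random(shape) < p


class TestDsc:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dsc(a, a) == 1.0
        assert dsc(a, ~a) == 0.0

    def test_half_overlap(self):
        a = np.zeros((8,), bool)
        m = np.zeros((8,), bool)
        a[:4] = True          # |A| = 4
        m[2:6] = True         # |M| = 4, |A∩M| = 2
        assert dsc(a, m) == 0.5

    def test_empty_conventions(self):
        empty = np.zeros((3, 3, 3), bool)
        full = ~empty
        assert dsc(empty, empty) == 1.0
        assert dsc(empty, full) == 0.0
        assert dsc(full, empty) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, m = _mask(rng), _mask(rng)
            assert dsc(a, m) == dsc(m, a)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, m = _mask(rng), _mask(rng)
            assert dsc(a, m) == pytest.approx(brute_dsc(a, m), rel=1e-12)


class TestDscBreakdown:
    def test_equal_maps_all_ones(self):
        rng = np.random.default_rng(2)
        lab = LabelMap(rng.integers(0, 3, (6, 6, 6)), (1, 1, 1))
        b = dsc_breakdown(lab, lab)
        assert (b.dsc_background, b.dsc_left, b.dsc_right, b.dsc_mean) == (1, 1, 1, 1)

    def test_three_class_mean_reproduces_published_aggregate(self):
        # per-class values printed for CBCT auto vs CT manual: their
        # unweighted mean reproduces the published "Mean" column, 94.15%
        b = DscBreakdown(dsc_background=99.96, dsc_left=91.56, dsc_right=90.94)
        assert round(b.dsc_mean, 2) == 94.15

    def test_two_class_degenerate_case(self):
        rng = np.random.default_rng(3)
        auto = rng.random((6, 6, 6)) < 0.4
        manual = rng.random((6, 6, 6)) < 0.4
        expected = 0.5 * (dsc(auto, manual) + dsc(~auto, ~manual))
        assert two_class_dsc_mean(auto, manual) == pytest.approx(expected)

    def test_misaligned_grids_rejected(self):
        a = LabelMap(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        b = LabelMap(np.zeros((5, 5, 5), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            dsc_breakdown(a, b)


class TestAhd:
    def test_identical_sets_zero(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3, 1:3, 1:3] = True
        r = ahd(a, a)
        assert (r.directed_a_to_m, r.directed_m_to_a, r.symmetric) == (0, 0, 0)

    def test_single_pair_distance(self):
        a = np.zeros((5, 5, 5), bool)
        m = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        m[0, 0, 3] = True
        r = ahd(a, m, spacing=(1, 1, 1))
        assert r.directed_a_to_m == pytest.approx(3.0)
        assert r.directed_m_to_a == pytest.approx(3.0)
        assert r.symmetric == pytest.approx(3.0)

    def test_asymmetric_two_point_case(self):
        a = np.zeros((5, 5, 5), bool)
        m = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = a[0, 0, 2] = True
        m[0, 0, 0] = True
        r = ahd(a, m, spacing=(1, 1, 1))
        assert r.directed_a_to_m == pytest.approx(1.0)
        assert r.directed_m_to_a == pytest.approx(0.0)
        assert r.symmetric == pytest.approx(0.5)

    def test_scales_linearly_with_spacing(self):
        rng = np.random.default_rng(4)
        a, m = _mask(rng, p=0.2), _mask(rng, p=0.2)
        r1 = ahd(a, m, spacing=(1, 1, 1))
        r2 = ahd(a, m, spacing=(2, 2, 2))
        assert r2.symmetric == pytest.approx(2 * r1.symmetric, rel=1e-9)
        assert r2.directed_a_to_m == pytest.approx(2 * r1.directed_a_to_m, rel=1e-9)

    def test_empty_set_rejected(self):
        a = np.zeros((3, 3, 3), bool)
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="empty"):
            ahd(a, m)

    def test_matches_brute_force_with_anisotropic_spacing(self):
        rng = np.random.default_rng(5)
        spacing = (0.4, 0.4, 1.0)
        for _ in range(50):
            a, m = _mask(rng, p=0.25), _mask(rng, p=0.25)
            if not a.any() or not m.any():
                continue
            r = ahd(a, m, spacing)
            assert r.directed_a_to_m == pytest.approx(
                brute_ahd_directed(a, m, spacing), rel=1e-9)
            assert r.directed_m_to_a == pytest.approx(
                brute_ahd_directed(m, a, spacing), rel=1e-9)


class TestRevisionFraction:
    def _lab(self, arr):
        return LabelMap(arr.astype(np.uint8), (1, 1, 1))

    def test_identical_maps_zero(self):
        rng = np.random.default_rng(6)
        lab = self._lab(rng.integers(0, 3, (6, 6, 6)))
        assert revision_fraction(lab, lab).mean_pct == 0.0

    def test_single_changed_voxel(self):
        rev = np.zeros((10, 10, 10))
        rev[:2, :10, :10] = 1  # 200-voxel structure
        orig = rev.copy()
        orig[0, 0, 0] = 0      # one voxel differs
        r = revision_fraction(self._lab(orig), self._lab(rev))
        assert r.left_pct == pytest.approx(0.5)

    def test_empty_original_full_revised(self):
        rev = np.zeros((6, 6, 6))
        rev[2:4, 2:4, 2:4] = 1
        r = revision_fraction(self._lab(np.zeros((6, 6, 6))), self._lab(rev))
        assert r.left_pct == 100.0

    def test_empty_revised_uses_original_denominator(self):
        orig = np.zeros((6, 6, 6))
        orig[2:4, 2:4, 2:4] = 2
        r = revision_fraction(self._lab(orig), self._lab(np.zeros((6, 6, 6))))
        assert r.right_pct == 100.0
        assert r.empty_revised_warning


class TestEvaluateCases:
    def _case(self, rng):
        lab = np.zeros((12, 12, 12), np.uint8)
        lab[2:6, 4:8, 4:8] = 1
        lab[8:11, 4:8, 4:8] = 2
        noisy = lab.copy()
        noisy[5, 4, 4] = 0
        return (LabelMap(noisy, (1, 1, 1)), LabelMap(lab, (1, 1, 1)))

    def test_side_mean_aggregation_identity(self):
        # aggregate side-mean equals (mean left + mean right)/2; applied to
        # the published per-side means (3.22, 4.14) mm this gives 3.68 mm
        assert round((3.22 + 4.14) / 2, 2) == 3.68
        rng = np.random.default_rng(7)
        preds, truths = {}, {}
        for i in range(4):
            p, t = self._case(rng)
            preds[f"c{i}"], truths[f"c{i}"] = p, t
        rep = evaluate_cases(preds, truths)
        agg = rep.aggregate
        assert agg["ahd_mean"]["mean"] == pytest.approx(
            0.5 * (agg["ahd_left"]["mean"] + agg["ahd_right"]["mean"]), rel=1e-12)
        pc = rep.per_case
        np.testing.assert_allclose(
            pc["ahd_mean"], 0.5 * (pc["ahd_left"] + pc["ahd_right"]))

    def test_single_case_flags_undefined_sd(self):
        rng = np.random.default_rng(8)
        p, t = self._case(rng)
        rep = evaluate_cases({"a": p}, {"a": t})
        assert rep.aggregate["dsc_mean"]["sd"] is None
        assert rep.aggregate["dsc_mean"].get("sd_undefined")

    def test_identical_cases_have_zero_sd_and_ci_width(self):
        rng = np.random.default_rng(9)
        p, t = self._case(rng)
        preds = {f"c{i}": p for i in range(3)}
        truths = {f"c{i}": t for i in range(3)}
        agg = evaluate_cases(preds, truths).aggregate
        assert agg["dsc_left"]["sd"] == pytest.approx(0.0)
        assert agg["dsc_left"]["ci_hi"] == pytest.approx(agg["dsc_left"]["ci_lo"])

    def test_unmatched_ids_rejected(self):
        rng = np.random.default_rng(10)
        p, t = self._case(rng)
        with pytest.raises(ValueError, match="unmatched"):
            evaluate_cases({"a": p}, {"b": t})
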