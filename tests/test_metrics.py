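"""Evaluation measures against brute-force set-counting and all-pairs
distance oracles, plus the closed-form identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import cdist, directed_hausdorff as scipy_dhd

from sdsseg import metrics as M


def brute_boundary(mask):
    """Independent 6-neighbourhood boundary extraction by explicit loop."""
    mask = np.asarray(mask, dtype=bool)
    pts = []
    for idx in np.argwhere(mask):
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= mask.shape).any() or not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.array(pts, dtype=np.int64).reshape(-1, mask.ndim)


def brute_directed(a, b):
    return cdist(a, b).min(axis=1).max()


def brute_surface_dists(pred, ref, spacing):
    bp = brute_boundary(pred) * np.asarray(spacing)
    br = brute_boundary(ref) * np.asarray(spacing)
    d = cdist(br, bp)
    return d.min(axis=1), d.min(axis=0)  # ref->pred, pred->ref


class TestOverlapMeasures:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 2), dtype=bool)
        m[1:3, 1:3, :] = True
        assert M.dice(m, m) == 1.0
        assert M.sensitivity(m, m) == 1.0
        assert M.specificity(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[3, 3] = True
        assert M.dice(a, b) == 0.0
        assert M.sensitivity(a, b) == 0.0
        assert M.specificity(a, b) == 0.0

    def test_counting_hand_cases(self):
        pred = np.zeros(10, dtype=bool)
        ref = np.zeros(10, dtype=bool)
        pred[:4] = True
        ref[2:6] = True      # |pred|=4, |ref|=4, overlap 2
        assert M.dice(pred, ref) == 0.5
        ref2 = np.zeros(20, dtype=bool)
        pred2 = np.zeros(20, dtype=bool)
        ref2[:10] = True
        pred2[7:13] = True   # overlap 3 of |ref|=10
        assert M.sensitivity(pred2, ref2) == 0.3
        pred3 = np.zeros(20, dtype=bool)
        ref3 = np.zeros(20, dtype=bool)
        pred3[:8] = True
        ref3[6:10] = True    # overlap 2 of |pred|=8
        assert M.specificity(pred3, ref3) == 0.25

    def test_empty_conventions(self):
        e = np.zeros((3, 3), dtype=bool)
        f = np.ones((3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            assert M.dice(e, e) == 1.0
        with pytest.warns(UserWarning):
            assert np.isnan(M.sensitivity(f, e))
        with pytest.warns(UserWarning):
            assert np.isnan(M.specificity(e, f))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            M.dice(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_sensitivity_specificity_duality_and_tnr(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((6, 6)) < 0.4, rng.random((6, 6)) < 0.4
        assert M.sensitivity(a, b) == M.specificity(b, a)
        tnr = M.true_negative_rate(a, b)
        assert 0.0 <= tnr <= 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(pred=arrays(bool, (4, 4, 3)), ref=arrays(bool, (4, 4, 3)))
def test_overlap_measures_match_counting_for_any_masks(pred, ref):
    inter = int((pred & ref).sum())
    np_, nr = int(pred.sum()), int(ref.sum())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = M.dice(pred, ref)
        s = M.sensitivity(pred, ref)
        p = M.specificity(pred, ref)
    assert d == (1.0 if np_ + nr == 0 else 2 * inter / (np_ + nr))
    assert (np.isnan(s) if nr == 0 else s == inter / nr)
    assert (np.isnan(p) if np_ == 0 else p == inter / np_)
    assert d == M.dice(ref, pred)  # symmetry


class TestHausdorff:
    def test_single_pair_345(self):
        assert M.directed_hausdorff([(0, 0)], [(3, 4)]) == 5.0

    def test_identity_is_zero(self):
        pts = [(0, 0), (2, 5), (7, 1)]
        assert M.directed_hausdorff(pts, pts) == 0.0

    def test_asymmetry_example(self):
        A, B = [(0, 0), (10, 0)], [(0, 0)]
        assert M.directed_hausdorff(A, B) == 10.0
        assert M.directed_hausdorff(B, A) == 0.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            M.directed_hausdorff(np.empty((0, 2)), [(0, 0)])

    def test_symmetric_hd_and_hd95_on_two_point_masks(self):
        a = np.zeros((11, 3), dtype=bool)
        b = np.zeros((11, 3), dtype=bool)
        a[0, 0] = a[10, 0] = True
        b[0, 0] = True
        assert M.hausdorff(a, b) == 10.0
        assert M.hausdorff(b, a) == 10.0  # symmetric by construction
        # directed distances {0, 10}: 95th percentile by linear interpolation
        assert M.hausdorff95(a, b) == pytest.approx(9.5)

    def test_identical_masks_zero_distance(self):
        m = np.zeros((5, 5, 3), dtype=bool)
        m[1:4, 1:4, 1] = True
        assert M.hausdorff(m, m) == 0.0
        assert M.hausdorff95(m, m) == 0.0

    def test_spacing_scales_distances_but_not_overlap(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 6, 4)) < 0.3, rng.random((6, 6, 4)) < 0.3
        hd1 = M.hausdorff(a, b, spacing=(1, 1, 1))
        hd2 = M.hausdorff(a, b, spacing=(2, 2, 2))
        assert hd2 == pytest.approx(2 * hd1)
        assert M.dice(a, b) == M.dice(a, b)
        h951 = M.hausdorff95(a, b, spacing=(1, 1, 1))
        h952 = M.hausdorff95(a, b, spacing=(2, 2, 2))
        assert h952 == pytest.approx(2 * h951)

    def test_hd95_never_exceeds_hd(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.random((6, 6, 3)) < 0.35, rng.random((6, 6, 3)) < 0.35
            if a.any() and b.any():
                assert M.hausdorff95(a, b) <= M.hausdorff(a, b) + 1e-12

    def test_matches_scipy_directed_hausdorff_on_point_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.integers(0, 12, size=(15, 3)).astype(float)
            b = rng.integers(0, 12, size=(9, 3)).astype(float)
            assert M.directed_hausdorff(a, b) == pytest.approx(
                scipy_dhd(a, b)[0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 10, size=(12, 2)).astype(float)
        b = rng.integers(0, 10, size=(7, 2)).astype(float)
        perm = rng.permutation(len(a))
        assert M.directed_hausdorff(a, b) == M.directed_hausdorff(a[perm], b)


class TestOracleEquivalence:
    def test_all_measures_match_brute_force_on_random_masks(self):
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(30):
            pred = rng.random((8, 8, 4)) < rng.uniform(0.1, 0.6)
            ref = rng.random((8, 8, 4)) < rng.uniform(0.1, 0.6)
            np_, nr = int(pred.sum()), int(ref.sum())
            inter = int((pred & ref).sum())
            if np_ + nr:
                assert M.dice(pred, ref) == 2 * inter / (np_ + nr)
            if nr:
                assert M.sensitivity(pred, ref) == inter / nr
            if np_:
                assert M.specificity(pred, ref) == inter / np_
            if np_ and nr:
                dr, dp = brute_surface_dists(pred, ref, (1, 1, 1))
                assert M.hausdorff(pred, ref) == max(dr.max(), dp.max())
                assert M.hausdorff95(pred, ref) == pytest.approx(
                    max(np.percentile(dr, 95), np.percentile(dp, 95)))
                checked += 1
        assert checked >= 20

    def test_boundary_extraction_matches_explicit_neighbour_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            m = rng.random((7, 6, 5)) < 0.4
            a = M.boundary_voxels(m)
            b = brute_boundary(m)
            assert {tuple(p) for p in a} == {tuple(p) for p in b}


class TestEvaluateVolume:
    def test_perfect_prediction(self):
        labels = np.zeros((4, 6, 6), dtype=np.int16)
        labels[1:3, 1:5, 1:5] = 2
        labels[1:3, 2:4, 2:4] = 1
        labels[1:3, 3, 3] = 4
        rep = M.evaluate_volume(labels, labels)
        for region in ("WT", "TC", "ET"):
            assert rep[region]["dice"] == 1.0
            assert rep[region]["hd"] == 0.0

    def test_missing_region_in_prediction(self):
        ref = np.zeros((3, 6, 6), dtype=np.int16)
        ref[1, 1:4, 1:4] = 2
        ref[1, 2, 2] = 4
        pred = ref.copy()
        pred[pred == 4] = 1      # prediction has no enhancing voxels
        rep = M.evaluate_volume(pred, ref)
        assert rep["ET"]["sensitivity"] == 0.0
        assert np.isnan(rep["ET"]["hd"])
        assert rep["WT"]["dice"] == 1.0

    def test_hand_built_pair_matches_counting_oracle(self):
        ref = np.zeros((2, 6, 6), dtype=np.int16)
        pred = np.zeros((2, 6, 6), dtype=np.int16)
        ref[0, 1:4, 1:4] = 2     # 9 edema
        ref[0, 2, 2] = 4         # 1 enhancing
        pred[0, 2:5, 2:5] = 2    # shifted edema
        pred[0, 3, 3] = 4
        rep = M.evaluate_volume(pred, ref)
        # WT: |ref|=9, |pred|=9, overlap 4 (label-2/4 union overlap region)
        assert rep["WT"]["dice"] == pytest.approx(2 * 4 / 18)
        assert rep["ET"]["dice"] == 0.0
        assert rep["ET"]["hd"] == pytest.approx(np.sqrt(2))
        frame = rep.to_frame()
        assert list(frame.columns) == ["dice", "sensitivity", "specificity",
                                       "hd", "hd95"]

    def test_cohort_aggregation_formats_mean_and_std(self):
        labels = np.zeros((3, 6, 6), dtype=np.int16)
        labels[1, 1:4, 1:4] = 2
        labels[1, 2, 2] = 4
        reps = [M.evaluate_volume(labels, labels) for _ in range(2)]
        agg = M.aggregate_reports(reps)
        assert agg.loc["WT", "dice"] == "1.0 ± 0.0"
        assert list(agg.index) == ["WT", "TC", "ET"]
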