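"""PET quantification and threshold detection: SUV metrics, backgrounds,
TBR, ROC/AUC, K-S threshold, DeLong, classification."""

import numpy as np
import pytest

import axskel.taxonomy as tax
from axskel.core import ImageVolume, LabelVolume, StructuringElement
from axskel.detection import (
    SuvMetrics,
    background_medians,
    classify_vois,
    delong_test,
    extract_suv_metrics,
    ks_optimal_threshold,
    measure_vois,
    roc_auc,
    sensitivity_specificity,
    tbr,
)
from axskel.errors import EmptyMaskError, InvalidArgumentError, UndefinedMetricError


def _pet(arr):
    return ImageVolume(np.asarray(arr, dtype=np.float32), (4.0,) * 3, modality="PET-SUV")


class TestSuvMetrics:
    def test_uniform_voi(self):
        pet = _pet(np.full((9, 9, 9), 5.0))
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        m = extract_suv_metrics(pet, mask)
        assert (m.suv_max, m.suv_peak, m.suv_mean) == (5.0, 5.0, 5.0)

    def test_hot_voxel_max_and_mean(self):
        arr = np.ones((11, 11, 11), dtype=np.float32)
        arr[5, 5, 5] = 10.0
        pet = _pet(arr)
        from axskel.voi import sphere_voi

        mask = sphere_voi((5, 5, 5), (11, 11, 11), 4.0, 10.0)  # 81 voxels
        m = extract_suv_metrics(pet, mask)
        assert m.suv_max == 10.0
        assert m.suv_mean == pytest.approx((10.0 + 80.0) / 81.0)

    def test_peak_matches_brute_force_neighbourhood_mean(self):
        rng = np.random.default_rng(5)
        fp = StructuringElement("sphere", 6.0).offsets(4.0)
        assert len(fp) == 19  # ~1 mL neighbourhood on the 4 mm grid
        for trial in range(20):
            arr = rng.gamma(2.0, 1.5, (10, 10, 10)).astype(np.float32)
            mask = rng.random((10, 10, 10)) < 0.25
            if not mask.any():
                mask[5, 5, 5] = True
            pet = _pet(arr)
            got = extract_suv_metrics(pet, mask).suv_peak
            best = -np.inf
            for c in np.argwhere(mask):
                pts = c + fp
                keep = ((pts >= 0) & (pts < 10)).all(axis=1)
                best = max(best, arr[tuple(pts[keep].T)].mean())
            assert got == pytest.approx(best, rel=1e-6)

    def test_empty_voi_rejected(self):
        with pytest.raises(EmptyMaskError):
            extract_suv_metrics(_pet(np.ones((4, 4, 4))), np.zeros((4, 4, 4), dtype=bool))


class TestBackgrounds:
    def test_uniform_pet_all_medians_equal(self, phantom_labels):
        pet = _pet(np.full(phantom_labels.shape, 2.5))
        bg = background_medians(pet, phantom_labels)
        for region in ("cervical", "thoracic", "lumbar", "spine", "femur", "liver", "aorta"):
            assert bg[region] == 2.5

    def test_femur_shell_removed_by_erosion(self):
        vox = np.zeros((12, 12, 12), dtype=np.int32)
        vox[2:10, 2:10, 2:10] = tax.STRUCTURE_IDS["femur_left"]
        lab = LabelVolume(vox, (4.0,) * 3)
        arr = np.zeros((12, 12, 12), dtype=np.float32)
        arr[2:10, 2:10, 2:10] = 1.0
        shell = (vox > 0) & ~np.pad((vox[3:9, 3:9, 3:9] > 0), 3)  # outer layer
        arr[shell] = 50.0  # hot cortical rim
        bg = background_medians(_pet(arr), lab)
        assert bg["femur"] == 1.0  # erosion sheds the rim entirely

    def test_median_robust_to_outlier(self, phantom_labels):
        arr = np.full(phantom_labels.shape, 3.0, dtype=np.float32)
        c = tuple(np.argwhere(phantom_labels.mask("L2"))[0])
        arr[c] = 500.0
        bg = background_medians(_pet(arr), phantom_labels)
        assert bg["lumbar"] == 3.0

    def test_absent_region_missing(self, phantom_labels):
        vox = phantom_labels.voxels.copy()
        vox[vox == tax.STRUCTURE_IDS["liver"]] = 0
        lab = LabelVolume(vox, (4.0,) * 3, taxonomy=phantom_labels.taxonomy)
        bg = background_medians(_pet(np.ones(vox.shape)), lab)
        assert "liver" not in bg


class TestTbr:
    def test_arithmetic(self):
        assert tbr(10.8, 6.0) == pytest.approx(1.8)

    def test_unity_and_scale_invariance(self):
        assert tbr(4.2, 4.2) == 1.0
        assert tbr(2 * 10.8, 2 * 6.0) == tbr(10.8, 6.0)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tbr(5.0, 0.0)


def _auc_oracle(scores, truth):
    """All-pairs Mann-Whitney count: wins + half-ties over n1*n0."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_half(self):
        r = roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == 0.5

    def test_matches_mann_whitney_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(6, 40)
            scores = rng.integers(0, 10, n).astype(float)  # heavy ties
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            assert roc_auc(scores, truth).auc == pytest.approx(
                _auc_oracle(scores, truth), abs=1e-10
            )

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_tpr_fpr_monotone(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        truth = rng.random(50) < 0.5
        r = roc_auc(scores, truth)
        assert (np.diff(r.tpr) <= 1e-12).all()
        assert (np.diff(r.fpr) <= 1e-12).all()


class TestKsThreshold:
    def test_separable_returns_lowest_positive_score(self):
        scores = [1.0, 2.0, 3.0, 7.0, 8.0]
        truth = [0, 0, 0, 1, 1]
        assert ks_optimal_threshold(scores, truth) == 7.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(8, 50)
            scores = np.round(rng.normal(size=n), 1)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            got = ks_optimal_threshold(scores, truth)
            # brute force over all observed thresholds, lowest-threshold ties
            best, best_j = None, -np.inf
            for t in sorted(set(scores)):
                tprv = np.mean(scores[truth] >= t)
                fprv = np.mean(scores[~truth] >= t)
                if tprv - fprv > best_j + 1e-12:
                    best, best_j = t, tprv - fprv
            assert got == best

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=40)
        truth = rng.random(40) < 0.5
        t1 = ks_optimal_threshold(scores, truth)
        t2 = ks_optimal_threshold(scores**3, truth)
        assert t2 == pytest.approx(t1**3)


class TestDelong:
    def test_identical_scores(self):
        rng = np.random.default_rng(11)
        s = rng.random(40)
        y = rng.random(40) < 0.5
        auc_a, auc_b, delta, var, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(12)
        y = rng.random(60) < 0.5
        a = rng.random(60) + y * 0.5
        b = rng.random(60) + y * 0.2
        ra = delong_test(a, b, y)
        rb = delong_test(b, a, y)
        assert ra[2] == pytest.approx(-rb[2])
        assert ra[4] == pytest.approx(rb[4])

    def test_variance_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(13)
        n = 300
        y = np.arange(n) < 100
        a = rng.normal(size=n) + y * 1.0
        b = 0.7 * a + rng.normal(size=n) * 0.7 + y * 0.4
        *_, var, _p = delong_test(a, b, y)

        def auc(scores, truth):
            return _auc_oracle(scores.tolist(), truth.tolist())

        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            diffs.append(auc(a[idx], yy) - auc(b[idx], yy))
        boot = float(np.var(diffs, ddof=1))
        assert var == pytest.approx(boot, rel=0.15)


class TestClassification:
    def test_boundary_is_closed(self, morph_vois):
        dvu = next(v for v in morph_vois if v.kind == "DVU")
        from axskel.detection import VoiMeasurement

        m = VoiMeasurement(dvu, SuvMetrics(13.5, 13.0, 12.0), "thoracic", 6.0, 2.25)
        pred = classify_vois([m])
        assert pred[dvu.key] is True  # TBR exactly at the 2.25 cut-off

    def test_tbr_rule_example(self, morph_vois):
        fj = next(v for v in morph_vois if v.kind == "FJ" and v.region == "lumbar")
        from axskel.detection import VoiMeasurement

        m = VoiMeasurement(fj, SuvMetrics(10.8, 10.0, 9.0), "lumbar", 6.0, 10.8 / 6.0)
        assert classify_vois([m])[fj.key] is True

    def test_lesions_only_in_planted_vois(self, lesion_setup, phantom_labels):
        pet, truth, vois = lesion_setup
        bg = background_medians(pet, phantom_labels)
        meas = measure_vois(pet, vois, bg)
        pred = classify_vois(meas)
        expect = truth.voi_truth(vois)
        assert pred == expect

    def test_raw_suvmax_rule(self, lesion_setup, phantom_labels):
        pet, truth, vois = lesion_setup
        bg = background_medians(pet, phantom_labels)
        meas = measure_vois(pet, vois, bg)
        pred = classify_vois(meas, rule="raw-suvmax")
        expect = truth.voi_truth(vois)
        assert pred == expect

    def test_background_matching_by_level(self, lesion_setup, phantom_labels):
        pet, _, vois = lesion_setup
        bg = background_medians(pet, phantom_labels)
        for m in measure_vois(pet, vois, bg):
            assert m.background_region == m.voi.region


class TestSensSpec:
    def test_perfect(self):
        assert sensitivity_specificity([1, 0, 1], [1, 0, 1]) == (100.0, 100.0)

    def test_all_positive_predictions(self):
        sens, spec = sensitivity_specificity([1, 1, 1, 1], [1, 0, 1, 0])
        assert (sens, spec) == (100.0, 0.0)

    def test_confusion_table_arithmetic(self):
        # TP 31, FN 5, TN 89, FP 11 -> sensitivity 86.1%, specificity 89.0%
        truth = [1] * 36 + [0] * 100
        pred = [1] * 31 + [0] * 5 + [0] * 89 + [1] * 11
        sens, spec = sensitivity_specificity(pred, truth)
        assert round(sens, 1) == 86.1
        assert round(spec, 1) == 89.0

    def test_empty_class_undefined(self):
        sens, spec = sensitivity_specificity([1, 1], [1, 1])
        assert sens == 100.0 and spec is None
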