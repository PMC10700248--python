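import itertools

import numpy as np
import pytest
from scipy import stats

from ovaseg import evaluation as ev
from _oracles import brute_components, brute_overlap, wilcoxon_enumerate
from ovaseg.volume_io import LabelMap


class TestOverlapMetrics:
    def test_identical_masks(self, toy_labels):
        assert ev.dice(toy_labels, toy_labels, 1) == 100.0
        assert ev.sensitivity_precision(toy_labels, toy_labels, 1) == (100.0, 100.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert ev.dice(a, b, 1) == 0.0

    def test_hand_counts(self):
        pred = np.zeros((1, 1, 10), dtype=np.uint8)
        gt = np.zeros((1, 1, 10), dtype=np.uint8)
        pred[0, 0, :4] = 1   # |P| = 4
        gt[0, 0, 1:7] = 1    # |G| = 6, |P n G| = 3
        assert ev.dice(pred, gt, 1) == pytest.approx(60.0)
        sens, prec = ev.sensitivity_precision(pred, gt, 1)
        assert (sens, prec) == (pytest.approx(50.0), pytest.approx(75.0))

    def test_containment_arithmetic(self):
        gt = np.zeros((2, 2, 4), dtype=np.uint8)
        gt[0, 0, :2] = 1
        pred = np.zeros_like(gt)
        pred[0, 0, :2] = 1
        pred[0, 1, :2] = 1  # P contains G, |P| = 2|G|
        sens, prec = ev.sensitivity_precision(pred, gt, 1)
        assert (sens, prec) == (100.0, 50.0)

    def test_against_voxel_loop_oracle(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(2, 7, 3))
            pred = rng.integers(0, 3, shape).astype(np.uint8)
            gt = rng.integers(0, 3, shape).astype(np.uint8)
            for site in (1, 2):
                tp, fp, fn = brute_overlap(pred, gt, site)
                if tp + fn == 0:
                    continue
                assert ev.dice(pred, gt, site) == pytest.approx(
                    100 * 2 * tp / (2 * tp + fp + fn))
                sens, prec = ev.sensitivity_precision(pred, gt, site)
                assert sens == pytest.approx(100 * tp / (tp + fn))
                if tp + fp:
                    assert prec == pytest.approx(100 * tp / (tp + fp))

    def test_f1_identity_and_symmetry(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(2, 8, 3))
            pred = (rng.uniform(size=shape) < 0.4).astype(np.uint8)
            gt = (rng.uniform(size=shape) < 0.4).astype(np.uint8)
            if not gt.any() or not pred.any():
                continue
            d = ev.dice(pred, gt, 1)
            sens, prec = ev.sensitivity_precision(pred, gt, 1)
            if sens + prec > 0:
                assert d == pytest.approx(2 * sens * prec / (sens + prec), abs=1e-12)
            assert d == pytest.approx(ev.dice(gt, pred, 1))
            s2, p2 = ev.sensitivity_precision(gt, pred, 1)
            assert sens == pytest.approx(p2)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            ev.dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)), 1)


class TestVolume:
    def test_unit_conversion(self):
        lab = LabelMap(np.ones((10, 10, 10), dtype=np.uint8), (1.0, 1.0, 1.0))
        assert ev.volume_cm3(lab, 1) == pytest.approx(1.0)
        assert ev.volume_cm3(lab, 2) == 0.0

    def test_anisotropic_spacing_arithmetic(self):
        lab = np.zeros((5, 10, 10), dtype=np.uint8)
        lab.flat[:100] = 1
        m = LabelMap(lab, (5.0, 0.68, 0.68))
        assert ev.volume_cm3(m, 1) == pytest.approx(100 * 5.0 * 0.68 * 0.68 / 1000)


class TestComponents:
    def test_empty_and_solid(self):
        empty = np.zeros((4, 4, 4), dtype=np.uint8)
        assert ev.component_count(empty, 1) == 0
        solid = np.ones((4, 4, 4), dtype=np.uint8)
        assert ev.component_count(solid, 1) == 1

    def test_corner_touch_connectivity(self):
        m = np.zeros((2, 2, 2), dtype=np.uint8)
        m[0, 0, 0] = m[1, 1, 1] = 1
        assert ev.component_count(m, 1, connectivity=26) == 1
        assert ev.component_count(m, 1, connectivity=6) == 2

    def test_against_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = (rng.uniform(size=(5, 5, 5)) < 0.3).astype(np.uint8)
            assert ev.component_count(m, 1, 26) == brute_components(m == 1, True)
            assert ev.component_count(m, 1, 6) == brute_components(m == 1, False)

    def test_invariant_under_flips(self, rng):
        m = (rng.uniform(size=(6, 6, 6)) < 0.3).astype(np.uint8)
        base = ev.component_count(m, 1)
        for ax in range(3):
            assert ev.component_count(np.flip(m, ax), 1) == base


class TestConfusion:
    def test_perfect_prediction_no_flags(self, toy_labels):
        flags = ev.cross_site_confusion(toy_labels, toy_labels)
        assert not any(flags.values())

    def test_constructed_direction(self):
        gt = np.ones((3, 3, 3), dtype=np.uint8)
        pred = np.full((3, 3, 3), 2, dtype=np.uint8)
        flags = ev.cross_site_confusion(pred, gt)
        assert flags[(1, 2)] and not flags[(2, 1)]

    def test_against_voxel_loop(self, rng):
        for _ in range(10):
            pred = rng.integers(0, 3, (4, 4, 4)).astype(np.uint8)
            gt = rng.integers(0, 3, (4, 4, 4)).astype(np.uint8)
            flags = ev.cross_site_confusion(pred, gt)
            for a, b in [(1, 2), (2, 1)]:
                expect = any(gt[idx] == a and pred[idx] == b
                             for idx in np.ndindex(gt.shape))
                assert flags[(a, b)] == expect


class TestBlandAltman:
    def test_identical_lists(self):
        bias, (lo, hi) = ev.bland_altman([1, 2, 3], [1, 2, 3])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        bias, (lo, hi) = ev.bland_altman([2, 5], [1, 2])
        sd = np.sqrt(2)
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(2 - 1.96 * sd)
        assert hi == pytest.approx(2 + 1.96 * sd)

    def test_undersegmentation_gives_positive_bias(self, rng):
        gt = rng.uniform(10, 100, 20)
        pred = gt * 0.8
        bias, _ = ev.bland_altman(gt, pred)
        assert bias > 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ev.bland_altman([1.0], [2.0])


class TestWilcoxon:
    def test_degenerate_equal_lists(self):
        w, p, n = ev.wilcoxon_paired([1, 2, 3], [1, 2, 3])
        assert (p, n) == (1.0, 0)

    def test_six_positive_differences_exact(self):
        a = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        w, p, n = ev.wilcoxon_paired(a + np.array([1, 2, 3, 4, 5, 6]), a)
        assert n == 6
        assert p == pytest.approx(2 / 64)

    def test_swap_symmetry(self, rng):
        a = rng.uniform(size=12)
        b = rng.uniform(size=12)
        assert ev.wilcoxon_paired(a, b)[1] == pytest.approx(ev.wilcoxon_paired(b, a)[1])

    def test_exact_p_matches_full_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 11))
            a = rng.uniform(size=n)
            b = rng.uniform(size=n)
            _, p, _ = ev.wilcoxon_paired(a, b)
            assert p == pytest.approx(wilcoxon_enumerate(a - b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            _, p, _ = ev.wilcoxon_paired(a, b)
            sp = stats.wilcoxon(a, b, method="exact", zero_method="wilcox")
            assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_ties_handled_with_midranks(self):
        a = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(6)  # |d| has a tie
        _, p, n = ev.wilcoxon_paired(a, b)
        assert n == 6
        assert p == pytest.approx(wilcoxon_enumerate(a - b), abs=1e-12)


class TestCohortReport:
    @pytest.fixture()
    def cohort(self, tmp_path, rng):
        """3 scans; scan c has no omental ground truth."""
        import pandas as pd
        from ovaseg import volume_io
        rows = []
        pred_dir = tmp_path / "pred"
        pred_dir.mkdir()
        for i, sid in enumerate(["a", "b", "c"]):
            gt = np.zeros((4, 8, 8), dtype=np.uint8)
            gt[1:3, 1:4, 1:4] = 1
            if sid != "c":
                gt[0, 5:7, 5:7] = 2
            pred = gt.copy()
            if sid == "b":
                pred[1, 1, 1] = 0
            if sid == "c":
                pred[3, 6:8, 0:2] = 2  # spurious omental prediction
            volume_io.write_labelmap(LabelMap(gt, (5, 1, 1), scan_id=sid),
                                     tmp_path / f"{sid}_gt.nii.gz")
            volume_io.write_labelmap(LabelMap(pred, (5, 1, 1), scan_id=sid),
                                     pred_dir / f"{sid}.nii.gz")
            rows.append({"patient_id": f"P{i}", "scan_id": sid, "timepoint": "pre",
                         "image": str(tmp_path / f"{sid}_gt.nii.gz"),
                         "label": str(tmp_path / f"{sid}_gt.nii.gz")})
        return pd.DataFrame(rows), pred_dir, tmp_path

    def test_site_filtering_rule(self, cohort):
        manifest, pred_dir, out = cohort
        report, per_scan = ev.cohort_report(manifest, pred_dir, out_dir=out / "rep")
        assert report["sites"]["omental"]["dsc"]["n"] == 2
        assert report["sites"]["pelvic_ovarian"]["dsc"]["n"] == 3
        # scan c: spurious omental prediction contributes no omental DSC
        row_c = per_scan[per_scan.scan_id == "c"].iloc[0]
        assert np.isnan(row_c["omental_dsc"])

    def test_aggregates_match_spreadsheet_recomputation(self, cohort):
        import pandas as pd
        manifest, pred_dir, out = cohort
        report, _ = ev.cohort_report(manifest, pred_dir, out_dir=out / "rep")
        per_scan = pd.read_csv(out / "rep" / "per_scan_metrics.csv")
        vals = per_scan["pelvic_ovarian_dsc"].dropna()
        assert report["sites"]["pelvic_ovarian"]["dsc"]["mean"] == pytest.approx(vals.mean())
        assert report["sites"]["pelvic_ovarian"]["dsc"]["sd"] == pytest.approx(
            vals.std(ddof=1))

    def test_missing_prediction_listed(self, cohort, tmp_path):
        manifest, pred_dir, _ = cohort
        (pred_dir / "a.nii.gz").unlink()
        with pytest.raises(FileNotFoundError, match="a.nii.gz"):
            ev.cohort_report(manifest, pred_dir)

    def test_compare_methods_wilcoxon(self, cohort):
        manifest, pred_dir, out = cohort
        _, per_scan = ev.cohort_report(manifest, pred_dir)
        res = ev.compare_methods(per_scan, per_scan)
        assert res["pelvic_ovarian"]["p"] == 1.0
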