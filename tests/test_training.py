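import json

import numpy as np
import pandas as pd
import pytest

from ovaseg.network import NetworkConfig, build_network
from ovaseg.training import (TrainConfig, Trainer, _Case, assign_folds,
                             combined_loss, lr_at_step, sample_patch)


class TestSchedule:
    def test_warmup_cosine_hits_peak_exactly(self):
        cfg = TrainConfig(total_steps=1000)
        warmup = round(cfg.warmup_fraction * 1000)
        assert lr_at_step(warmup, 1000, cfg) == cfg.peak_lr
        lrs = [lr_at_step(s, 1000, cfg) for s in range(1001)]
        assert max(lrs) == cfg.peak_lr

    def test_zero_at_final_step(self):
        cfg = TrainConfig(total_steps=1000)
        assert lr_at_step(1000, 1000, cfg) == 0.0

    def test_decay_midpoint_closed_form(self):
        cfg = TrainConfig(total_steps=1000, warmup_fraction=0.0)
        # halfway through decay: peak * 0.5 * (1 + cos(pi/2)) = peak / 2
        assert lr_at_step(500, 1000, cfg) == pytest.approx(0.01)

    def test_continuous_at_warmup_boundary(self):
        cfg = TrainConfig(total_steps=1000)
        w = round(cfg.warmup_fraction * 1000)
        assert lr_at_step(w, 1000, cfg) - lr_at_step(w - 1, 1000, cfg) < 0.015

    def test_poly_schedule(self):
        cfg = TrainConfig.baseline(total_steps=1000)
        assert lr_at_step(0, 1000, cfg) == 0.01
        assert lr_at_step(1000, 1000, cfg) == 0.0
        assert lr_at_step(500, 1000, cfg) == pytest.approx(0.01 * 0.5 ** 0.9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at_step(1001, 1000, TrainConfig(total_steps=1000))

    def test_recipe_constants(self):
        tuned, base = TrainConfig(), TrainConfig.baseline()
        assert (tuned.batch_size, tuned.momentum, tuned.weight_decay,
                tuned.peak_lr) == (4, 0.98, 1e-4, 0.02)
        assert (base.batch_size, base.momentum, base.weight_decay,
                base.peak_lr, base.schedule) == (2, 0.99, 3e-5, 0.01, "poly")


class TestLoss:
    def test_near_perfect_scores_near_optimum(self):
        target = np.zeros((1, 4, 4, 4), dtype=np.int64)
        target[0, 1:3, 1:3, 1:3] = 1
        scores = np.full((1, 4, 4, 4, 3), -20.0, dtype=np.float64)
        for c in range(3):
            scores[..., c][target == c] = 20.0
        val = combined_loss(scores, target)
        assert val < 1e-3

    def test_uniform_probabilities_match_hand_computation(self):
        # 2-voxel toy instance, one background one class-1 voxel, zero scores
        scores = np.zeros((1, 1, 1, 2, 3))
        target = np.array([[[[0, 1]]]])
        val = combined_loss(scores, target)
        ce = -np.log(1 / 3)
        # batch dice per fg class c: (2*(1/3) + 1) / (2/3 + 1 + 1) for c=1
        # (one gt voxel, predicted mass 2/3), and (0 + 1)/(2/3 + 0 + 1) for c=2
        d1 = (2 / 3 + 1) / (2 / 3 + 1 + 1)
        d2 = 1 / (2 / 3 + 1)
        expect = ce + 1 - (d1 + d2) / 2
        assert val == pytest.approx(expect, rel=1e-6)

    def test_permutation_invariance(self, rng):
        scores = rng.standard_normal((1, 2, 2, 4, 3))
        target = rng.integers(0, 3, (1, 2, 2, 4))
        v1 = combined_loss(scores, target)
        perm = rng.permutation(4)
        v2 = combined_loss(scores[:, :, :, perm], target[:, :, :, perm])
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_deep_supervision_weighted_sum(self, rng):
        s0 = rng.standard_normal((1, 4, 4, 4, 3))
        s1 = rng.standard_normal((1, 2, 2, 2, 3))
        target = rng.integers(0, 3, (1, 4, 4, 4))
        v = combined_loss({0: s0, 1: s1}, target)
        v0 = combined_loss(s0, target)
        v1 = combined_loss(s1, target[:, ::2, ::2, ::2])
        assert v == pytest.approx((v0 + 0.5 * v1) / 1.5, rel=1e-9)

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            combined_loss(np.zeros((1, 4, 4, 4, 3)), np.zeros((1, 4, 4, 5), dtype=int))


class TestSamplePatch:
    def test_forced_foreground_always_contains_lesion_voxel(self, rng):
        vol = np.zeros((10, 10, 10), dtype=np.float32)
        lab = np.zeros((10, 10, 10), dtype=np.int64)
        lab[7, 2, 9] = 1
        for _ in range(20):
            _, lp = sample_patch(vol, lab, (4, 4, 4), p_fg=1.0, rng=rng)
            assert (lp == 1).any()

    def test_uniform_positions_flat_histogram(self, rng):
        """p_fg = 0: chi-square of start positions vs uniform, 10^4 draws."""
        from scipy import stats
        vol = np.zeros((6, 1, 1), dtype=np.float32)
        lab = np.zeros((6, 1, 1), dtype=np.int64)
        counts = np.zeros(3, dtype=int)  # valid z starts: 0..2 for patch 4
        for _ in range(10_000):
            p, _ = sample_patch(vol + np.arange(6)[:, None, None], lab, (4, 1, 1),
                                p_fg=0.0, rng=rng)
            counts[int(p[0, 0, 0])] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_volume_smaller_than_patch_padded(self, rng):
        vol = np.ones((3, 3, 3), dtype=np.float32)
        lab = np.ones((3, 3, 3), dtype=np.int64)
        pv, pl = sample_patch(vol, lab, (6, 6, 6), p_fg=0.0, rng=rng)
        assert pv.shape == (6, 6, 6)
        assert set(np.unique(pl)) == {0, 1}  # label padding is background


class TestFolds:
    def manifest(self, n_patients, scans_each=2):
        rows = []
        for p in range(n_patients):
            for s in range(scans_each):
                rows.append({"patient_id": f"P{p}", "scan_id": f"P{p}_s{s}",
                             "timepoint": "pre" if s == 0 else "post",
                             "image": "", "label": ""})
        return pd.DataFrame(rows)

    def test_grouped_balanced_five_fold(self):
        m = self.manifest(10)
        folds = assign_folds(m, 5, seed=0)
        by_fold = {}
        for sid, f in folds.items():
            by_fold.setdefault(f, set()).add(sid.split("_")[0])
        assert sorted(by_fold) == [0, 1, 2, 3, 4]
        assert all(len(p) == 2 for p in by_fold.values())
        # brute-force pair scan: scans of one patient never span folds
        for a in folds:
            for b in folds:
                if a.split("_")[0] == b.split("_")[0]:
                    assert folds[a] == folds[b]

    def test_k1_single_fold(self):
        folds = assign_folds(self.manifest(3), 1, seed=0)
        assert set(folds.values()) == {0}

    def test_deterministic_in_seed(self):
        m = self.manifest(7)
        assert assign_folds(m, 3, 5) == assign_folds(m, 3, 5)
        assert assign_folds(m, 3, 5) != assign_folds(m, 3, 6)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            assign_folds(self.manifest(3), 5, seed=0)


class TestTrainer:
    def test_loss_decreases_and_log_written(self, tmp_path, rng):
        vol = rng.standard_normal((12, 16, 16)).astype(np.float32)
        lab = np.zeros((12, 16, 16), dtype=np.int64)
        lab[4:8, 4:12, 4:12] = 1
        vol[lab == 1] += 3.0
        cfg = NetworkConfig(base_filters=2, blocks_per_stage=(1, 1, 1, 1),
                            spacing=(1, 1, 1))
        tcfg = TrainConfig(batch_size=2, total_steps=30, patch_size=(8, 8, 8),
                           log_every=10)
        tr = Trainer([_Case("a", vol, lab)], cfg, tcfg,
                     log_path=tmp_path / "log.jsonl")
        tr.run()
        first = np.mean([h["loss"] for h in tr.history[:5]])
        last = np.mean([h["loss"] for h in tr.history[-5:]])
        assert last < first
        recs = [json.loads(l) for l in (tmp_path / "log.jsonl").read_text().splitlines()]
        assert {"step", "lr", "loss"} <= set(recs[0])

    def test_ensemble_probability_is_mean_of_members(self, rng):
        from ovaseg.inference import InferenceConfig, sliding_window_predict

        class StubNet:
            n_classes = 3

            def __init__(self, bias):
                self.bias = bias
                self.config = None

            def patch_divisor(self):
                return (1, 1, 1)

            def __call__(self, x):
                s = np.repeat(x, 3, axis=-1)
                s[..., 1] += self.bias
                return s

        img = rng.standard_normal((6, 6, 6)).astype(np.float32)
        cfg = InferenceConfig(window_size=(6, 6, 6), tta=False)
        pa = sliding_window_predict(img, [StubNet(0.3)], cfg)
        pb = sliding_window_predict(img, [StubNet(-0.2)], cfg)
        pab = sliding_window_predict(img, [StubNet(0.3), StubNet(-0.2)], cfg)
        assert np.allclose(pab, (pa + pb) / 2, atol=1e-6)
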