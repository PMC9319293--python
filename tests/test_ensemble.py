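"""Weighted fusion, grid-search calibration and the evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebusml.ensemble import (PAPER_CUTOFF, PAPER_WEIGHTS, EnsembleConfig,
                             fuse, fuse_batch, metrics, optimize)


class TestFuse:
    def test_default_weights_sum_to_one(self):
        cfg = EnsembleConfig()
        assert cfg.weights == PAPER_WEIGHTS
        assert sum(cfg.weights) == pytest.approx(1.0, abs=1e-12)

    def test_agreement_is_fixed_point(self):
        for p in (0.0, 0.25, 0.53, 1.0):
            fused, _ = fuse(p, p, p, EnsembleConfig((0.2, 0.3, 0.5), 0.5))
            assert fused == pytest.approx(p)

    def test_published_worked_example(self):
        fused, label = fuse(0.9, 0.2, 0.8)
        assert fused == pytest.approx(0.41 * 0.9 + 0.08 * 0.2 + 0.51 * 0.8)
        assert fused == pytest.approx(0.793)
        assert label == 1

    def test_cutoff_boundary_is_benign(self):
        fused, label = fuse(0.53, 0.53, 0.53)
        assert fused == pytest.approx(PAPER_CUTOFF)
        assert label == 0

    def test_missing_p3_renormalizes(self):
        fused, _ = fuse(0.8, 0.4, None, EnsembleConfig((0.25, 0.25, 0.5), 0.5))
        assert fused == pytest.approx(0.6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig((0.5, 0.5, 0.1), 0.5)
        with pytest.raises(ValueError):
            EnsembleConfig((-0.1, 0.6, 0.5), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(*[st.floats(0, 1) for _ in range(3)]),
           st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    def test_convex_combination_bounds(self, ps, ws):
        total = sum(ws)
        if total == 0:
            return
        w = tuple(x / total for x in ws)
        w = (w[0], w[1], 1.0 - w[0] - w[1])
        if w[2] < 0:
            return
        fused, _ = fuse(*ps, EnsembleConfig(w, 0.5))
        assert min(ps) - 1e-9 <= fused <= max(ps) + 1e-9


class TestOptimize:
    def test_beats_every_single_model(self, rng):
        y = rng.integers(0, 2, size=80)
        p1 = np.clip(y + rng.normal(0, 0.4, 80), 0, 1)
        p2 = rng.random(80)
        p3 = np.clip(y + rng.normal(0, 0.3, 80), 0, 1)
        cfg = optimize(p1, p2, p3, y)
        fused, pred = fuse_batch(p1, p2, p3, cfg)
        acc = (pred == y).mean()
        for p in (p1, p2, p3):
            best_single = max((((p > c).astype(int) == y).mean()
                               for c in np.arange(0.01, 1, 0.01)))
            assert acc >= best_single - 1e-12

    def test_perfect_agreement_tie_break_deterministic(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        cfg = optimize(p, p, p, y)
        # accuracy 1 first reached at cutoff 0.2 (classification is strict >)
        # with lexicographically smallest weights (0, 0, 1)
        assert cfg.cutoff == pytest.approx(0.2)
        assert cfg.weights == (0.0, 0.0, 1.0)

    def test_noise_model_gets_near_zero_weight(self, rng):
        y = rng.integers(0, 2, size=200)
        p1 = np.clip(y + rng.normal(0, 0.2, 200), 0, 1)
        p2 = rng.random(200)                    # pure noise
        p3 = np.clip(y + rng.normal(0, 0.25, 200), 0, 1)
        cfg = optimize(p1, p2, p3, y)
        assert cfg.weights[1] <= 0.15

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError):
            optimize(np.ones(4), np.ones(4), np.ones(4), np.ones(4, dtype=int))


class TestMetrics:
    def test_worked_confusion_row(self):
        pred = np.array([1] * 23 + [0] * 2 + [1] * 4 + [0] * 11)
        y = np.array([1] * 25 + [0] * 15)
        r = metrics(pred, y)
        assert (r.tp, r.fn, r.fp, r.tn) == (23, 2, 4, 11)
        pct = r.as_percent()
        assert pct["accuracy"] == 85.00
        assert pct["sensitivity"] == 92.00
        assert pct["specificity"] == 73.33
        assert pct["ppv"] == 85.19
        assert pct["npv"] == 84.62

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        r = metrics(y, y, scores=y.astype(float))
        pct = r.as_percent()
        assert all(pct[k] == 100.0 for k in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv"))
        assert r.auc == 1.0

    def test_no_malignant_cases_gives_na_sensitivity(self):
        y = np.zeros(6, dtype=int)
        r = metrics(np.zeros(6, dtype=int), y)
        assert r.sensitivity is None
        assert r.as_percent()["sensitivity"] is None

    def test_agrees_with_recount_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            r = metrics(pred, y)
            tp = sum(1 for a, b in zip(pred, y) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(pred, y) if a == 0 and b == 0)
            assert r.tp == tp and r.tn == tn
            assert r.accuracy == pytest.approx((tp + tn) / n)
            # exact identity before rounding
            n_mal, n_ben = int((y == 1).sum()), int((y == 0).sum())
            sen = r.sensitivity if n_mal else 0.0
            spec = r.specificity if n_ben else 0.0
            assert r.accuracy * n == pytest.approx(sen * n_mal + spec * n_ben)
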