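"""Three-rule cascade logic, threshold optimizer, and the stand-in B/S scorer."""

import math

import numpy as np
import pytest

from hurthleseq.cascade import (
    BENIGN,
    SUSPICIOUS,
    CascadeConfig,
    cascade_call,
    _benign_mask,
    optimize_thresholds,
    standin_bs_scorer,
    tune_nominal_threshold,
)


def cascade_oracle(h, n, bs, cfg):
    """Literal transcription of the three printed rules."""
    if bs < cfg.t_bs_nominal:
        return (BENIGN, 1, False)
    if h > cfg.t_h and n < cfg.t_n and cfg.t_bs_nominal <= bs < cfg.t_bs_hurthle:
        return (BENIGN, 2, True)
    return (SUSPICIOUS, 3, False)


CFG = CascadeConfig(t_h=0.0, t_n=0.0, t_bs_nominal=0.0, t_bs_hurthle=0.5)


@pytest.mark.parametrize(
    "h, n, bs, call, rule, rescued",
    [
        (5.0, 5.0, -0.01, BENIGN, 1, False),       # rule 1 regardless of H/N
        (0.6, -0.2, 0.3, BENIGN, 2, True),          # textbook rescue
        (0.6, 0.2, 0.3, SUSPICIOUS, 3, False),      # NI-positive blocks rescue
        (-0.6, -0.2, 0.3, SUSPICIOUS, 3, False),    # HI-negative blocks rescue
        (0.6, -0.2, 0.5, SUSPICIOUS, 3, False),     # BS == t_bs_hurthle: strict <
        (0.6, -0.2, 0.0, BENIGN, 2, True),          # BS == t_bs_nominal: left-closed
        (0.0, -0.2, 0.3, SUSPICIOUS, 3, False),     # H == t_h: strict >
        (0.6, 0.0, 0.3, SUSPICIOUS, 3, False),      # N == t_n: strict <
    ],
)
def test_rule_table_and_boundaries(h, n, bs, call, rule, rescued):
    res = cascade_call(h, n, bs, CFG)
    assert (res.call, res.rule_fired, res.rescue_flag) == (call, rule, rescued)


def test_missing_n_only_allowed_for_hi_negative():
    res = cascade_call(-1.0, None, 0.3, CFG)
    assert res.call == SUSPICIOUS
    res = cascade_call(-1.0, None, -0.5, CFG)
    assert res.call == BENIGN and res.rule_fired == 1
    with pytest.raises(ValueError, match="missing N score"):
        cascade_call(1.0, None, 0.3, CFG)
    with pytest.raises(ValueError, match="missing N score"):
        cascade_call(1.0, math.nan, 0.3, CFG)


def test_nonfinite_scores_rejected():
    with pytest.raises(ValueError):
        cascade_call(math.inf, 0.0, 0.0, CFG)


def test_config_requires_adjusted_at_least_nominal():
    with pytest.raises(ValueError, match="adjusted threshold"):
        CascadeConfig(t_h=0, t_n=0, t_bs_nominal=1.0, t_bs_hurthle=0.5)


def test_degenerate_config_disables_rescue():
    cfg = CascadeConfig(t_h=0, t_n=0, t_bs_nominal=0.2, t_bs_hurthle=0.2)
    for bs in (-0.1, 0.2, 0.3):
        res = cascade_call(1.0, -1.0, bs, cfg)
        assert not res.rescue_flag
        assert res.call == (BENIGN if bs < 0.2 else SUSPICIOUS)


def test_randomized_agreement_with_oracle_and_exclusivity():
    """10^4 random score triples / configs, drawn on a lattice to hit ties."""
    rng = np.random.default_rng(123)
    grid = np.round(np.linspace(-1, 1, 9), 3)
    for _ in range(10_000):
        h, n, bs, t_h, t_n = rng.choice(grid, 5)
        t_nom = rng.choice(grid)
        t_bsh = t_nom + abs(rng.choice(grid))
        cfg = CascadeConfig(t_h=t_h, t_n=t_n, t_bs_nominal=t_nom, t_bs_hurthle=t_bsh)
        res = cascade_call(h, n, bs, cfg)
        assert (res.call, res.rule_fired, res.rescue_flag) == cascade_oracle(h, n, bs, cfg)
        assert res.rule_fired in (1, 2, 3)  # exactly one rule fires


def test_benign_rate_monotone_in_thresholds():
    """Raising t_bs_hurthle never removes benign calls; raising t_n never removes them."""
    rng = np.random.default_rng(5)
    h, n, bs = rng.normal(size=(3, 400))
    base = _benign_mask(h, n, bs, 0.0, 0.0, 0.0, 0.4)[0]
    wider = _benign_mask(h, n, bs, 0.0, 0.0, 0.0, 0.9)[0]
    assert (wider | ~base).all() and wider.sum() >= base.sum()
    laxer_n = _benign_mask(h, n, bs, 0.0, 0.8, 0.0, 0.4)[0]
    assert (laxer_n | ~base).all()


class TestTuneNominal:
    def test_picks_most_specific_threshold_above_floor(self):
        bs = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        t = tune_nominal_threshold(bs, y, sensitivity_floor=0.9)
        sens = (bs[y] >= t).mean()
        assert sens > 0.9
        assert t == 0.8  # every benign below it -> specificity 1 at full sensitivity

    def test_warns_when_floor_unreachable(self):
        bs = np.array([0.5, 0.5])
        y = np.array([1, 0], dtype=bool)
        with pytest.warns(RuntimeWarning):
            tune_nominal_threshold(bs, y, sensitivity_floor=2.0)


class TestOptimizer:
    def _scores(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        mal = rng.random(n) < 0.3
        bs = rng.normal(0, 1, n) + 1.6 * mal
        h = rng.normal(0, 1, n)
        nn = rng.normal(0, 1, n) + 1.0 * mal
        return h, nn, bs, mal

    def test_floor_zero_is_unconstrained_specificity_maximum(self):
        h, n, bs, mal = self._scores()
        cfg, rep = optimize_thresholds(h, n, bs, mal, sensitivity_floor=0.0,
                                       n_quantiles=12)
        # brute force over the same grids
        qs = np.linspace(0, 1, 12)
        best_spec = -1.0
        t_nom = cfg.t_bs_nominal
        rule1 = bs < t_nom
        for t_h in np.unique(np.quantile(h, qs)):
            for t_n in np.unique(np.quantile(n, qs)):
                for t_bsh in np.concatenate([[t_nom], np.unique(np.quantile(bs[bs >= t_nom], qs))]):
                    benign = rule1 | ((~rule1) & (h > t_h) & (n < t_n) & (bs < t_bsh))
                    best_spec = max(best_spec, benign[~mal].mean())
        assert rep.specificity == pytest.approx(best_spec)

    def test_separable_scores_reach_perfect_performance(self):
        mal = np.array([False] * 50 + [True] * 50)
        bs = np.where(mal, 2.0, -2.0) + np.linspace(0, 0.1, 100)
        h = np.zeros(100)
        n = np.zeros(100)
        cfg, rep = optimize_thresholds(h, n, bs, mal, sensitivity_floor=0.9)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_rescue_never_hurts_constrained_specificity(self):
        h, n, bs, mal = self._scores(seed=3)
        cfg, rep = optimize_thresholds(h, n, bs, mal, sensitivity_floor=0.85)
        assert rep.floor_met and rep.sensitivity > 0.85
        # specificity at the degenerate config (no rescue window)
        no_rescue = _benign_mask(h, n, bs, cfg.t_h, cfg.t_n,
                                 cfg.t_bs_nominal, cfg.t_bs_nominal)[0]
        assert rep.specificity >= no_rescue[~mal].mean()

    def test_impossible_floor_returns_max_sensitivity_with_warning(self):
        h, n, bs, mal = self._scores(seed=4, n=60)
        with pytest.warns(RuntimeWarning, match="floor"):
            cfg, rep = optimize_thresholds(
                h, n, bs, mal, t_bs_nominal=float(bs.max()) + 1.0,
                sensitivity_floor=0.99,
            )
        assert not rep.floor_met


class TestStandinBs:
    def test_separable_toy_auc_one_and_determinism(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 30)
        X = rng.normal(size=(60, 4))
        X[:, 0] += 4.0 * y
        s1 = standin_bs_scorer(X, y, seed=9).scores(X)
        s2 = standin_bs_scorer(X, y, seed=9).scores(X)
        np.testing.assert_array_equal(s1, s2)
        from hurthleseq.classifiers import roc_auc

        assert roc_auc(s1, y) == 1.0

    def test_ensemble_size(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 20)
        X = rng.normal(size=(40, 3)) + y[:, None]
        scorer = standin_bs_scorer(X, y, seed=2, n_models=5)
        assert len(scorer.models) == 5
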