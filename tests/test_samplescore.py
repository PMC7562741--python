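"""Kernel statistic, KS-like walk scores, and cohort contrasts."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_bundle
from synopipe.samplescore import (
    compare_groups,
    enrichment_scores,
    expression_statistic,
    hedges_g,
)


def walk_oracle(ranks_col, weights_col, in_set, tau=1.0, mode="diff"):
    """Step-by-step enumeration of the random walk for one sample."""
    p = len(ranks_col)
    order = sorted(range(p), key=lambda g: ranks_col[g])
    m = sum(in_set)
    total = sum(abs(weights_col[g]) ** tau for g in order if in_set[g])
    cum, vmax, vmin = 0.0, -np.inf, np.inf
    for g in order:
        if in_set[g]:
            cum += abs(weights_col[g]) ** tau / total
        else:
            cum -= 1.0 / (p - m)
        vmax, vmin = max(vmax, cum), min(vmin, cum)
    if mode == "diff":
        return max(vmax, 0.0) + min(vmin, 0.0)
    return vmax if abs(vmax) >= abs(vmin) else vmin


def test_kernel_statistic_monotone_in_expression():
    b = make_bundle(np.array([[1.0, 2.0, 3.0]]))
    stat = expression_statistic(b)
    z = stat.zhat.iloc[0]
    assert z["S0"] < z["S1"] < z["S2"]


def test_kernel_statistic_matches_direct_summation(rng):
    X = rng.normal(6, 1, size=(3, 5))
    stat = expression_statistic(make_bundle(X))
    for i in range(3):
        h = X[i].std(ddof=1) / 4.0
        for j in range(5):
            manual = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(5)])
            assert stat.zhat.iloc[i, j] == pytest.approx(manual, abs=1e-12)


def test_constant_genes_excluded_with_warning(rng):
    X = rng.normal(0, 1, size=(5, 6))
    X[2] = 3.0
    with pytest.warns(UserWarning, match="constant"):
        stat = expression_statistic(make_bundle(X))
    assert stat.excluded == ["g2"]
    assert "g2" not in stat.zhat.index


def test_walk_matches_enumeration_oracle(rng):
    X = rng.normal(6, 1, size=(4, 5))
    b = make_bundle(X)
    stat = expression_statistic(b)
    sets = {"s": ["g1", "g3"]}
    for tau in (0.0, 1.0, 2.0):
        for mode in ("diff", "max"):
            sm = enrichment_scores(stat, sets, tau=tau, mode=mode)
            for j, col in enumerate(stat.ranks.columns):
                ranks = stat.ranks[col].to_numpy()
                weights = stat.weights[col].to_numpy()
                in_set = np.array([g in {"g1", "g3"} for g in stat.ranks.index])
                expected = walk_oracle(ranks, weights, in_set, tau=tau, mode=mode)
                assert sm.scores.iloc[0, j] == pytest.approx(expected, abs=1e-12)


def test_top_half_set_scores_positive(rng):
    # genes 0..4 strictly above genes 5..9 in every sample
    X = np.vstack([rng.normal(10, 0.1, size=(5, 6)), rng.normal(0, 0.1, size=(5, 6))])
    # ensure per-sample z-ranks favor the high block: shift block samples jointly
    X[:5] += np.arange(6) * 2.0
    X[5:] -= np.arange(6) * 2.0
    b = make_bundle(X)
    stat = expression_statistic(b)
    sm = enrichment_scores(stat, {"top": [f"g{i}" for i in range(5)]})
    top_ranks = stat.ranks.iloc[:5]
    if (top_ranks.to_numpy() <= 5).all():
        assert (sm.scores.to_numpy() > 0).all()


def test_score_bounds_and_error_cases(rng):
    X = rng.normal(0, 1, size=(10, 5))
    stat = expression_statistic(make_bundle(X))
    sm = enrichment_scores(stat, {"s": [f"g{i}" for i in range(4)]})
    assert (np.abs(sm.scores.to_numpy()) < 1.0).all()
    with pytest.raises(ValueError, match="no genes"):
        enrichment_scores(stat, {"none": ["zzz"]})
    with pytest.raises(ValueError, match="whole matrix"):
        enrichment_scores(stat, {"all": [f"g{i}" for i in range(10)]})


def test_scores_exactly_invariant_under_monotone_gene_transforms(rng):
    X = rng.normal(6, 1, size=(12, 6))
    b = make_bundle(X)
    stat = expression_statistic(b, kernel="ecdf")
    sets = {"s": ["g0", "g3", "g7"]}
    sm = enrichment_scores(stat, sets)
    # strictly increasing per-gene transforms leave row orders intact
    Y = X.copy()
    Y[::2] = np.exp(Y[::2] / 2.0)
    Y[1::2] = Y[1::2] ** 3 + 5.0
    stat2 = expression_statistic(make_bundle(Y), kernel="ecdf")
    sm2 = enrichment_scores(stat2, sets)
    assert (stat.ranks.to_numpy() == stat2.ranks.to_numpy()).all()
    assert (sm.scores.to_numpy() == sm2.scores.to_numpy()).all()


def test_uniform_weight_complement_antisymmetry(rng):
    # tau=0: all weights equal; complement set walks mirror each other
    X = rng.normal(0, 1, size=(8, 5))
    stat = expression_statistic(make_bundle(X))
    half = [f"g{i}" for i in range(4)]
    comp = [f"g{i}" for i in range(4, 8)]
    s1 = enrichment_scores(stat, {"a": half}, tau=0.0).scores.to_numpy()
    s2 = enrichment_scores(stat, {"b": comp}, tau=0.0).scores.to_numpy()
    assert np.allclose(s1, -s2, atol=1e-12)


def test_hedges_g_hand_example_and_trivial_cases():
    g, J = hedges_g([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert J == pytest.approx(0.8)
    assert g == pytest.approx(-2.4)
    g0, _ = hedges_g([1.0, 2.0], [1.0, 2.0])
    assert g0 == 0.0


def test_compare_groups_identical_and_error_cases(rng):
    X = rng.normal(0, 1, size=(6, 8))
    b = make_bundle(X)
    stat = expression_statistic(b)
    sm = enrichment_scores(stat, {"s": ["g0", "g1"]})
    # duplicate the scores across cohorts -> t=0, p=1, g=0
    sm.scores.iloc[0, :4] = [0.1, 0.2, 0.3, 0.4]
    sm.scores.iloc[0, 4:] = [0.1, 0.2, 0.3, 0.4]
    res = compare_groups(sm, b.cohort)
    assert res.loc["s", "t"] == pytest.approx(0.0)
    assert res.loc["s", "p"] == pytest.approx(1.0)
    assert res.loc["s", "g"] == pytest.approx(0.0)
    bad_cohort = b.cohort.copy()
    bad_cohort[:] = 1
    bad_cohort.iloc[0] = 0
    with pytest.raises(ValueError, match=">= 2 samples"):
        compare_groups(sm, bad_cohort)


def test_hedges_g_small_sample_correction_removes_bias(rng):
    gs = [hedges_g(rng.normal(1.0, 1.0, 4), rng.normal(0.0, 1.0, 4))[0]
          for _ in range(1000)]
    assert np.mean(gs) == pytest.approx(1.0, abs=0.1)


def test_planted_set_shift_detected_with_positive_effect():
    from synopipe.samplescore import expression_statistic as estat
    from synopipe.synthdata import SimulationConfig, generate_expression

    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=200, n_signal_genes=25, lfc_range=(1.5, 1.5), down_fraction=0.0,
            n_modules=0, module_size=0, n_samples_per_cohort=(4, 4), seed=seed,
        )
        b = generate_expression(cfg)
        stat = estat(b)
        sm = enrichment_scores(stat, {"planted": list(b.ground_truth.signal_genes)})
        res = compare_groups(sm, b.cohort)
        hits += (res.loc["planted", "p"] < 0.05) and (res.loc["planted", "g"] > 0)
    assert hits / n_seeds >= 0.9
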