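"""TOM construction, module detection, eigengenes, merging, trait QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_bundle
from synopipe.coexnet import (
    NetworkParams,
    ModuleSet,
    build_tom,
    compute_eigengenes,
    correlate_traits,
    detect_modules,
    merge_modules,
    qc_module,
)
from synopipe.synthdata import SimulationConfig, generate_expression

PARAMS = NetworkParams(power=2.0, min_module_size=3)


def tom_oracle(corr, beta):
    """Direct evaluation of the TOM formula for a small matrix."""
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    n = len(a)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def test_affine_duplicate_genes_have_unit_adjacency_and_tom():
    x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
    X = np.vstack([x, 2 * x + 3, -x + 1])
    tom = build_tom(make_bundle(X), PARAMS)
    assert tom.iloc[0, 1] == pytest.approx(1.0)
    assert tom.iloc[0, 2] == pytest.approx(1.0)  # unsigned network


def test_three_gene_tom_matches_formula_oracle(rng):
    # construct genes with controlled pairwise correlations
    X = rng.normal(0, 1, size=(3, 40))
    tom = build_tom(make_bundle(X), PARAMS)
    corr = np.corrcoef(X)
    expected = tom_oracle(corr, 2.0)
    assert np.allclose(tom.to_numpy(), expected, atol=1e-12)
    # symmetry, unit diagonal, range
    T = tom.to_numpy()
    assert np.allclose(T, T.T)
    assert np.allclose(np.diag(T), 1.0)
    assert (T >= 0).all() and (T <= 1).all()


def test_independent_genes_have_negligible_tom(rng):
    X = rng.normal(0, 1, size=(60, 20))
    tom = build_tom(make_bundle(X), NetworkParams(power=30.0, min_module_size=3))
    off = tom.to_numpy()[~np.eye(60, dtype=bool)]
    assert np.quantile(off, 0.99) < 0.05


def test_zero_variance_gene_rejected():
    X = np.vstack([np.ones(6), np.arange(6.0)])
    with pytest.raises(ValueError, match="zero-variance"):
        build_tom(make_bundle(X), PARAMS)


def test_two_separable_blocks_recovered_exactly():
    cfg = SimulationConfig(
        n_genes=240, n_signal_genes=0, n_modules=2, module_size=120,
        n_samples_per_cohort=(10, 10), factor_noise_sd=0.0, seed=4,
    )
    b = generate_expression(cfg)
    params = NetworkParams(power=30.0, min_module_size=100)
    modules = detect_modules(build_tom(b, params), params, bundle=b)
    truth = b.ground_truth.module_members
    got = {m: set(modules.members(m)) for m in modules.module_names}
    assert len(got) == 2
    assert set(map(frozenset, got.values())) == set(
        frozenset(v) for v in truth.values()
    )


def test_min_size_above_gene_count_gives_all_grey(rng):
    X = rng.normal(0, 1, size=(30, 10))
    params = NetworkParams(power=6.0, min_module_size=100)
    with pytest.warns(UserWarning):
        modules = detect_modules(build_tom(make_bundle(X), params), params)
    assert (modules.labels == "grey").all()


def test_module_detection_invariant_to_gene_order(rng):
    cfg = SimulationConfig(
        n_genes=260, n_signal_genes=0, n_modules=2, module_size=100,
        n_samples_per_cohort=(8, 8), factor_noise_sd=0.3, seed=9,
    )
    b = generate_expression(cfg)
    params = NetworkParams(power=12.0, min_module_size=80)
    ms1 = detect_modules(build_tom(b, params), params, bundle=b)
    perm = rng.permutation(b.n_genes)
    b2 = b.subset_genes([b.genes[i] for i in perm])
    ms2 = detect_modules(build_tom(b2, params), params, bundle=b2)
    aligned = ms2.labels.reindex(ms1.labels.index)
    # same partition up to label names
    table = pd.crosstab(ms1.labels, aligned)
    assert (table.astype(bool).sum(axis=1) == 1).all()


def test_eigengene_matches_svd_oracle_and_sign_convention(rng):
    f = rng.normal(0, 1, 12)
    X = 0.9 * f[None, :] + rng.normal(0, 0.3, size=(8, 12))
    b = make_bundle(X)
    labels = pd.Series("turquoise", index=b.genes)
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    Xs = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    expected = vt[0] if vt[0] @ Xs.mean(0) > 0 else -vt[0]
    assert np.allclose(np.abs(ms.me["turquoise"]), np.abs(expected), atol=1e-10)
    assert float(np.corrcoef(ms.me["turquoise"], Xs.mean(0))[0, 1]) > 0
    assert np.linalg.norm(ms.me["turquoise"]) == pytest.approx(1.0)
    assert ms.explained_variance["turquoise"] == pytest.approx(
        s[0] ** 2 / (s**2).sum(), abs=1e-10
    )


def test_identical_gene_module_has_unit_kme(rng):
    x = rng.normal(0, 1, 10)
    X = np.vstack([x, x, x, rng.normal(0, 1, 10)])
    b = make_bundle(X)
    labels = pd.Series(["blue", "blue", "blue", "grey"], index=b.genes)
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    assert np.allclose(ms.kme.loc[["g0", "g1", "g2"], "blue"], 1.0)


def test_anticorrelated_two_gene_module_symmetric_kme(rng):
    x = rng.normal(0, 1, 10)
    X = np.vstack([x, -x + 0.1])
    b = make_bundle(X)
    labels = pd.Series(["blue", "blue"], index=b.genes)
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    k = ms.kme["blue"]
    assert abs(k["g0"]) == pytest.approx(abs(k["g1"]), abs=1e-10)


def test_merge_modules_follows_eigengene_correlation(rng):
    f1 = rng.normal(0, 1, 16)
    f2 = 0.97 * f1 + 0.16 * rng.normal(0, 1, 16)  # cor ~ 0.97 -> merge
    f3 = rng.normal(0, 1, 16)                      # independent -> keep
    blocks = [f1, f2, f3]
    X = np.vstack(
        [fk[None, :] + rng.normal(0, 0.05, size=(6, 16)) for fk in blocks]
    )
    b = make_bundle(X)
    labels = pd.Series(
        ["turquoise"] * 6 + ["blue"] * 6 + ["brown"] * 6, index=b.genes
    )
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    cor12 = float(np.corrcoef(ms.me["turquoise"], ms.me["blue"])[0, 1])
    assert 1 - cor12 < 0.2
    merged = merge_modules(b, ms, merge_height=0.2)
    assert len(merged.module_names) == 2
    sizes = sorted(len(merged.members(m)) for m in merged.module_names)
    assert sizes == [6, 12]


def test_merge_keeps_distant_modules(rng):
    f1, f2 = rng.normal(0, 1, 16), rng.normal(0, 1, 16)
    X = np.vstack(
        [f1[None, :] + rng.normal(0, 0.05, (6, 16)),
         f2[None, :] + rng.normal(0, 0.05, (6, 16))]
    )
    b = make_bundle(X)
    labels = pd.Series(["turquoise"] * 6 + ["blue"] * 6, index=b.genes)
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    merged = merge_modules(b, ms, merge_height=0.2)
    assert len(merged.module_names) == 2


def test_trait_correlation_identity_and_textbook_oracle(rng):
    f = rng.normal(0, 1, 12)
    X = f[None, :] + rng.normal(0, 0.2, size=(6, 12))
    b = make_bundle(X)
    labels = pd.Series("turquoise", index=b.genes)
    ms = compute_eigengenes(b, ModuleSet(labels=labels))
    me = ms.me
    trait2 = rng.normal(0, 1, 12)
    clinical = pd.DataFrame(
        {"sledai": me["turquoise"].to_numpy(), "crp": trait2, "c3": np.full(12, 5.0)},
        index=me.index,
    )
    r, p, notes = correlate_traits(me, clinical)
    assert r.loc["turquoise", "sledai"] == pytest.approx(1.0)
    assert p.loc["turquoise", "sledai"] < 1e-10
    # textbook Pearson for the random trait
    x, y = me["turquoise"].to_numpy(), trait2
    manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r.loc["turquoise", "crp"] == pytest.approx(manual, abs=1e-12)
    assert "c3" in notes and "constant" in notes["c3"]
    assert np.isnan(r.loc["turquoise", "c3"])


def test_independent_trait_rarely_strong(rng):
    hits = 0
    n = 400
    for _ in range(n):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0, 1, 8)
        r = np.corrcoef(x, y)[0, 1]
        hits += abs(r) > 0.5
    # |r| <= 0.5 in >= 95% of independent draws at n=8... allow slack
    assert hits / n < 0.25


def test_qc_strong_classification_boundary_inclusive(rng):
    cfg = SimulationConfig(
        n_genes=150, n_signal_genes=0, n_modules=1, module_size=100,
        n_samples_per_cohort=(10, 10), factor_noise_sd=0.3,
        trait_loadings={0: 2.0}, trait_noise_sd=0.3, seed=6,
    )
    b = generate_expression(cfg)
    params = NetworkParams(power=12.0, min_module_size=80)
    ms = detect_modules(build_tom(b, params), params, bundle=b)
    ms = compute_eigengenes(b, ms)
    clin = b.clinical.copy()
    r, p, notes = correlate_traits(ms.me, clin)
    # plant an exact boundary case
    mod = ms.module_names[0]
    r.loc[mod, "sledai"] = 0.5
    p.loc[mod, "sledai"] = 0.049
    ms.trait_cor, ms.trait_p = r, p
    qc = qc_module(mod, b, ms)
    assert qc["trait_strength"]["sledai"]["strong"] is True
    r.loc[mod, "sledai"] = 0.49
    qc = qc_module(mod, b, ms)
    assert qc["trait_strength"]["sledai"]["strong"] is False


def test_qc_concordance_for_trait_driving_module():
    cfg = SimulationConfig(
        n_genes=150, n_signal_genes=0, n_modules=1, module_size=100,
        n_samples_per_cohort=(10, 10), factor_noise_sd=0.5,
        trait_loadings={0: 2.0}, trait_noise_sd=0.3, seed=13,
    )
    b = generate_expression(cfg)
    params = NetworkParams(power=12.0, min_module_size=80)
    ms = detect_modules(build_tom(b, params), params, bundle=b)
    ms = compute_eigengenes(b, ms)
    clin = b.clinical.copy()
    ms.trait_cor, ms.trait_p, _ = correlate_traits(ms.me, clin)
    qc = qc_module(ms.module_names[0], b, ms)
    assert qc["kme_trait_concordance"] > 0.5
    assert qc["trait_strength"]["sledai"]["strong"] is True
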