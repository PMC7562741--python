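"""Per-sample gene-set enrichment via a weighted KS-like random walk.

For each gene i and sample j a kernel-smoothed expression statistic

    z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i),   h_i = s_i / 4,

locates the sample within the gene's expression distribution. Genes
are ranked per sample by z (descending) and given the symmetric rank
weight r_ij = |p/2 - rank_ij|. A random walk down the ranking adds
r^tau (normalized within the set) on set genes and subtracts
1/(p - m) on the rest; the enrichment score is the maximum positive
plus the minimum negative deviation ("diff" mode) or the single
largest-magnitude deviation ("max" mode). Scores are rank-based and
therefore invariant to per-sample monotone transforms of expression.

Cohort contrasts of the scores use Welch's t test and Hedges' g with
the small-sample correction J = 1 - 3 / (4 (n1 + n2 - 2) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionBundle

__all__ = [
    "ExpressionStatistic",
    "ScoreMatrix",
    "expression_statistic",
    "enrichment_scores",
    "compare_groups",
    "hedges_g",
]


@dataclass
class ExpressionStatistic:
    """Kernel statistic, per-sample ranks (1 = highest z) and weights."""

    zhat: pd.DataFrame      # genes x samples
    ranks: pd.DataFrame     # genes x samples, int, 1..p
    weights: pd.DataFrame   # genes x samples, |p/2 - rank|
    excluded: list[str]
    kernel: str = "gaussian"


@dataclass
class ScoreMatrix:
    scores: pd.DataFrame    # gene sets x samples
    tau: float
    mode: str


def expression_statistic(
    bundle: ExpressionBundle | pd.DataFrame, kernel: str = "gaussian", chunk: int = 4096
) -> ExpressionStatistic:
    """Per-gene expression statistic, per-sample ranks and rank weights.

    ``kernel="gaussian"`` gives the smoothed statistic
    z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i) with h_i = s_i / 4;
    ``kernel="ecdf"`` uses the mid-rank empirical CDF of the gene's
    values instead, which makes the downstream scores exactly invariant
    under monotone per-gene transforms of expression. Genes constant
    across every sample carry no ranking information and are excluded
    with a warning.
    """
    if kernel not in {"gaussian", "ecdf"}:
        raise ValueError(f"unknown kernel {kernel!r}")
    X = bundle.values if isinstance(bundle, ExpressionBundle) else bundle
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples for the kernel statistic")
    sd = X.to_numpy().std(axis=1, ddof=1)
    excluded = list(X.index[sd == 0])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} constant gene(s) from scoring")
        X = X.loc[X.index[sd > 0]]
        sd = sd[sd > 0]
    arr = X.to_numpy(dtype=float)
    p, n = arr.shape
    zhat = np.empty_like(arr)
    if kernel == "gaussian":
        h = sd / 4.0
        for start in range(0, p, chunk):
            stop = min(start + chunk, p)
            block = arr[start:stop]
            diffs = (block[:, :, None] - block[:, None, :]) / h[start:stop, None, None]
            zhat[start:stop] = stats.norm.cdf(diffs).mean(axis=2)
    else:
        # mid-rank ECDF within each gene row (ties averaged)
        for i in range(p):
            row = arr[i]
            less = (row[:, None] > row[None, :]).sum(axis=1)
            equal = (row[:, None] == row[None, :]).sum(axis=1)
            zhat[i] = (less + 0.5 * equal) / n

    # ranks per sample: 1 = largest zhat; ties broken by row order (stable)
    order = np.argsort(-zhat, axis=0, kind="stable")
    ranks = np.empty_like(order)
    for j in range(n):
        ranks[order[:, j], j] = np.arange(1, p + 1)
    weights = np.abs(p / 2.0 - ranks)
    return ExpressionStatistic(
        zhat=pd.DataFrame(zhat, index=X.index, columns=X.columns),
        ranks=pd.DataFrame(ranks, index=X.index, columns=X.columns),
        weights=pd.DataFrame(weights, index=X.index, columns=X.columns),
        excluded=excluded,
        kernel=kernel,
    )


def enrichment_scores(
    stat: ExpressionStatistic,
    gene_sets: dict[str, list[str]],
    tau: float = 1.0,
    mode: str = "diff",
) -> ScoreMatrix:
    """KS-like random-walk enrichment score per gene set and sample."""
    if mode not in {"diff", "max"}:
        raise ValueError(f"unknown score mode {mode!r}")
    genes = list(stat.ranks.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    ranks = stat.ranks.to_numpy()
    weights = stat.weights.to_numpy()
    n = ranks.shape[1]

    set_masks: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        m = len(set(idx))
        if m == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if m >= p:
            raise ValueError(f"gene set {name!r} covers the whole matrix")
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        set_masks[name] = mask

    scores = np.zeros((len(set_masks), n))
    # per sample: genes ordered by rank 1..p
    for j in range(n):
        order = np.argsort(ranks[:, j], kind="stable")
        w_col = weights[:, j][order]
        for si, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            m = int(in_set.sum())
            w_set = np.where(in_set, np.abs(w_col) ** tau, 0.0)
            total = w_set.sum()
            if total == 0:
                # degenerate: all set genes carry zero weight; uniform steps
                w_set = np.where(in_set, 1.0, 0.0)
                total = float(m)
            dec = 1.0 / (p - m)
            steps = np.where(in_set, w_set / total, -dec)
            walk = np.cumsum(steps)
            v_max = float(walk.max())
            v_min = float(walk.min())
            if mode == "diff":
                scores[si, j] = max(v_max, 0.0) + min(v_min, 0.0)
            else:
                scores[si, j] = v_max if abs(v_max) >= abs(v_min) else v_min
    return ScoreMatrix(
        scores=pd.DataFrame(scores, index=list(set_masks), columns=stat.ranks.columns),
        tau=tau,
        mode=mode,
    )


def hedges_g(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Hedges' g (x vs y) with small-sample correction; returns (g, J)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    s_pooled = np.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    )
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    diff = x.mean() - y.mean()
    if s_pooled == 0:
        g = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        g = J * diff / s_pooled
    return float(g), float(J)


def compare_groups(
    score_matrix: ScoreMatrix, cohort: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t and Hedges' g per gene set between cohorts (1 minus 0)."""
    scores = score_matrix.scores
    cohort = cohort.reindex(scores.columns)
    case = scores.columns[cohort == 1]
    ctrl = scores.columns[cohort == 0]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each cohort needs >= 2 samples for the contrast")
    rows = []
    for name in scores.index:
        x = scores.loc[name, case].to_numpy(dtype=float)
        y = scores.loc[name, ctrl].to_numpy(dtype=float)
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            if x.mean() == y.mean():
                t, pval, df = 0.0, 1.0, float(len(x) + len(y) - 2)
            else:
                t, pval, df = np.sign(x.mean() - y.mean()) * np.inf, 0.0, float("nan")
        else:
            t, pval = stats.ttest_ind(x, y, equal_var=False)
            v1, v2 = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
            df = (v1 + v2) ** 2 / (
                v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1)
            ) if (v1 + v2) > 0 else float("nan")
        g, J = hedges_g(x, y)
        rows.append(
            {
                "set": name,
                "mean_case": x.mean(),
                "mean_control": y.mean(),
                "t": float(t),
                "df": float(df),
                "p": float(pval),
                "g": g,
                "J": J,
                "significant": bool(pval < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("set")
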