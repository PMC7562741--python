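"""Empirical-Bayes moderated two-group differential expression.

The model is the standard hierarchical one for per-gene variances on a
microarray: each gene's sample variance s2_g (d_g residual df) is
shrunk toward a prior variance s0^2 with d0 prior df,

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

and the moderated t-statistic t = LFC / (s_post * sqrt(1/n1 + 1/n2))
is referred to a t distribution with d0 + d_g degrees of freedom.
When the prior is not supplied, (d0, s0^2) are estimated by closed-form
moment matching of log s2_g against the scaled-F model (mean and
variance of the log-F distribution, inverting the trigamma function).
d0 = 0 recovers the ordinary pooled two-sample t; d0 = inf gives the
z-form with the prior standard deviation.

P-values are Benjamini-Hochberg adjusted; the significance gate is a
pre-specified FDR (default 0.2). Results computed under two probe
annotation definitions can be merged, keeping the more significant
entry per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionBundle

__all__ = [
    "ModerationPrior",
    "DEResult",
    "fit_moderated",
    "adjust_bh",
    "merge_annotations",
    "estimate_prior",
]

DEFAULT_FDR = 0.2


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes hyperparameters: prior df d0 and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be nonnegative (or inf)")
        if not self.s0_sq > 0 and self.d0 > 0:
            raise ValueError("s0_sq must be positive when d0 > 0")


@dataclass
class DEResult:
    """Per-gene differential expression table.

    Columns: gene, lfc, s2, df_resid, s2_post, t, df_total, p, q,
    significant, source, and error (True where the statistic is
    undefined, e.g. zero variance with d0 = 0).
    """

    table: pd.DataFrame
    prior: ModerationPrior
    fdr: float
    source: str


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Moment-match (d0, s0^2) from observed gene variances.

    Under the scaled-F model, e_g = log s2_g has
    mean  log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and variance trigamma(d/2) + trigamma(d0/2); both moments are
    matched in closed form, inverting the trigamma for d0.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least two positive gene variances to fit the prior")
    e = np.log(s2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    emean = float(np.mean(e))
    base = emean - float(special.polygamma(0, df / 2.0)) + np.log(df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar / 1.0)
        s0_sq = float(np.exp(base + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(base))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def fit_moderated(
    bundle: ExpressionBundle,
    prior: ModerationPrior | None = None,
    fdr: float = DEFAULT_FDR,
    source: str = "A",
) -> DEResult:
    """Two-group moderated differential expression (case minus control)."""
    case = bundle.case_samples
    ctrl = bundle.control_samples
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each cohort needs >= 2 samples (got {n1} vs {n2})")
    X1 = bundle.values[case].to_numpy()
    X2 = bundle.values[ctrl].to_numpy()
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    lfc = m1 - m2
    df_resid = float(n1 + n2 - 2)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior is None:
        prior = estimate_prior(s2, df_resid)
    d0, s0_sq = prior.d0, prior.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    error = s2_post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * se_factor)
    t = np.where(error, np.nan, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(error, np.nan, p)

    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = adjust_bh(p[ok])
    significant = (q < fdr) & ok

    table = pd.DataFrame(
        {
            "gene": bundle.genes,
            "lfc": lfc,
            "s2": s2,
            "df_resid": df_resid,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "significant": significant,
            "source": source,
            "error": error,
        }
    )
    return DEResult(table=table, prior=prior, fdr=fdr, source=source)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def merge_annotations(res_a: DEResult, res_b: DEResult) -> tuple[DEResult, pd.DataFrame]:
    """Merge per-gene results from two annotation definitions.

    For genes present in both, the entry with the smaller p wins (ties:
    smaller q, then source order A before B). Significance is
    re-evaluated per kept entry against the gate; q-values are NOT
    recomputed on the merged list. Genes whose two entries disagree on
    the sign of the fold change are kept but reported in the
    discordance table.
    """
    a = res_a.table.assign(_rank=0)
    b = res_b.table.assign(_rank=1)
    both = pd.concat([a, b], ignore_index=True)
    both = both.sort_values(["gene", "p", "q", "_rank"], kind="mergesort")
    kept = both.groupby("gene", sort=True).head(1).drop(columns="_rank").reset_index(drop=True)

    in_both = set(res_a.table["gene"]) & set(res_b.table["gene"])
    disc_rows = []
    if in_both:
        av = res_a.table.set_index("gene")
        bv = res_b.table.set_index("gene")
        for g in sorted(in_both):
            la, lb = av.at[g, "lfc"], bv.at[g, "lfc"]
            if np.sign(la) * np.sign(lb) < 0:
                disc_rows.append({"gene": g, "lfc_a": la, "lfc_b": lb})
    discordance = pd.DataFrame(disc_rows, columns=["gene", "lfc_a", "lfc_b"])

    gate = res_a.fdr
    kept["significant"] = (kept["q"] < gate) & kept["q"].notna()
    merged = DEResult(table=kept, prior=res_a.prior, fdr=gate, source="merged")
    return merged, discordance
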