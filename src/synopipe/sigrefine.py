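"""Two-pass Spearman co-expression refinement of literature signatures.

A literature-derived gene signature (possibly from another species,
mapped through a user-supplied ortholog table) is trimmed to its
co-expressed core in the dataset at hand:

pass 1 keeps a gene when it correlates significantly (two-sided
p < alpha, Spearman) with at least a fraction f of the *other* original
signature genes; pass 2 keeps a gene when its Spearman rho is positive
with at least the fraction f of the other pass-1 survivors. Defaults
are f = 0.25 and alpha = 0.05. The fractional threshold uses the
ceiling and excludes self-correlation; the refined set is always a
subset of the input and every per-gene count is recorded in an audit
trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionBundle

__all__ = [
    "SignatureRefinementParams",
    "RefinedSignature",
    "RefinementError",
    "spearman_matrix",
    "refine_signature",
    "map_orthologs",
]


@dataclass(frozen=True)
class SignatureRefinementParams:
    fraction: float = 0.25
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


class RefinementError(ValueError):
    def __init__(self, message: str, audit: dict | None = None):
        super().__init__(message)
        self.audit = audit or {}


@dataclass
class RefinedSignature:
    genes: list[str]
    audit: dict = field(default_factory=dict)


def spearman_matrix(
    bundle: ExpressionBundle, genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pairwise Spearman rho and two-sided p over all samples.

    Genes absent from the matrix are dropped (reported); constant genes
    yield NA correlations (reported).
    """
    if bundle.n_samples < 4:
        raise ValueError("need >= 4 samples for Spearman correlation")
    present = [g for g in genes if g in bundle.values.index]
    dropped = [g for g in genes if g not in bundle.values.index]
    if len(present) < 2:
        raise ValueError("fewer than two signature genes present in the matrix")
    X = bundle.values.loc[present].to_numpy(dtype=float)
    constant = [g for g, row in zip(present, X) if np.all(row == row[0])]
    rho, p = stats.spearmanr(X.T)
    if np.ndim(rho) == 0:  # spearmanr collapses for 2 genes
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    rho_df = pd.DataFrame(rho, index=present, columns=present)
    p_df = pd.DataFrame(p, index=present, columns=present)
    notes = {"dropped_missing": dropped, "constant_genes": constant}
    return rho_df, p_df, notes


def refine_signature(
    bundle: ExpressionBundle,
    signature: list[str],
    params: SignatureRefinementParams | None = None,
) -> RefinedSignature:
    """Apply the two-pass co-expression refinement to a signature."""
    params = params or SignatureRefinementParams()
    rho, p, notes = spearman_matrix(bundle, signature)
    present = list(rho.index)
    if len(present) < 4:
        raise RefinementError(
            f"signature has only {len(present)} genes in the matrix (need >= 4)",
            audit=notes,
        )

    # pass 1: significant correlation with >= ceil(f * (m - 1)) other originals
    m = len(present)
    need1 = math.ceil(params.fraction * (m - 1))
    pvals = p.to_numpy().copy()
    np.fill_diagonal(pvals, np.nan)
    sig_counts = np.nansum(pvals < params.alpha, axis=1).astype(int)
    pass1 = [g for g, cnt in zip(present, sig_counts) if cnt >= need1]
    audit = {
        **notes,
        "n_input": len(signature),
        "n_present": m,
        "pass1_required": need1,
        "pass1_counts": dict(zip(present, map(int, sig_counts))),
        "pass1_kept": pass1,
    }
    if not pass1:
        raise RefinementError("pass 1 removed every gene", audit=audit)

    # pass 2: positive rho with >= ceil(f * (|pass1| - 1)) other pass-1 genes
    m2 = len(pass1)
    need2 = math.ceil(params.fraction * (m2 - 1))
    rho1 = rho.loc[pass1, pass1].to_numpy().copy()
    np.fill_diagonal(rho1, np.nan)
    pos_counts = np.nansum(rho1 > 0, axis=1).astype(int)
    refined = [g for g, cnt in zip(pass1, pos_counts) if cnt >= need2]
    audit.update(
        {
            "pass2_required": need2,
            "pass2_counts": dict(zip(pass1, map(int, pos_counts))),
            "pass2_kept": refined,
        }
    )
    return RefinedSignature(genes=refined, audit=audit)


def map_orthologs(
    signature: list[str], ortholog_table: pd.DataFrame
) -> tuple[list[str], dict]:
    """Map signature symbols through a two-column (source, target) table.

    One-to-many mappings expand to every target; unmapped symbols are
    reported, never silently dropped.
    """
    if ortholog_table is None or len(ortholog_table) == 0:
        raise ValueError("empty ortholog table")
    if ortholog_table.shape[1] < 2:
        raise ValueError("ortholog table needs (source, target) columns")
    src = ortholog_table.iloc[:, 0].astype(str)
    tgt = ortholog_table.iloc[:, 1].astype(str)
    lookup: dict[str, list[str]] = {}
    for s, t in zip(src, tgt):
        lookup.setdefault(s, []).append(t)
    mapped: list[str] = []
    unmapped: list[str] = []
    expansions: dict[str, list[str]] = {}
    for g in signature:
        targets = lookup.get(g)
        if not targets:
            unmapped.append(g)
            continue
        uniq = list(dict.fromkeys(targets))
        if len(uniq) > 1:
            expansions[g] = uniq
        for t in uniq:
            if t not in mapped:
                mapped.append(t)
    report = {"unmapped": unmapped, "expansions": expansions}
    return mapped, report
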