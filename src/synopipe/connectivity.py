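"""Connectivity-score filtering and drug-target summarization.

Inputs are perturbagen connectivity scores in [-100, 100] (-100 = a
transcriptional program perfectly opposing the query disease
signature). Compounds and knock-downs are admitted in the
[-100, -75] range and overexpression perturbations in [50, 100]
(boundaries inclusive). Targets whose agonists and antagonists act on
the same side of zero are excluded as direction-inconsistent. Each
surviving target with at least two compounds is summarized by count,
score range, mean +/- SEM (sample sd, n-1, over sqrt(n)) and its most
negative ("top") compound; knock-down/overexpression rows are ranked
by absolute score into a biological-upstream-regulator (BUR) list.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "TargetSummary",
    "validate_connectivity",
    "filter_connectivity",
    "check_direction_consistency",
    "summarize_targets",
    "rank_regulators",
    "format_target_table",
    "round_half_even",
]

PERTURBATION_TYPES = ("compound", "KD", "OE")
COLUMNS = ("perturbagen", "type", "score", "target", "moa_direction")

COMPOUND_RANGE = (-100.0, -75.0)
KD_RANGE = (-100.0, -75.0)
OE_RANGE = (50.0, 100.0)


@dataclass
class TargetSummary:
    target: str
    n: int
    score_min: float
    score_max: float
    mean: float
    sem: float
    top_compound: str
    flags: tuple[str, ...] = ()


def validate_connectivity(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a connectivity table."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"connectivity table missing columns: {missing}")
    out = table.copy()
    bad_type = ~out["type"].isin(PERTURBATION_TYPES)
    if bad_type.any():
        raise ValueError(f"unknown perturbation type(s): {sorted(out.loc[bad_type, 'type'].unique())}")
    scores = pd.to_numeric(out["score"], errors="coerce")
    if scores.isna().any():
        raise ValueError("non-numeric connectivity score present")
    if (scores < -100).any() or (scores > 100).any():
        raise ValueError("connectivity scores must lie in [-100, 100]")
    out["score"] = scores
    out["moa_direction"] = out["moa_direction"].where(
        out["moa_direction"].isin(["agonist", "antagonist"]), other=pd.NA
    )
    return out


def filter_connectivity(
    table: pd.DataFrame,
    compound_range: tuple[float, float] = COMPOUND_RANGE,
    kd_range: tuple[float, float] = KD_RANGE,
    oe_range: tuple[float, float] = OE_RANGE,
) -> pd.DataFrame:
    """Keep rows whose score falls in the admitted range for their type
    (boundaries inclusive)."""
    table = validate_connectivity(table)
    ranges = {"compound": compound_range, "KD": kd_range, "OE": oe_range}
    keep = pd.Series(False, index=table.index)
    for ptype, (lo, hi) in ranges.items():
        mask = table["type"] == ptype
        keep |= mask & (table["score"] >= lo) & (table["score"] <= hi)
    return table.loc[keep].reset_index(drop=True)


def check_direction_consistency(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-target agonist/antagonist direction check.

    A target fails when both its agonist and antagonist score sets are
    non-empty and all of them lie on the same side of zero; a target
    with only one direction (or none annotated) passes vacuously.
    """
    rows = []
    for target, grp in filtered.dropna(subset=["target"]).groupby("target", sort=True):
        directions = grp["moa_direction"]
        n_na = int(directions.isna().sum())
        agonist = grp.loc[directions == "agonist", "score"]
        antagonist = grp.loc[directions == "antagonist", "score"]
        note = ""
        if n_na:
            note = f"{n_na} row(s) without direction annotation skipped"
        if len(agonist) == 0 or len(antagonist) == 0:
            passed = True
            if len(agonist) == 0 and len(antagonist) == 0:
                note = (note + "; " if note else "") + "no direction annotations"
            else:
                note = (note + "; " if note else "") + "single direction only (vacuous pass)"
        else:
            signs = set(np.sign(agonist)) | set(np.sign(antagonist))
            passed = not (signs == {1.0} or signs == {-1.0})
        rows.append({"target": target, "passed": passed, "note": note})
    return pd.DataFrame(rows, columns=["target", "passed", "note"])


def summarize_targets(
    filtered: pd.DataFrame,
    min_count: int = 2,
    require_direction_consistency: bool = True,
) -> list[TargetSummary]:
    """Per-target compound summaries, sorted by ascending mean score."""
    if len(filtered) == 0:
        return []
    filtered = validate_connectivity(filtered)
    compounds = filtered[(filtered["type"] == "compound") & filtered["target"].notna()]
    if require_direction_consistency and len(compounds):
        consistency = check_direction_consistency(filtered)
        failed = set(consistency.loc[~consistency["passed"], "target"])
    else:
        failed = set()
    summaries: list[TargetSummary] = []
    for target, grp in compounds.groupby("target", sort=True):
        if target in failed:
            continue
        n = len(grp)
        if n < min_count:
            continue
        scores = grp["score"].to_numpy(dtype=float)
        sem = float(np.std(scores, ddof=1) / np.sqrt(n))
        # top compound = most negative score; ties go to the first id
        top = grp.sort_values(["score", "perturbagen"]).iloc[0]["perturbagen"]
        summaries.append(
            TargetSummary(
                target=target,
                n=n,
                score_min=float(scores.min()),
                score_max=float(scores.max()),
                mean=float(scores.mean()),
                sem=sem,
                top_compound=str(top),
            )
        )
    summaries.sort(key=lambda s: (s.mean, s.target))
    return summaries


def rank_regulators(filtered: pd.DataFrame, top_n: int = 50) -> pd.DataFrame:
    """Rank knock-down/overexpression rows by |score| into a BUR list.

    KD and OE evidence for the same gene stay separate lines; ties
    break on (target, type, perturbagen) for reproducibility.
    """
    if len(filtered) == 0:
        return pd.DataFrame(columns=["target", "type", "perturbagen", "score", "abs_score"])
    filtered = validate_connectivity(filtered)
    rows = filtered[filtered["type"].isin(["KD", "OE"])].copy()
    if len(rows) == 0:
        return pd.DataFrame(columns=["target", "type", "perturbagen", "score", "abs_score"])
    rows["abs_score"] = rows["score"].abs()
    rows["target"] = rows["target"].fillna(rows["perturbagen"])
    rows = rows.sort_values(
        ["abs_score", "target", "type", "perturbagen"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    out = rows.head(top_n)[["target", "type", "perturbagen", "score", "abs_score"]]
    return out.reset_index(drop=True)


def round_half_even(value: float, ndigits: int = 2) -> float:
    """Banker's rounding on the decimal value the float represents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(float(value), 10))).quantize(q, rounding=ROUND_HALF_EVEN))


def format_target_table(summaries: list[TargetSummary]) -> pd.DataFrame:
    """Report-style table: count, printed range, mean +/- SEM (2 dp)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "target": s.target,
                "count": s.n,
                "range": f"({round_half_even(s.score_max):.2f})–({round_half_even(s.score_min):.2f})",
                "mean": round_half_even(s.mean),
                "sem": round_half_even(s.sem),
                "top_drug": s.top_compound,
            }
        )
    return pd.DataFrame(rows, columns=["target", "count", "range", "mean", "sem", "top_drug"])
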