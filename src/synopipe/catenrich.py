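"""Fisher-exact over-representation of gene lists in category taxonomies.

Each category yields a 2x2 table against a gene universe:

    a = |list & category|      b = |list \\ category|
    c = |category \\ list|      d = |universe \\ (list | category)|

The right-sided p-value is the hypergeometric upper tail P(X >= a);
the reported effect is the sample odds ratio ad/(bc). The 95% CI uses
the Woolf log method, falling back to the Haldane-Anscombe 0.5
correction (CI only) when a cell is empty. An empty overlap (a = 0) is
reported as OR = 0 with a "plot-upper-bound" flag, the convention used
for forest plots where such categories are drawn at the CI upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneCategoryTaxonomy",
    "EnrichmentRecord",
    "fisher_enrichment",
    "enrich_all",
    "records_to_frame",
]


@dataclass
class GeneCategoryTaxonomy:
    """A named collection of (possibly overlapping) gene categories."""

    name: str
    categories: dict[str, list[str]]
    universe_policy: str = "filtered-genes"

    def __post_init__(self) -> None:
        for cat, genes in self.categories.items():
            if len(genes) == 0:
                raise ValueError(f"category {cat!r} is empty")
            if len(set(genes)) != len(genes):
                self.categories[cat] = list(dict.fromkeys(genes))

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.categories.values():
            out.update(genes)
        return out


@dataclass
class EnrichmentRecord:
    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    direction: str
    significant: bool
    flags: tuple[str, ...] = field(default_factory=tuple)


def _right_tail(a: int, n_list: int, k_cat: int, n_universe: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=universe, K=category, n=list).

    Summing pmf terms directly keeps the extreme tails accurate.
    """
    upper = min(k_cat, n_list)
    if a <= 0:
        return 1.0
    xs = np.arange(a, upper + 1)
    if xs.size == 0:
        return 0.0
    return float(np.sum(stats.hypergeom.pmf(xs, n_universe, k_cat, n_list)))


def fisher_enrichment(
    gene_list: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    category_name: str = "",
) -> EnrichmentRecord:
    """Right-sided Fisher exact enrichment of ``gene_list`` in ``category``."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    list_set = set(gene_list)
    if not list_set:
        raise ValueError("empty gene list")
    outside = list_set - universe_set
    if outside:
        raise ValueError(f"gene list not contained in universe: {sorted(outside)[:5]}")
    cat_set = set(category) & universe_set
    if not cat_set:
        raise ValueError(f"category {category_name!r} disjoint from universe")

    a = len(list_set & cat_set)
    b = len(list_set - cat_set)
    c = len(cat_set - list_set)
    d = len(universe_set) - a - b - c

    p = _right_tail(a, len(list_set), len(cat_set), len(universe_set))

    flags: list[str] = []
    if a == 0:
        odds = 0.0
        flags.append("plot-upper-bound")
    elif b == 0 or c == 0:
        odds = math.inf
        flags.append("infinite-or")
    else:
        odds = (a * d) / (b * c)

    # Woolf log CI; Haldane-Anscombe 0.5 on every cell when any is zero
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("haldane-ci")
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(1 - 0.025)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)

    direction = "increased" if odds > 1 else "decreased"
    significant = (p < alpha) and (ci_low > 1.0 or ci_high < 1.0)
    return EnrichmentRecord(
        category=category_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        direction=direction,
        significant=significant,
        flags=tuple(flags),
    )


def enrich_all(
    gene_list: Iterable[str],
    taxonomy: GeneCategoryTaxonomy | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Enrichment record per category, sorted by ascending p.

    Per-category failures (e.g. a category disjoint from the universe)
    are returned as flagged records rather than raised, so one bad
    category does not sink the rest of the taxonomy.
    """
    cats = taxonomy.categories if isinstance(taxonomy, GeneCategoryTaxonomy) else dict(taxonomy)
    gene_list = list(gene_list)
    universe = list(universe)
    records: list[EnrichmentRecord] = []
    for cat_name in cats:
        try:
            rec = fisher_enrichment(
                gene_list, cats[cat_name], universe, alpha=alpha, category_name=cat_name
            )
        except ValueError as exc:
            rec = EnrichmentRecord(
                category=cat_name,
                a=0,
                b=0,
                c=0,
                d=0,
                odds_ratio=math.nan,
                ci_low=math.nan,
                ci_high=math.nan,
                p=math.nan,
                direction="na",
                significant=False,
                flags=(f"error: {exc}",),
            )
        records.append(rec)
    records.sort(key=lambda r: (math.isnan(r.p), r.p, r.category))
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular (CSV-ready) form of enrichment records.

    ``log2_or`` supports forest plots on a log2 axis; records flagged
    "plot-upper-bound" should be drawn at the CI upper bound.
    """
    rows = []
    for r in records:
        with np.errstate(divide="ignore"):
            log2_or = float(np.log2(r.odds_ratio)) if r.odds_ratio > 0 else -math.inf
        rows.append(
            {
                "category": r.category,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "direction": r.direction,
                "significant": r.significant,
                "log2_or": log2_or,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
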