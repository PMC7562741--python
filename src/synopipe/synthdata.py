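"""Synthetic data with the statistical structure of a two-cohort
synovial microarray immunoprofiling study.

The generator emulates (i) a log2 expression matrix over two small
cohorts (case = 1, control = 0) with planted cohort fold changes on a
block of "signal" genes, (ii) latent-factor co-expression modules whose
factors drive clinical traits (so module-trait correlations have known
targets), (iii) cell/function gene-category taxonomies with an
optional category planted to be enriched among the signal genes at a
configured odds ratio, and (iv) a perturbagen connectivity-score table
with planted drug-target groups, range decoys and a
direction-inconsistent pair. Every quantity the generator plants is
recorded in a :class:`GroundTruth` so downstream stages can be tested
for recovery.

Noise is independent Gaussian on the log2 scale (baseline sd 1.5
across genes, residual sd 0.5 within genes), the simplest model
consistent with log2 microarray intensities. A fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import CLINICAL_TRAITS, ExpressionBundle, write_gmt
from .catenrich import GeneCategoryTaxonomy

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedTarget",
    "generate_expression",
    "generate_taxonomy",
    "generate_connectivity_table",
    "write_ground_truth",
    "DEFAULT_PLANTED_TARGETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated design: ~20,000 genes, two cohorts of
    four samples, several hundred signal genes with log2 fold changes
    up to a few units, and latent-factor modules tied to clinical
    traits.
    """

    n_genes: int = 20000
    n_samples_per_cohort: tuple[int, int] = (4, 4)
    n_signal_genes: int = 500
    lfc_range: tuple[float, float] = (0.5, 2.5)
    down_fraction: float = 0.5
    n_modules: int = 5
    module_size: int = 200
    factor_noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    residual_sd: float = 0.5
    trait_loadings: dict | None = None  # module index -> coefficient on SLEDAI
    trait_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n1, n2 = self.n_samples_per_cohort
        if n1 < 2 or n2 < 2:
            raise ValueError("each cohort needs >= 2 samples")
        if self.n_signal_genes + self.n_modules * self.module_size > self.n_genes:
            raise ValueError("signal genes plus module genes exceed the gene count")
        lo, hi = self.lfc_range
        if not (0.0 <= lo <= hi <= 5.0):
            raise ValueError("lfc_range must satisfy 0 <= lo <= hi <= 5")
        if hi > 0 and lo < 0.25 and lo != 0.0:
            raise ValueError("nonzero minimum |LFC| must be >= 0.25")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ValueError("down_fraction must lie in [0, 1]")
        if self.factor_noise_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        for m in self.trait_loadings or {}:
            if not 0 <= int(m) < max(self.n_modules, 1):
                raise ValueError(f"trait loading refers to unknown module {m}")

    def resolved_trait_loadings(self) -> dict[int, float]:
        """SLEDAI loadings; the default ties the first two modules to it."""
        if self.trait_loadings is not None:
            return {int(m): float(c) for m, c in self.trait_loadings.items()}
        defaults = {0: 1.5, 1: -1.0}
        return {m: c for m, c in defaults.items() if m < self.n_modules}

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        n1, n2 = self.n_samples_per_cohort
        return (
            [f"SLE{i + 1}" for i in range(n1)],
            [f"OA{i + 1}" for i in range(n2)],
        )


@dataclass
class PlantedTarget:
    target: str
    scores: list[float]
    perturbagens: list[str] | None = None
    ptype: str = "compound"
    moa_direction: str = "antagonist"


#: Two-compound groups whose printed summary statistics are exact at
#: two decimals; used as the generator's default planted targets.
DEFAULT_PLANTED_TARGETS = (
    PlantedTarget("Cholinesterase", [-88.16, -93.36], ["mestinon", "isoflurophate"]),
    PlantedTarget("mTORC1/2", [-88.13, -91.07], ["sirolimus", "n-acetyl-cysteine"]),
)


@dataclass
class GroundTruth:
    signal_genes: dict[str, float] = field(default_factory=dict)  # gene -> true LFC
    module_members: dict[str, list[str]] = field(default_factory=dict)
    factors: pd.DataFrame | None = None                            # samples x modules
    trait_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_category: dict | None = None
    planted_targets: list[dict] = field(default_factory=list)

    def validate(self, gene_ids: set[str]) -> None:
        missing = [g for g in self.signal_genes if g not in gene_ids]
        for members in self.module_members.values():
            missing += [g for g in members if g not in gene_ids]
        if missing:
            raise ValueError(f"planted gene ids not in matrix: {missing[:5]}")
        seen: set[str] = set()
        for members in self.module_members.values():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"module memberships overlap: {sorted(overlap)[:5]}")
            seen.update(members)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_expression(config: SimulationConfig) -> ExpressionBundle:
    """Simulate the expression matrix, clinical table and ground truth."""
    rng = _rng(config, 0)
    genes = config.gene_ids()
    case_ids, ctrl_ids = config.sample_ids()
    samples = case_ids + ctrl_ids
    n1, n2 = len(case_ids), len(ctrl_ids)
    n = n1 + n2
    p = config.n_genes

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    X = baseline[:, None] + rng.normal(0.0, config.residual_sd, size=(p, n))

    # planted cohort fold changes on the signal block
    lo, hi = config.lfc_range
    magnitudes = rng.uniform(lo, hi, size=config.n_signal_genes)
    signs = np.where(
        rng.random(config.n_signal_genes) < config.down_fraction, -1.0, 1.0
    )
    lfcs = magnitudes * signs
    X[: config.n_signal_genes, :n1] += lfcs[:, None]

    # latent-factor modules: member expression is baseline + loading x
    # factor + factor noise (replacing, not stacking on, the residual)
    factors = rng.normal(0.0, 1.0, size=(n, config.n_modules))
    module_members: dict[str, list[str]] = {}
    start = config.n_signal_genes
    for m in range(config.n_modules):
        rows = slice(start, start + config.module_size)
        loadings = rng.uniform(0.6, 1.0, size=config.module_size)
        X[rows] = (
            baseline[rows, None]
            + loadings[:, None] * factors[:, m][None, :]
            + rng.normal(0.0, config.factor_noise_sd, size=(config.module_size, n))
        )
        module_members[f"M{m + 1}"] = genes[start : start + config.module_size]
        start += config.module_size

    cohort = pd.Series([1] * n1 + [0] * n2, index=samples)

    # clinical traits as linear functions of latent factors
    trait_coefficients: dict[str, dict[str, float]] = {}
    base_scale = {
        "sledai": (8.25, 1.0),
        "anti_dsdna": (97.6, 20.0),
        "c3": (82.5, 10.0),
        "c4": (13.0, 2.0),
        "crp": (12.5, 2.0),
    }
    clin = pd.DataFrame(index=samples)
    for t_idx, trait in enumerate(CLINICAL_TRAITS):
        mean, scale = base_scale[trait]
        coefs: dict[str, float] = {}
        if trait == "sledai":
            for m, coef in config.resolved_trait_loadings().items():
                coefs[f"M{int(m) + 1}"] = float(coef)
            noise_sd = config.trait_noise_sd
        else:
            if config.n_modules > 0:
                m = t_idx % config.n_modules
                coefs[f"M{m + 1}"] = float(scale) * (1.0 if t_idx % 2 else -1.0)
            noise_sd = config.trait_noise_sd * scale
        vals = np.full(n, mean, dtype=float)
        for mod, coef in coefs.items():
            vals += coef * factors[:, int(mod[1:]) - 1]
        vals += rng.normal(0.0, noise_sd, size=n)
        clin[trait] = np.clip(vals, 0.0, None)
        trait_coefficients[trait] = coefs
    clin["cohort"] = cohort.values

    truth = GroundTruth(
        signal_genes=dict(zip(genes[: config.n_signal_genes], map(float, lfcs))),
        module_members=module_members,
        factors=pd.DataFrame(
            factors, index=samples, columns=list(module_members) or None
        ),
        trait_coefficients=trait_coefficients,
    )
    truth.validate(set(genes))

    values = pd.DataFrame(X, index=genes, columns=samples)
    return ExpressionBundle(
        values=values, cohort=cohort, clinical=clin, ground_truth=truth
    )


def generate_taxonomy(
    config: SimulationConfig,
    truth: GroundTruth,
    kind: str = "cells",
    n_categories: int = 32,
    total_genes: int = 926,
    planted_or: float | None = 3.0,
    planted_size: int = 100,
) -> GeneCategoryTaxonomy:
    """Gene-category taxonomy over the simulated gene universe.

    For ``kind="cells"`` the default layout is 32 categories whose
    union holds exactly 926 genes; one category is planted to be
    enriched among the true signal genes at the configured odds ratio
    (``planted_or=None`` or 1 plants nothing). ``kind="functions"``
    yields 52 function groups, ``kind="tissue"`` two tissue-cell
    categories; neither is planted.
    """
    genes = config.gene_ids()
    n_universe = len(genes)
    rng = _rng(config, 1 + {"cells": 0, "functions": 1, "tissue": 2}[kind])

    if kind == "functions":
        cats = {}
        for i in range(52):
            size = int(rng.integers(20, 101))
            members = rng.choice(n_universe, size=size, replace=False)
            cats[f"FUNC{i + 1:02d}"] = [genes[g] for g in sorted(members)]
        return GeneCategoryTaxonomy(name="function-groups", categories=cats)
    if kind == "tissue":
        cats = {}
        for name in ("fibroblast", "synoviocyte"):
            members = rng.choice(n_universe, size=50, replace=False)
            cats[name] = [genes[g] for g in sorted(members)]
        return GeneCategoryTaxonomy(name="tissue-cells", categories=cats)
    if kind != "cells":
        raise ValueError(f"unknown taxonomy kind {kind!r}")

    if total_genes > n_universe or planted_size > n_universe:
        raise ValueError("category larger than gene universe")
    if total_genes - planted_size < n_categories - 1:
        raise ValueError("too few genes to give every category a member")

    signal = [g for g in truth.signal_genes]
    signal_idx = {g for g in signal}
    is_signal = np.array([g in signal_idx for g in genes])
    s = int(is_signal.sum())

    # planted category: biased inclusion so the sample odds ratio of
    # membership among signal genes targets planted_or
    omega = 1.0 if planted_or in (None, 0) else float(planted_or)
    p0 = planted_size / n_universe
    p1 = omega * p0 / (1.0 - p0 + omega * p0)
    draw = rng.random(n_universe)
    in_planted = np.where(is_signal, draw < p1, draw < p0)
    planted_genes = [g for g, m in zip(genes, in_planted) if m]
    if len(planted_genes) < 2:
        planted_genes = genes[:2]
    if len(planted_genes) > total_genes - (n_categories - 1):
        planted_genes = planted_genes[: total_genes - (n_categories - 1)]

    # fill the pool to exactly `total_genes`, then split the remainder
    rest_pool_size = total_genes - len(planted_genes)
    candidates = np.array([i for i, g in enumerate(genes) if g not in set(planted_genes)])
    rest_idx = rng.choice(candidates, size=rest_pool_size, replace=False)
    rest = [genes[i] for i in rest_idx]
    rng.shuffle(rest)
    chunks = np.array_split(np.array(rest, dtype=object), n_categories - 1)

    cats = {"CELL01_planted": sorted(planted_genes)}
    pool = list(planted_genes) + rest
    for i, chunk in enumerate(chunks):
        members = list(chunk)
        # allow a little overlap between categories (shared markers)
        n_extra = int(rng.integers(0, 4))
        if n_extra:
            extra = rng.choice(len(pool), size=n_extra, replace=False)
            members.extend(pool[e] for e in extra)
        cats[f"CELL{i + 2:02d}"] = sorted(set(members))

    truth.planted_category = {
        "name": "CELL01_planted",
        "genes": sorted(planted_genes),
        "target_or": None if planted_or in (None, 0) else float(planted_or),
        "n_signal_in_category": int(sum(1 for g in planted_genes if g in signal_idx)),
    }
    return GeneCategoryTaxonomy(name="cell-categories", categories=cats)


def generate_connectivity_table(
    config: SimulationConfig,
    planted_targets: tuple[PlantedTarget, ...] | list[PlantedTarget] = DEFAULT_PLANTED_TARGETS,
    truth: GroundTruth | None = None,
    n_decoys: int = 40,
    n_regulators: int = 60,
    include_inconsistent_pair: bool = True,
) -> pd.DataFrame:
    """Perturbagen connectivity table with planted target groups.

    Adds score-range decoys (including one at -74.9, just outside the
    compound window), an agonist/antagonist pair acting on the same
    side of zero (to exercise the direction-consistency exclusion) and
    knock-down/overexpression regulator rows for BUR ranking.
    """
    rng = _rng(config, 9)
    rows: list[dict] = []
    planted_records = []
    for pt in planted_targets:
        if any(abs(s) > 100 for s in pt.scores):
            raise ValueError(f"planted scores outside [-100, 100] for {pt.target!r}")
        names = pt.perturbagens or [
            f"{pt.target.lower()}-cpd{i + 1}" for i in range(len(pt.scores))
        ]
        for name, score in zip(names, pt.scores):
            rows.append(
                {
                    "perturbagen": name,
                    "type": pt.ptype,
                    "score": float(score),
                    "target": pt.target,
                    "moa_direction": pt.moa_direction,
                }
            )
        planted_records.append(
            {
                "target": pt.target,
                "scores": [float(s) for s in pt.scores],
                "true_mean": float(np.mean(pt.scores)),
            }
        )

    # decoys outside the admitted score windows
    for i in range(n_decoys):
        score = float(rng.uniform(-74.5, 45.0))
        rows.append(
            {
                "perturbagen": f"decoy{i + 1}",
                "type": "compound",
                "score": round(score, 2),
                "target": f"DecoyTarget{i % 7 + 1}",
                "moa_direction": "antagonist" if i % 2 else "agonist",
            }
        )
    rows.append(
        {
            "perturbagen": "decoy-boundary",
            "type": "compound",
            "score": -74.9,
            "target": "DecoyBoundary",
            "moa_direction": "antagonist",
        }
    )
    if include_inconsistent_pair:
        rows.append(
            {
                "perturbagen": "incons-agonist",
                "type": "compound",
                "score": -85.0,
                "target": "InconsistentTarget",
                "moa_direction": "agonist",
            }
        )
        rows.append(
            {
                "perturbagen": "incons-antagonist",
                "type": "compound",
                "score": -80.0,
                "target": "InconsistentTarget",
                "moa_direction": "antagonist",
            }
        )

    for i in range(n_regulators):
        if i % 2:
            score = float(rng.uniform(-99.9, -75.0))
            ptype = "KD"
        else:
            score = float(rng.uniform(50.0, 99.9))
            ptype = "OE"
        rows.append(
            {
                "perturbagen": f"REG{i + 1:03d}-{ptype.lower()}",
                "type": ptype,
                "score": round(score, 2),
                "target": f"REG{i + 1:03d}",
                "moa_direction": None,
            }
        )
    # out-of-range regulator decoys
    rows.append(
        {"perturbagen": "reg-decoy-kd", "type": "KD", "score": -60.0,
         "target": "REGDECOY1", "moa_direction": None}
    )
    rows.append(
        {"perturbagen": "reg-decoy-oe", "type": "OE", "score": 30.0,
         "target": "REGDECOY2", "moa_direction": None}
    )

    table = pd.DataFrame(rows, columns=["perturbagen", "type", "score", "target", "moa_direction"])
    if (table["score"].abs() > 100).any():
        raise ValueError("generated score outside [-100, 100]")
    if truth is not None:
        truth.planted_targets = planted_records
    return table


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "signal_genes": truth.signal_genes,
        "module_members": truth.module_members,
        "factors": None if truth.factors is None else truth.factors.to_dict(),
        "trait_coefficients": truth.trait_coefficients,
        "planted_category": truth.planted_category,
        "planted_targets": truth.planted_targets,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_taxonomy(taxonomy: GeneCategoryTaxonomy, path: str | Path) -> None:
    write_gmt(taxonomy.categories, path, description=taxonomy.name)
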