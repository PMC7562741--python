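"""Expression data containers, file I/O, and preprocessing.

Expression data is a log2 intensity matrix (genes in rows, samples in
columns) with a binary cohort label per sample (case = 1, control = 0)
and an optional clinical trait table. Preprocessing mirrors a standard
small-cohort microarray workflow: removal of low-intensity probes,
automated outlier-sample detection on principal components and the
UPGMA sample dendrogram, and collapse of multiple probes per gene to a
single representative row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionBundle",
    "ExpressionLoadError",
    "FilterReport",
    "OutlierReport",
    "load_expression",
    "write_expression",
    "load_clinical",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "filter_low_intensity",
    "detect_outlier_samples",
    "collapse_probes",
]

#: Clinical trait columns expected in a clinical table (all nonnegative).
CLINICAL_TRAITS = ("sledai", "anti_dsdna", "c3", "c4", "crp")


class ExpressionLoadError(ValueError):
    """Raised when an expression/clinical/gene-set file fails validation."""


@dataclass
class ExpressionBundle:
    """Log2 expression matrix plus per-sample metadata.

    Parameters
    ----------
    values:
        Genes x samples matrix of log2 intensities. Row index holds
        unique gene (or probe) ids, columns hold unique sample ids.
    cohort:
        Binary label per sample (1 = case, 0 = control), indexed by
        sample id.
    clinical:
        Optional per-sample clinical trait table (samples in rows).
    probe_map:
        Optional mapping from row id (probe) to gene symbol.
    ground_truth:
        Attached by the synthetic generator only; ignored otherwise.
    """

    values: pd.DataFrame
    cohort: pd.Series
    clinical: pd.DataFrame | None = None
    probe_map: pd.Series | None = None
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicate sample ids: {dups[:5]}")
        if v.isna().any().any():
            bad = v.columns[v.isna().any()].tolist()
            raise ExpressionLoadError(f"missing values in samples {bad[:5]}")
        self.values = v.astype(float)
        cohort = self.cohort.reindex(v.columns)
        if cohort.isna().any():
            missing = cohort.index[cohort.isna()].tolist()
            raise ExpressionLoadError(f"samples without cohort label: {missing[:5]}")
        if not set(np.unique(cohort.to_numpy())) <= {0, 1}:
            raise ExpressionLoadError("cohort labels must be binary 0/1")
        self.cohort = cohort.astype(int)
        if self.clinical is not None:
            self.clinical = _validate_clinical(self.clinical, list(v.columns))
        if self.probe_map is not None:
            pm = self.probe_map.reindex(v.index)
            if pm.isna().any():
                missing = pm.index[pm.isna()].tolist()
                raise ExpressionLoadError(f"probe map not total on rows: {missing[:5]}")
            self.probe_map = pm.astype(str)

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_samples(self) -> list[str]:
        return list(self.cohort.index[self.cohort == 1])

    @property
    def control_samples(self) -> list[str]:
        return list(self.cohort.index[self.cohort == 0])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionBundle":
        return ExpressionBundle(
            values=self.values.loc[list(genes)],
            cohort=self.cohort,
            clinical=self.clinical,
            probe_map=None if self.probe_map is None else self.probe_map.loc[list(genes)],
            ground_truth=self.ground_truth,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionBundle":
        samples = list(samples)
        return ExpressionBundle(
            values=self.values[samples],
            cohort=self.cohort.loc[samples],
            clinical=None if self.clinical is None else self.clinical.loc[samples],
            probe_map=self.probe_map,
            ground_truth=self.ground_truth,
        )


def _validate_clinical(clinical: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    missing = [s for s in samples if s not in clinical.index]
    if missing:
        raise ExpressionLoadError(f"clinical table missing samples: {missing[:5]}")
    clinical = clinical.loc[samples].copy()
    for col in clinical.columns:
        if col == "cohort":
            continue
        vals = pd.to_numeric(clinical[col], errors="coerce")
        if (vals.dropna() < 0).any():
            bad = clinical.index[vals < 0].tolist()
            raise ExpressionLoadError(f"negative clinical value in {col} for {bad[:3]}")
        clinical[col] = vals
    return clinical


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    fmt: str | None = None,
    cohort: Mapping[str, int] | pd.Series | None = None,
    clinical: pd.DataFrame | None = None,
    probe_map: pd.Series | None = None,
) -> ExpressionBundle:
    """Read a genes x samples expression table (TSV or CSV).

    The first column holds gene ids; the header row holds sample ids.
    Duplicate sample columns, duplicate gene rows, and non-numeric
    cells are rejected with an error naming the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionLoadError(f"no such file: {path}")
    sep = _infer_sep(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) < 2:
        raise ExpressionLoadError(f"malformed header in {path.name}: {header!r}")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ExpressionLoadError(f"duplicate sample column {sid!r} in {path.name}")
        seen.add(sid)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = sample_ids
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ExpressionLoadError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path.name}"
            )
        numeric[col] = converted
    if cohort is None:
        raise ExpressionLoadError("cohort labels are required to build a bundle")
    cohort = pd.Series(dict(cohort)) if not isinstance(cohort, pd.Series) else cohort
    return ExpressionBundle(
        values=numeric, cohort=cohort, clinical=clinical, probe_map=probe_map
    )


def _infer_sep(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"tsv", "csv"}:
            raise ExpressionLoadError(f"unknown format {fmt!r}")
        return "\t" if fmt == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_expression(bundle: ExpressionBundle, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, fmt)
    out = bundle.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=sep)


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical CSV (first column = sample id)."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [c.lower() for c in df.columns]
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ExpressionLoadError(f"malformed GMT line {ln}: {line!r}")
            name = parts[0]
            if name in sets:
                raise ExpressionLoadError(f"duplicate gene set {name!r} at line {ln}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ExpressionLoadError(f"empty gene set {name!r} at line {ln}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column probe -> gene TSV."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ExpressionLoadError("probe map must have exactly two columns")
    return pd.Series(df[1].values, index=df[0].values)


# ---------------------------------------------------------------------------
# Low-intensity / low-variability filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    mode: str
    cutoff: float
    n_removed: int
    removed: list[str] = field(default_factory=list)


def filter_low_intensity(
    bundle: ExpressionBundle,
    threshold: float | None = None,
    iqr_quantile: float | None = None,
) -> tuple[ExpressionBundle, FilterReport]:
    """Remove uninformative genes before downstream analysis.

    Threshold mode removes genes whose *maximum* log2 intensity stays
    below ``threshold`` (every sample below the cutoff; default 2.34 in
    the pipeline config). IQR mode removes genes whose interquartile
    range falls below the ``iqr_quantile`` quantile of all gene IQRs.
    Exactly one mode must be chosen.
    """
    if (threshold is None) == (iqr_quantile is None):
        raise ValueError("choose exactly one of threshold / iqr_quantile")
    x = bundle.values
    if threshold is not None:
        keep = x.max(axis=1) >= threshold
        cutoff = float(threshold)
        mode = "threshold"
    else:
        if not 0.0 < iqr_quantile < 1.0:
            raise ValueError("iqr_quantile must lie in (0, 1)")
        q3 = x.quantile(0.75, axis=1)
        q1 = x.quantile(0.25, axis=1)
        iqr = q3 - q1
        cutoff = float(iqr.quantile(iqr_quantile))
        keep = iqr >= cutoff
        mode = "iqr"
    removed = list(x.index[~keep])
    if not keep.any():
        raise ValueError("filter removed every gene (degenerate matrix)")
    report = FilterReport(mode=mode, cutoff=cutoff, n_removed=len(removed), removed=removed)
    if not removed:
        return bundle, report
    return bundle.subset_genes(list(x.index[keep])), report


# ---------------------------------------------------------------------------
# Outlier sample detection
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    flagged: list[str]
    pc_coords: pd.DataFrame
    centroid_distance: pd.Series
    mad: float
    pca_flag: pd.Series
    first_merge_height: pd.Series
    dendro_threshold: float
    dendro_flag: pd.Series


def detect_outlier_samples(bundle: ExpressionBundle, k: float = 3.0) -> OutlierReport:
    """Flag aberrant samples on PC1-3 distance and the UPGMA dendrogram.

    A sample is flagged when BOTH hold: its Euclidean distance from its
    cohort centroid in PC1-3 space exceeds ``k`` times the scaled MAD of
    all such distances, AND its first merge in the average-linkage
    (UPGMA) dendrogram of Euclidean sample distances happens above 1.5x
    the second-largest merge height. Both sub-criteria are reported
    separately so the automated call can be audited.
    """
    if bundle.n_samples < 4:
        raise ValueError("insufficient samples (need >= 4) for outlier detection")
    X = bundle.values.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    n_comp = min(3, min(Xc.shape) - 1) or 1
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = u[:, :3] * s[:3] if Xc.shape[1] >= 3 else u[:, :n_comp] * s[:n_comp]
    coords = coords[:, :3]
    pc = pd.DataFrame(
        coords, index=bundle.samples, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    dist = pd.Series(0.0, index=bundle.samples)
    for label in (0, 1):
        members = bundle.cohort.index[bundle.cohort == label]
        if len(members) == 0:
            continue
        sub = pc.loc[members]
        centroid = sub.mean(axis=0)
        dist.loc[members] = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
    mad = float(1.4826 * np.median(np.abs(dist - np.median(dist))))
    if math.isinf(k):
        pca_flag = pd.Series(False, index=bundle.samples)
    else:
        pca_flag = dist > k * mad if mad > 0 else dist > 0
        if mad == 0:
            # all-identical cohorts: nothing to flag
            pca_flag = pd.Series(False, index=bundle.samples)

    d = pdist(X, metric="euclidean")
    Z = linkage(d, method="average")
    n = bundle.n_samples
    first_merge = np.full(n, np.nan)
    cluster_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, h, _cnt) in enumerate(Z):
        members = cluster_members[int(a)] + cluster_members[int(b)]
        # only leaves merging for the first time get this height
        for leaf in members:
            if np.isnan(first_merge[leaf]):
                first_merge[leaf] = h
        cluster_members[n + step] = members
    heights = np.sort(Z[:, 2])
    dendro_threshold = float(1.5 * heights[-2]) if len(heights) >= 2 else float("inf")
    fm = pd.Series(first_merge, index=bundle.samples)
    dendro_flag = fm > dendro_threshold if dendro_threshold > 0 else pd.Series(False, index=bundle.samples)
    if dendro_threshold == 0:
        dendro_flag = pd.Series(False, index=bundle.samples)
    flagged = list(pc.index[(pca_flag & dendro_flag).to_numpy()])
    return OutlierReport(
        flagged=flagged,
        pc_coords=pc,
        centroid_distance=dist,
        mad=mad,
        pca_flag=pca_flag,
        first_merge_height=fm,
        dendro_threshold=dendro_threshold,
        dendro_flag=dendro_flag,
    )


# ---------------------------------------------------------------------------
# Probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(
    obj,
    probe_map: pd.Series,
    rule: str,
    module_set=None,
):
    """Collapse multiple probes per gene to one representative row.

    ``rule`` is one of:

    - ``max_mean``: keep the probe with highest mean intensity
      (expression bundles);
    - ``min_p``: keep the most significant probe (differential
      expression tables);
    - ``max_kME``: keep the probe with the strongest correlation to its
      module eigengene (requires ``module_set``).

    Ties break lexicographically on probe id so the outcome is
    reproducible.
    """
    if rule not in {"max_mean", "min_p", "max_kME"}:
        raise ValueError(f"unknown collapse rule {rule!r}")

    from .diffexpr import DEResult  # local import to avoid a cycle

    if isinstance(obj, ExpressionBundle):
        index = obj.values.index
    elif isinstance(obj, DEResult):
        index = pd.Index(obj.table["gene"])
    else:
        raise TypeError("collapse_probes expects an ExpressionBundle or DEResult")

    pm = probe_map.reindex(index)
    if pm.isna().any():
        missing = list(pm.index[pm.isna()])
        raise ValueError(f"probe map not total on rows: {missing[:5]}")

    if rule == "max_mean":
        if not isinstance(obj, ExpressionBundle):
            raise ValueError("max_mean collapse applies to expression bundles")
        score = obj.values.mean(axis=1)
        best = _argbest(pm, score, maximize=True)
        sub = obj.values.loc[best]
        sub.index = pm.loc[best].values
        return ExpressionBundle(values=sub, cohort=obj.cohort, clinical=obj.clinical)
    if rule == "min_p":
        if not isinstance(obj, DEResult):
            raise ValueError("min_p collapse applies to differential expression results")
        score = pd.Series(obj.table["p"].to_numpy(), index=index)
        best = _argbest(pm, score, maximize=False)
        keep_mask = pd.Index(obj.table["gene"]).isin(best)
        out = obj.table.loc[keep_mask].copy()
        out["probe"] = out["gene"]
        out["gene"] = pm.loc[out["probe"]].values
        return DEResult(table=out.reset_index(drop=True), prior=obj.prior, fdr=obj.fdr, source=obj.source)
    # max_kME
    if module_set is None:
        raise ValueError("max_kME collapse requires a ModuleSet")
    if not isinstance(obj, ExpressionBundle):
        raise ValueError("max_kME collapse applies to expression bundles")
    kme = module_set.kme
    labels = module_set.labels
    score = pd.Series(index=index, dtype=float)
    for probe in index:
        mod = labels.get(probe, "grey")
        if mod != "grey" and mod in kme.columns:
            score.loc[probe] = abs(kme.loc[probe, mod])
        else:
            score.loc[probe] = abs(kme.loc[probe]).max() if probe in kme.index else 0.0
    best = _argbest(pm, score, maximize=True)
    sub = obj.values.loc[best]
    sub.index = pm.loc[best].values
    return ExpressionBundle(values=sub, cohort=obj.cohort, clinical=obj.clinical)


def _argbest(pm: pd.Series, score: pd.Series, maximize: bool) -> list[str]:
    """Per gene, the winning probe id; ties go to the lexicographically first."""
    df = pd.DataFrame({"gene": pm.values, "score": score.loc[pm.index].values, "probe": pm.index})
    df = df.sort_values(["gene", "score", "probe"], ascending=[True, not maximize, True])
    winners = df.groupby("gene", sort=True).head(1)
    # preserve original row order of winners
    order = {p: i for i, p in enumerate(pm.index)}
    return sorted(winners["probe"].tolist(), key=lambda p: order[p])
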