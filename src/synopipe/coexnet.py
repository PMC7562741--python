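"""Weighted co-expression network modules (WGCNA-style).

Genes are connected by a soft-thresholded correlation adjacency
a_ij = |cor(x_i, x_j)|^beta (unsigned; a signed variant
((1+cor)/2)^beta is available). The topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

measures shared neighborhoods; 1 - TOM is the clustering
dissimilarity. Modules come from average-linkage hierarchical
clustering with a deterministic top-down tree cut (see
``detect_modules``), are summarized by module eigengenes (first
principal component of the standardized member expression), merged
when eigengenes are close, and correlated with clinical traits. The
default soft power is 30 and the default minimum module size 100,
matching a high-power microarray configuration; merge height defaults
to 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .exprio import ExpressionBundle

__all__ = [
    "NetworkParams",
    "ModuleSet",
    "build_tom",
    "detect_modules",
    "compute_eigengenes",
    "merge_modules",
    "correlate_traits",
    "qc_module",
    "MODULE_PALETTE",
]

#: Deterministic module label palette (ordered by module size).
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet",
)

GREY = "grey"


@dataclass(frozen=True)
class NetworkParams:
    power: float = 30.0
    signed: bool = False
    min_module_size: int = 100
    cut_height: float = 1.0
    merge_height: float = 0.2
    pam: bool = True
    #: Core detection: minimum drop (decades of mean TOM) between a
    #: subtree's own cohesion and its merge into the rest of the tree.
    gap_decades: float = 0.2
    #: Membership bar for the eigengene-based refinement (|kME|), the
    #: same "strong correlation" convention used for trait QC.
    kme_threshold: float = 0.5
    #: Fallback membership bar without expression data: mean TOM to the
    #: module as a fraction of the module's median member connectivity.
    trim_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("soft power must be >= 1")
        if not 0.0 < self.merge_height < 1.0:
            raise ValueError("merge height must lie in (0, 1)")
        if self.min_module_size < 3:
            raise ValueError("minimum module size must be >= 3")


@dataclass
class ModuleSet:
    """Gene -> module assignment plus derived summaries."""

    labels: pd.Series
    me: pd.DataFrame | None = None          # samples x modules
    kme: pd.DataFrame | None = None         # genes x modules
    explained_variance: pd.Series | None = None
    trait_cor: pd.DataFrame | None = None   # modules x traits (r)
    trait_p: pd.DataFrame | None = None
    trait_notes: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.sort_values(ascending=False).index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def build_tom(bundle: ExpressionBundle | pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Topological overlap matrix from soft-thresholded correlations."""
    X = bundle.values if isinstance(bundle, ExpressionBundle) else bundle
    if X.shape[1] < 4:
        raise ValueError("need >= 4 samples to build a co-expression network")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = list(X.index[sd == 0])
        raise ValueError(f"zero-variance gene(s) present: {bad[:5]}")
    corr = np.corrcoef(arr)
    np.clip(corr, -1.0, 1.0, out=corr)
    if params.signed:
        adj = ((1.0 + corr) / 2.0) ** params.power
    else:
        adj = np.abs(corr) ** params.power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=X.index, columns=X.index)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def _tree_cores(
    T: np.ndarray, min_core: int, cut_height: float, gap_decades: float
) -> list[list[int]]:
    """Candidate module cores from the TOM dendrogram on a log scale.

    A high soft power compresses 1 - TOM against 1, so the tree is
    built on -log10(TOM), where average linkage compares geometric
    means and module boundaries appear as additive jumps in merge
    height. A subtree is a core candidate when it holds at least
    ``min_core`` leaves and joins the rest of the tree at least
    ``gap_decades`` decades above its own root merge (a >= 10**gap
    drop in mean topological overlap). Smallest candidates are taken
    first (they are the purest); overlapping larger ones are skipped.
    """
    n = T.shape[0]
    Dlog = -np.log10(np.clip(T, 1e-15, None))
    np.fill_diagonal(Dlog, 0.0)
    Z = linkage(squareform(Dlog, checks=False), method="average")
    max_height = np.inf if cut_height >= 1.0 else -np.log10(1.0 - cut_height)
    root = to_tree(Z)

    candidates: list[tuple[int, float, object]] = []
    stack: list[tuple[object, float | None]] = [(root, None)]
    while stack:
        node, parent_dist = stack.pop()
        if node.is_leaf():
            continue
        if (
            parent_dist is not None
            and node.count >= min_core
            and node.dist <= max_height
            and parent_dist - node.dist >= gap_decades
        ):
            candidates.append((node.count, node.dist, node))
        stack.append((node.left, node.dist))
        stack.append((node.right, node.dist))

    candidates.sort(key=lambda t: (t[0], t[1]))
    taken = np.zeros(n, dtype=bool)
    cores: list[list[int]] = []
    for _, _, node in candidates:
        leaves = node.pre_order(lambda leaf: leaf.id)
        if not taken[leaves].any():
            cores.append(sorted(leaves))
            taken[leaves] = True
    return cores


def _kme_partition(
    X: np.ndarray, cores: list[list[int]], params: NetworkParams, n_iter: int = 3
) -> np.ndarray:
    """Iterative eigengene-based membership refinement.

    Starting from the tree cores, each round summarizes every module by
    its eigengene (first PC of the standardized member expression) and
    reassigns every gene to the module whose eigengene it correlates
    with best, when that kME clears ``kme_threshold`` (absolute kME for
    unsigned networks); near-duplicate modules (eigengene dissimilarity
    below the merge height) are fused between rounds.
    """
    n = X.shape[0]
    n_samples = X.shape[1]
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    members = [list(c) for c in cores]
    assign = np.full(n, -1, dtype=int)
    for _ in range(n_iter):
        mes = []
        for rows in members:
            _, _, vt = np.linalg.svd(Xs[rows], full_matrices=False)
            v = vt[0]
            if float(v @ Xs[rows].mean(axis=0)) < 0:
                v = -v
            mes.append(v)
        ME = np.asarray(mes)
        # fuse modules whose eigengenes are nearly the same signal
        fused: list[list[int]] = []
        used = np.zeros(len(members), dtype=bool)
        for i in range(len(members)):
            if used[i]:
                continue
            group = list(members[i])
            for j in range(i + 1, len(members)):
                if not used[j] and 1.0 - float(np.corrcoef(ME[i], ME[j])[0, 1]) < params.merge_height:
                    group += members[j]
                    used[j] = True
            used[i] = True
            fused.append(sorted(set(group)))
        if len(fused) < len(members):
            members = fused
            continue
        MEs = (ME - ME.mean(axis=1, keepdims=True)) / ME.std(axis=1, ddof=1, keepdims=True)
        kme = Xs @ MEs.T / (n_samples - 1)
        strength = kme if params.signed else np.abs(kme)
        best = np.argmax(strength, axis=1)
        best_val = strength[np.arange(n), best]
        assign = np.where(best_val >= params.kme_threshold, best, -1)
        members = [list(np.where(assign == k)[0]) for k in range(len(members))]
        members = [m for m in members if len(m) >= 2]
        if not members:
            return np.full(n, -1, dtype=int)
        # re-densify indices after dropping empty modules
        remap = {}
        for new_k, rows in enumerate(members):
            for g in rows:
                remap[g] = new_k
        assign = np.array([remap.get(g, -1) for g in range(n)], dtype=int)
    return assign


def detect_modules(
    tom: pd.DataFrame, params: NetworkParams, bundle: ExpressionBundle | None = None
) -> ModuleSet:
    """Cluster the TOM into modules; unassigned genes are labelled grey.

    Module cores come from the TOM dendrogram (see ``_tree_cores``).
    With ``params.pam`` and an expression bundle, membership is then
    refined by iterated eigengene correlation — the kME analogue of
    assigning outliers to the nearest cluster by partitioning around
    medoids; without expression data, grey genes join the module with
    the highest mean TOM similarity when it clears ``trim_threshold``
    times the module's median member connectivity. Modules below the
    minimum size are dissolved to grey at the end.
    """
    genes = list(tom.index)
    n = len(genes)
    T = tom.to_numpy(dtype=float)
    min_core = max(params.min_module_size // 2, 4)
    cores = _tree_cores(T, min_core, params.cut_height, params.gap_decades)

    if not cores:
        warnings.warn("no module core found; all genes grey")
        return ModuleSet(labels=pd.Series(GREY, index=genes))

    if params.pam and bundle is not None:
        X = bundle.values.loc[genes].to_numpy(dtype=float)
        assign = _kme_partition(X, cores, params)
    else:
        assign = np.full(n, -1, dtype=int)
        for k, core in enumerate(cores):
            for g in core:
                assign[g] = k
        if params.pam:
            medians = []
            for core in cores:
                sub = T[np.ix_(core, core)]
                medians.append(
                    float(np.median((sub.sum(axis=1) - 1.0) / (len(core) - 1)))
                    if len(core) > 1
                    else 0.0
                )
            for g in np.where(assign == -1)[0]:
                sims = [T[g, core].mean() for core in cores]
                best = int(np.argmax(sims))
                if sims[best] >= params.trim_threshold * medians[best]:
                    assign[g] = best

    # dissolve undersized modules
    sizes: dict[int, int] = {}
    for a in assign:
        if a >= 0:
            sizes[a] = sizes.get(a, 0) + 1
    for k, size in sizes.items():
        if size < params.min_module_size:
            assign[assign == k] = -1
    if not (assign >= 0).any():
        warnings.warn("no module reached the minimum size; all genes grey")
        return ModuleSet(labels=pd.Series(GREY, index=genes))

    return ModuleSet(labels=_palette_labels(assign, genes))


def _palette_labels(assign: np.ndarray, genes: list[str]) -> pd.Series:
    """Map module indices to palette colors, largest module first."""
    sizes: dict[int, int] = {}
    for a in assign:
        if a >= 0:
            sizes[a] = sizes.get(a, 0) + 1
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    name_of = {
        m: (MODULE_PALETTE[i] if i < len(MODULE_PALETTE) else f"module{i + 1}")
        for i, m in enumerate(order)
    }
    return pd.Series(
        [name_of[a] if a >= 0 else GREY for a in assign], index=genes
    )


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def compute_eigengenes(bundle: ExpressionBundle, module_set: ModuleSet) -> ModuleSet:
    """First-PC module eigengenes (unit norm, sign-fixed) and kME.

    The eigengene sign is fixed so it correlates positively with the
    module's mean standardized expression profile. kME is the Pearson
    correlation of every gene with every module eigengene.
    """
    labels = module_set.labels
    modules = module_set.module_names
    if not modules:
        raise ValueError("no modules to summarize")
    X = bundle.values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(bundle.values.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    gene_pos = {g: i for i, g in enumerate(bundle.genes)}

    me = {}
    ev = {}
    for mod in modules:
        members = [g for g in module_set.members(mod) if g in gene_pos]
        rows = [gene_pos[g] for g in members]
        sub = Xs[rows]
        if len(rows) == 1:
            warnings.warn(f"module {mod!r} has a single gene; eigengene degenerates")
            vec = sub[0]
            vec = vec / np.linalg.norm(vec)
            me[mod] = vec
            ev[mod] = 1.0
            continue
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        vec = vt[0]
        mean_profile = sub.mean(axis=0)
        orient = float(np.dot(vec, mean_profile))
        if orient < 0 or (orient == 0 and _first_nonzero_sign(vec) < 0):
            vec = -vec
        me[mod] = vec
        ev[mod] = float(s[0] ** 2 / np.sum(s**2))

    me_df = pd.DataFrame(me, index=bundle.samples)
    # kME: Pearson correlation of each gene profile with each eigengene
    n = len(bundle.samples)
    me_std = (me_df - me_df.mean(axis=0)) / me_df.std(axis=0, ddof=1)
    Xs1 = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1)[:, None]
    kme = pd.DataFrame(
        Xs1 @ me_std.to_numpy() / (n - 1), index=bundle.genes, columns=me_df.columns
    )
    return replace(
        module_set,
        me=me_df,
        kme=kme.clip(-1.0, 1.0),
        explained_variance=pd.Series(ev),
    )


def _first_nonzero_sign(vec: np.ndarray) -> float:
    nz = vec[vec != 0]
    return float(np.sign(nz[0])) if nz.size else 1.0


# ---------------------------------------------------------------------------
# Module merging
# ---------------------------------------------------------------------------

def merge_modules(
    bundle: ExpressionBundle, module_set: ModuleSet, merge_height: float | None = None
) -> ModuleSet:
    """Merge modules whose eigengene dissimilarity 1 - cor falls below
    the merge height (complete linkage over the eigengene dendrogram),
    recomputing eigengenes until stable."""
    if merge_height is None:
        merge_height = NetworkParams().merge_height
    current = module_set
    if current.me is None:
        current = compute_eigengenes(bundle, current)
    for _ in range(50):
        modules = current.module_names
        if len(modules) < 2:
            return current
        me = current.me[modules]
        corr = np.corrcoef(me.to_numpy().T)
        np.clip(corr, -1.0, 1.0, out=corr)
        D = 1.0 - corr
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="complete")
        # strict "< merge_height" merging
        groups = fcluster(Z, t=np.nextafter(merge_height, 0.0), criterion="distance")
        if len(set(groups)) == len(modules):
            return current
        labels = current.labels.copy()
        assign = np.full(len(labels), -1, dtype=int)
        group_of = {mod: g for mod, g in zip(modules, groups)}
        for i, g in enumerate(labels):
            if g != GREY:
                assign[i] = group_of[g]
        labels = _palette_labels(assign, list(labels.index))
        current = compute_eigengenes(bundle, ModuleSet(labels=labels))
    return current


# ---------------------------------------------------------------------------
# Trait correlation and QC
# ---------------------------------------------------------------------------

def correlate_traits(
    me: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pearson r and two-sided p for each module eigengene x trait.

    Missing trait values use pairwise deletion (reported in notes);
    constant traits are reported NA with a reason.
    """
    traits = clinical.loc[me.index]
    r = pd.DataFrame(index=me.columns, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=me.columns, columns=traits.columns, dtype=float)
    notes: dict[str, str] = {}
    for trait in traits.columns:
        tv = pd.to_numeric(traits[trait], errors="coerce")
        mask = tv.notna()
        if mask.sum() < len(tv):
            notes[trait] = f"pairwise deletion: {int((~mask).sum())} missing sample(s)"
        if mask.sum() < 3:
            notes[trait] = "fewer than 3 complete samples"
            continue
        if tv[mask].nunique() <= 1:
            notes[trait] = "constant trait; correlation undefined"
            continue
        for mod in me.columns:
            rr, pp = stats.pearsonr(me.loc[mask, mod], tv[mask])
            r.loc[mod, trait] = rr
            p.loc[mod, trait] = pp
    return r, p, notes


def qc_module(
    module: str,
    bundle: ExpressionBundle,
    module_set: ModuleSet,
    primary_trait: str = "sledai",
    strong_r: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Module quality control.

    Returns (i) a per-cohort eigengene consistency summary, (ii) the
    concordance between member kME and member gene-trait correlation
    for the primary trait, and (iii) a strong/weak call per
    module-trait correlation (|r| >= 0.5 and p < 0.05, boundary
    inclusive).
    """
    if module_set.me is None or module_set.kme is None:
        raise ValueError("compute eigengenes before QC")
    members = module_set.members(module)
    if not members:
        raise ValueError(f"module {module!r} has no members")
    me = module_set.me[module]
    cohort = bundle.cohort
    consistency = {
        "case_mean": float(me[cohort == 1].mean()),
        "case_sd": float(me[cohort == 1].std(ddof=1)),
        "control_mean": float(me[cohort == 0].mean()),
        "control_sd": float(me[cohort == 0].std(ddof=1)),
    }

    concordance_r = float("nan")
    if bundle.clinical is not None and primary_trait in bundle.clinical.columns:
        tv = pd.to_numeric(bundle.clinical[primary_trait], errors="coerce")
        mask = tv.notna()
        if mask.sum() >= 3 and tv[mask].nunique() > 1:
            gene_trait = []
            for g in members:
                gr, _ = stats.pearsonr(bundle.values.loc[g, mask], tv[mask])
                gene_trait.append(gr)
            kme_members = module_set.kme.loc[members, module]
            if len(members) >= 3 and np.std(gene_trait) > 0 and kme_members.std() > 0:
                concordance_r = float(np.corrcoef(kme_members, gene_trait)[0, 1])

    strength = {}
    if module_set.trait_cor is not None and module in module_set.trait_cor.index:
        for trait in module_set.trait_cor.columns:
            rr = module_set.trait_cor.loc[module, trait]
            pp = module_set.trait_p.loc[module, trait]
            strong = bool(
                pd.notna(rr) and pd.notna(pp) and abs(rr) >= strong_r and pp < alpha
            )
            strength[trait] = {"r": rr, "p": pp, "strong": strong}

    return {
        "module": module,
        "n_genes": len(members),
        "me_consistency": consistency,
        "kme_trait_concordance": concordance_r,
        "trait_strength": strength,
    }
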