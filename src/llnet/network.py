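"""Weighted gene co-expression network analysis.

An unsigned weighted network is built from all-against-all Pearson
correlations raised to a soft threshold power beta, chosen as the smallest
power whose connectivity distribution approximates scale-free topology at a
signed R^2 > 0.80. Modules are branches of an average-linkage dendrogram of
the topological-overlap dissimilarity, cut at a constant height with a
minimum module size; each module is summarized by its eigengene (first
right-singular vector of the standardized module submatrix), highly
correlated modules (eigengene dissimilarity < 0.20) are merged, and module
eigengenes are tested against lipid traits with Spearman's rank correlation
at an alpha level adjusted for the extrapolated number of modules in the
full probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats

from .association import spearman_test

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "select_probes_by_meta_trait",
    "adjacency_matrix",
    "connectivity",
    "scale_free_fit",
    "select_soft_power",
    "tom_similarity",
    "detect_modules",
    "eigengene",
    "compute_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "extrapolate_module_alpha",
    "module_membership_vs_significance",
    "replication_coexpression",
]

BACKGROUND = 0  # module label for unassigned probes


@dataclass
class NetworkConfig:
    top_fraction: float = 0.10
    power_grid: tuple[int, ...] = tuple(range(1, 21))
    signed_r2_min: float = 0.80
    min_module_size: int = 10
    merge_height: float = 0.20
    dissimilarity: str = "tom"  # or "adjacency"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if min(self.power_grid) < 1:
            raise ValueError("powers must be >= 1")
        if self.dissimilarity not in ("tom", "adjacency"):
            raise ValueError("dissimilarity must be 'tom' or 'adjacency'")


@dataclass
class ModuleSet:
    """Module assignment plus per-module summary statistics."""

    assignment: pd.Series  # probe -> module label (BACKGROUND allowed)
    eigengenes: pd.DataFrame | None = None  # module x sample
    kme: pd.DataFrame | None = None  # probe x module
    gene_significance: pd.DataFrame | None = None  # probe x trait
    module_trait: pd.DataFrame | None = None  # (module, trait) -> rho, p

    @property
    def labels(self) -> list:
        return sorted(set(self.assignment) - {BACKGROUND})

    def module_probes(self, label) -> pd.Index:
        return self.assignment.index[self.assignment == label]

    @property
    def n_modules(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# probe pre-selection


def select_probes_by_meta_trait(
    meta_results: pd.DataFrame, top_fraction: float = 0.10
) -> pd.Index:
    """Retain the strongest fraction of expression signals by multivariate P.

    ``meta_results`` is indexed by probe with a ``p`` column and an optional
    ``gene`` column; probes of the same gene are collapsed to the single
    best-P signal before ranking. Ties at the boundary are broken by probe
    id (ascending), which makes the selection deterministic.
    """
    if "p" not in meta_results.columns:
        raise ValueError("meta_results must have a 'p' column")
    order = np.lexsort(
        (meta_results.index.astype(str), meta_results["p"].to_numpy())
    )
    df = meta_results.iloc[order]
    if "gene" in df.columns:
        labelled = df["gene"].notna() & (df["gene"] != "")
        best = df[labelled].drop_duplicates(subset="gene", keep="first")
        df = pd.concat([best, df[~labelled]]).sort_values("p", kind="mergesort")
    n_keep = max(1, int(len(df) * top_fraction))
    return df.index[:n_keep]


# ---------------------------------------------------------------------------
# soft threshold selection


def adjacency_matrix(corr: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned weighted adjacency |cor|^beta with zero diagonal."""
    a = np.abs(np.asarray(corr, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_j a_ij (diagonal excluded)."""
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Connectivities are grouped into ``n_bins`` equal-width bins; the log10
    bin frequency is regressed on the log10 bin-mean connectivity, and the
    resulting R^2 is signed by the negative of the slope sign so that
    decaying (power-law-like) degree distributions score positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 5:
        raise ValueError("scale-free fit needs >= 5 positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        raise ValueError(
            "scale-free fit undefined: connectivities occupy a single bin"
        )
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(r**2 * (-np.sign(slope)))


def select_soft_power(
    corr: np.ndarray, config: NetworkConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft threshold power.

    For each power in the grid, compute the adjacency, the connectivity
    distribution and its signed scale-free fit; the chosen beta is the
    smallest power whose signed R^2 exceeds ``signed_r2_min`` (the smallest
    qualifying power maximizes mean connectivity among qualifying powers,
    since connectivity decreases monotonically in beta).
    """
    config = config or NetworkConfig()
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    rows = []
    chosen = None
    for beta in config.power_grid:
        a = adjacency_matrix(corr, beta)
        k = connectivity(a)
        try:
            r2 = scale_free_fit(k)
        except ValueError:
            r2 = np.nan
        rows.append((beta, r2, float(k.mean()), float(k.max())))
        if chosen is None and np.isfinite(r2) and r2 > config.signed_r2_min:
            chosen = beta
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k", "max_k"])
    if chosen is None:
        raise ValueError(
            f"no power in {config.power_grid} reaches signed R^2 > "
            f"{config.signed_r2_min}"
        )
    return chosen, table


# ---------------------------------------------------------------------------
# topological overlap and module detection


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where L = A @ A is
    the shared-neighbour weight; the diagonal is 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _constant_height_cut(linkage: np.ndarray, fraction: float = 0.9) -> float:
    """Cut height for branch detection: ``fraction`` of the way from the
    lowest merge height to the median merge height.

    Tight co-expressed branches merge far below the bulk of the dendrogram
    (whose merges concentrate near the median), so this cut separates them
    from the background mass; on uncorrelated data the minimum and median
    nearly coincide, the cut hugs the lowest merges, and average linkage
    pulls any growing cluster's height back toward the median, so no
    cluster reaches the minimum module size."""
    heights = linkage[:, 2]
    # epsilon guards against branches whose heights are zero up to rounding
    return float(
        heights.min() + fraction * (np.median(heights) - heights.min()) + 1e-9
    )


def detect_modules(
    dissimilarity: np.ndarray,
    probes: pd.Index,
    config: NetworkConfig | None = None,
    cut_height: float | None = None,
) -> ModuleSet:
    """Average-linkage clustering of the dissimilarity, constant-height
    branch cut, minimum module size enforced; remaining probes are labelled
    background (0). Modules are labelled 1..K by decreasing size.
    """
    config = config or NetworkConfig()
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n < config.min_module_size:
        return ModuleSet(pd.Series(BACKGROUND, index=probes, name="module"))
    condensed = d[np.triu_indices(n, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    if cut_height is None:
        cut_height = _constant_height_cut(Z)
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_label = 1
    for cluster_id, size in sizes.items():
        if size >= config.min_module_size:
            labels[raw == cluster_id] = next_label
            next_label += 1
    return ModuleSet(pd.Series(labels, index=probes, name="module"))


# ---------------------------------------------------------------------------
# eigengenes


def eigengene(submatrix: pd.DataFrame) -> pd.Series:
    """Summary profile of a module: first right-singular vector over samples.

    Probes are standardized across samples first; the returned profile has
    unit variance and is oriented so that its mean correlation with the
    member probes is positive.
    """
    if submatrix.shape[0] < 2:
        raise ValueError("eigengene needs >= 2 probes")
    M = submatrix.to_numpy(dtype=float)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (M - M.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    v = v / v.std(ddof=0)
    if np.mean(Z @ v) < 0:
        v = -v
    return pd.Series(v, index=submatrix.columns, name="eigengene")


def compute_eigengenes(modules: ModuleSet, expression: pd.DataFrame) -> pd.DataFrame:
    """Eigengene for every module (modules x samples)."""
    rows = {}
    for label in modules.labels:
        rows[label] = eigengene(expression.loc[modules.module_probes(label)])
    if not rows:
        return pd.DataFrame(columns=expression.columns)
    eg = pd.DataFrame(rows).T
    eg.index.name = "module"
    return eg


def merge_modules(
    modules: ModuleSet,
    expression: pd.DataFrame,
    merge_height: float = 0.20,
) -> ModuleSet:
    """Merge modules whose eigengenes are highly correlated.

    Eigengenes are clustered with dissimilarity 1 - cor under average
    linkage; clusters joined below ``merge_height`` are merged and the
    merged eigengenes recomputed, iterating until the module count is
    stable.
    """
    assignment = modules.assignment.copy()
    while True:
        ms = ModuleSet(assignment)
        labels = ms.labels
        if len(labels) < 2:
            break
        eg = compute_eigengenes(ms, expression)
        corr = np.corrcoef(eg.to_numpy())
        d = 1.0 - corr
        condensed = d[np.triu_indices(len(labels), k=1)]
        Z = hierarchy.linkage(condensed, method="average")
        grouped = hierarchy.fcluster(Z, t=merge_height, criterion="distance")
        if len(set(grouped)) == len(labels):
            break
        relabel = {}
        for new, old_group in enumerate(pd.unique(grouped), start=1):
            for lab, g in zip(labels, grouped):
                if g == old_group:
                    relabel[lab] = new
        assignment = assignment.map(lambda x: relabel.get(x, BACKGROUND))
    out = ModuleSet(assignment)
    out.eigengenes = compute_eigengenes(out, expression)
    return out


# ---------------------------------------------------------------------------
# module-trait statistics


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float | None = None
) -> pd.DataFrame:
    """Spearman rank correlation (t-test) of each eigengene with each trait.

    Returns a long-format table (module, trait, rho, p, significant); the
    significance gate is ``alpha`` when given (typically the extrapolated
    module-count-adjusted level).
    """
    rows = []
    for label in eigengenes.index:
        for trait in traits.columns:
            rho, p = spearman_test(
                eigengenes.loc[label, traits.index], traits[trait]
            )
            rows.append((label, trait, rho, p))
    out = pd.DataFrame(rows, columns=["module", "trait", "rho", "p"])
    if alpha is not None:
        out["significant"] = out["p"] < alpha
    return out


def extrapolate_module_alpha(
    n_modules_subset: int,
    n_probes_subset: int,
    n_probes_total: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Extrapolate the module count to the full probe set and Bonferroni-
    adjust alpha: estimate = modules * total / subset; alpha / estimate."""
    if min(n_modules_subset, n_probes_subset, n_probes_total) <= 0:
        raise ValueError("counts must be positive")
    estimate = n_modules_subset * n_probes_total / n_probes_subset
    return estimate, alpha / estimate


def module_membership_vs_significance(
    modules: ModuleSet,
    expression: pd.DataFrame,
    trait: pd.Series,
    label,
) -> pd.DataFrame:
    """Per-probe module membership (kME) against gene significance (GS).

    kME is the Pearson correlation of a member probe with the module
    eigengene; GS is the absolute Pearson correlation of the probe with the
    trait. The table's ``kme_gs_correlation`` attr holds cor(kME, GS) within
    the module (NaN when degenerate, e.g. all kME identical).
    """
    probes = modules.module_probes(label)
    if len(probes) == 0:
        raise ValueError(f"module {label!r} is empty")
    if modules.eigengenes is None or label not in modules.eigengenes.index:
        raise ValueError("eigengenes not computed for this module set")
    samples = trait.index
    eg = modules.eigengenes.loc[label, samples].to_numpy(dtype=float)
    M = expression.loc[probes, samples].to_numpy(dtype=float)
    t = trait.to_numpy(dtype=float)

    def _cor(rows, v):
        rc = rows - rows.mean(axis=1, keepdims=True)
        vc = v - v.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
        return (rc @ vc) / denom

    kme = _cor(M, eg)
    gs = np.abs(_cor(M, t))
    out = pd.DataFrame({"kme": kme, "gs": gs}, index=probes)
    if np.std(kme) == 0 or np.std(gs) == 0:
        out.attrs["kme_gs_correlation"] = np.nan
    else:
        out.attrs["kme_gs_correlation"] = float(np.corrcoef(kme, gs)[0, 1])
    return out


def replication_coexpression(
    expression: pd.DataFrame, genes: list, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise Spearman co-expression among a gene set in an independent
    expression matrix, with a Bonferroni gate of alpha / n_unordered_pairs.
    Rows are ordered pairs (both directions, as reported)."""
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    n_pairs = len(genes) * (len(genes) - 1) // 2
    if n_pairs == 0:
        raise ValueError("need >= 2 genes")
    gate = alpha / n_pairs
    rows = []
    for ga in genes:
        for gb in genes:
            if ga == gb:
                continue
            rho, p = spearman_test(expression.loc[ga], expression.loc[gb])
            rows.append((ga, gb, rho, p, p < gate))
    out = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rho", "p", "significant"]
    )
    out.attrs["bonferroni_gate"] = gate
    return out
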