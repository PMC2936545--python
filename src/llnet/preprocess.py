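"""Expression and genotype QC, normalization, and trait standardization.

The stages mirror a standard bead-array population study: technical
replicates are correlated (Pearson >= 0.94 and Spearman >= 0.60 to keep a
sample) and combined by a bead-weighted mean; probe intensity distributions
are forced identical by quantile normalization; probes that are
non-autosomal, complementary to erythrocyte globin transcripts, or
multi-mapping are removed; lipid traits are tested for normality
(Anderson-Darling), Box-Cox transformed when needed, and standardized to
Z-scores separately within each sex; SNPs are filtered on call rate > 0.95,
MAF > 0.01 and Hardy-Weinberg exact P > 1e-6; and population-structure
outliers are flagged at 8 standard deviations along any principal component
deemed significant by a Tracy-Widom test at P < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import GenotypeDataset

__all__ = [
    "ReplicatePair",
    "QCReport",
    "qc_replicates",
    "combine_replicates",
    "quantile_normalize",
    "filter_probes",
    "anderson_darling_pvalue",
    "transform_trait",
    "hwe_exact_test",
    "qc_genotypes",
    "tracy_widom_sf",
    "pca_outliers",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass
class ReplicatePair:
    """One sample's two technical replicate arrays (linear-scale signals
    ``s1``/``s2`` with bead counts ``b1``/``b2``, all probe-indexed)."""

    sample_id: str
    s1: pd.Series
    s2: pd.Series
    b1: pd.Series
    b2: pd.Series
    corrupted: bool = False  # generator-only flag; never used by QC

    def __post_init__(self) -> None:
        for layer in (self.s2, self.b1, self.b2):
            if not layer.index.equals(self.s1.index):
                raise ValueError("replicate layers must share probe indexing")


@dataclass
class QCReport:
    """Per-sample / per-SNP QC statistics and drop decisions."""

    replicates: pd.DataFrame | None = None  # pearson, spearman, kept, reason
    snps: pd.DataFrame | None = None  # call_rate, maf, hwe_p, kept, reason
    samples_dropped: list = field(default_factory=list)
    pca_outliers: list = field(default_factory=list)
    tw_pvalues: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# replicate QC and combination


def qc_replicates(
    pairs: list[ReplicatePair],
    pearson_min: float = 0.94,
    spearman_min: float = 0.60,
) -> QCReport:
    """Correlate each sample's technical replicates on normalized log2 values.

    All replicate arrays are log2-transformed and quantile-normalized
    together, then per-sample Pearson and Spearman correlations are taken;
    a sample is dropped if Pearson < ``pearson_min`` or Spearman <
    ``spearman_min``. MA coordinates (M = log2 ratio, A = mean log2
    intensity) are recorded for plotting/inspection.
    """
    if not pairs:
        raise ValueError("no replicate pairs supplied")
    cols = {}
    for pair in pairs:
        if len(pair.s1) < 2:
            raise ValueError("replicate QC needs >= 2 probes")
        cols[(pair.sample_id, 1)] = np.log2(pair.s1.to_numpy(dtype=float))
        cols[(pair.sample_id, 2)] = np.log2(pair.s2.to_numpy(dtype=float))
    mat = pd.DataFrame(cols, index=pairs[0].s1.index)
    mat = quantile_normalize(mat)

    rows = []
    ma = {}
    for pair in pairs:
        x = mat[(pair.sample_id, 1)].to_numpy()
        y = mat[(pair.sample_id, 2)].to_numpy()
        ma[pair.sample_id] = (x - y, 0.5 * (x + y))
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            rows.append((pair.sample_id, np.nan, np.nan, False, "degenerate"))
            continue
        pr = float(np.corrcoef(x, y)[0, 1])
        sr = float(stats.spearmanr(x, y).statistic)
        if not (np.isfinite(pr) and np.isfinite(sr)):
            rows.append((pair.sample_id, np.nan, np.nan, False, "degenerate"))
            continue
        kept = pr >= pearson_min and sr >= spearman_min
        reason = "" if kept else "replicate_correlation"
        rows.append((pair.sample_id, pr, sr, kept, reason))
    table = pd.DataFrame(
        rows, columns=["sample", "pearson", "spearman", "kept", "reason"]
    ).set_index("sample")
    report = QCReport(replicates=table)
    report.ma_coordinates = ma
    report.samples_dropped = table.index[~table["kept"]].tolist()
    return report


def combine_replicates(pair: ReplicatePair) -> pd.Series:
    """Bead-weighted mean of the two replicate signals, probe by probe:
    delta_p = (b1*S1 + b2*S2) / (b1 + b2)."""
    b1 = pair.b1.to_numpy(dtype=float)
    b2 = pair.b2.to_numpy(dtype=float)
    if (b1 <= 0).any() or (b2 <= 0).any():
        raise ValueError("bead counts must be positive")
    delta = (b1 * pair.s1.to_numpy(float) + b2 * pair.s2.to_numpy(float)) / (b1 + b2)
    return pd.Series(delta, index=pair.s1.index, name=pair.sample_id)


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(
    matrix: pd.DataFrame, groups: dict | None = None
) -> pd.DataFrame:
    """Force every column's intensity distribution to the cross-column mean
    quantile vector. Ties within a column receive the mean of the pooled
    quantile values they span.

    ``groups`` optionally maps column -> group label; normalization is then
    performed independently within each group (e.g. per array strip).
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires complete data")
    if groups is not None:
        out = matrix.copy()
        labels = pd.Series({c: groups[c] for c in matrix.columns})
        for _, cols in labels.groupby(labels).groups.items():
            out[list(cols)] = quantile_normalize(matrix[list(cols)])
        return out
    if matrix.shape[1] == 1:
        return matrix.copy()

    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average assigned quantiles over tied input values
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(annotations: pd.DataFrame) -> pd.Series:
    """Keep mask: autosomal, not a globin probe, unique genomic mapping."""
    for col in ("chromosome", "globin", "n_mappings"):
        if col not in annotations.columns:
            raise ValueError(f"probe annotations lack {col!r}")
    chrom = annotations["chromosome"].astype(str).str.replace("chr", "", regex=False)
    keep = (
        chrom.isin(AUTOSOMES)
        & ~annotations["globin"].astype(bool)
        & (annotations["n_mappings"].astype(int) == 1)
    )
    keep.name = "keep"
    return keep


# ---------------------------------------------------------------------------
# trait transformation


def anderson_darling_pvalue(x: np.ndarray) -> float:
    """Anderson-Darling normality test P value (case 3: mean and variance
    estimated), using the Stephens small-sample correction and the standard
    piecewise exponential approximation of the null distribution."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("Anderson-Darling needs n >= 8")
    y = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = np.clip(stats.norm.cdf(y), 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s >= 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s >= 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(min(max(p, 0.0), 1.0))


def transform_trait(
    values: pd.Series, sex: pd.Series, ad_alpha: float = 0.01
) -> tuple[pd.Series, dict]:
    """Per-sex normality gate, Box-Cox when needed, then Z-scores.

    Within each sex: if the Anderson-Darling test rejects normality at
    ``ad_alpha``, a Box-Cox power transform with maximum-likelihood lambda
    is applied (values must be positive); the (possibly transformed) values
    are standardized to mean 0, sd 1. The two standardized vectors are
    recombined in the original sample order. Returns the Z-scores and a
    per-sex metadata dict with the AD P value and fitted lambda.
    """
    if not values.index.equals(sex.index):
        sex = sex.loc[values.index]
    out = pd.Series(np.nan, index=values.index, name=values.name)
    meta: dict[str, dict] = {}
    for level in pd.unique(sex):
        mask = (sex == level).to_numpy()
        x = values[mask].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"trait constant within sex {level!r}: zero variance")
        ad_p = anderson_darling_pvalue(x)
        lam = None
        if ad_p < ad_alpha:
            if (x <= 0).any():
                raise ValueError(
                    "Box-Cox requires positive values; shift the trait or "
                    "exclude non-positive measurements before transforming"
                )
            x, lam = stats.boxcox(x)
        z = (x - x.mean()) / x.std(ddof=0)
        out[mask] = z
        meta[str(level)] = {"ad_p": ad_p, "boxcox_lambda": lam}
    return out, meta


# ---------------------------------------------------------------------------
# genotype QC


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium test P value.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the probabilities of tables no more likely than the observed
    one (two-sided exact test conditional on allele counts).
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab  # allele A count
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(homr + 1)
        - special.gammaln(homc + 1)
        + hets * np.log(2.0)
        - special.gammaln(2 * n + 1)
        + special.gammaln(rare + 1)
        + special.gammaln(2 * n - rare + 1)
    )
    probs = np.exp(logp)
    obs_het = n_ab
    p_obs = probs[hets == obs_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_genotypes(
    gd: GenotypeDataset,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    sample_call_rate_min: float = 0.95,
) -> tuple[QCReport, GenotypeDataset]:
    """SNP and sample QC gates.

    Samples with call rate < ``sample_call_rate_min`` are removed first;
    then a SNP is kept iff call rate > ``call_rate_min``, minor allele
    frequency > ``maf_min``, and exact HWE P > ``hwe_p_min``.
    """
    dos = gd.dosages.to_numpy(dtype=float)
    sample_cr = 1.0 - np.isnan(dos).mean(axis=1)
    sample_keep = sample_cr >= sample_call_rate_min
    dropped_samples = gd.samples[~sample_keep].tolist()
    dos = dos[sample_keep]

    rows = []
    for j, snp in enumerate(gd.snp_ids):
        col = dos[:, j]
        obs = col[~np.isnan(col)]
        cr = obs.size / col.size if col.size else 0.0
        if obs.size == 0:
            rows.append((snp, cr, np.nan, np.nan, False, "call_rate"))
            continue
        n_aa = int((obs == 0).sum())
        n_ab = int((obs == 1).sum())
        n_bb = int((obs == 2).sum())
        freq = (n_ab + 2 * n_bb) / (2 * obs.size)
        maf = min(freq, 1 - freq)
        hwe_p = hwe_exact_test(n_aa, n_ab, n_bb)
        reasons = []
        if not cr > call_rate_min:
            reasons.append("call_rate")
        if not maf > maf_min:
            reasons.append("maf")
        if not hwe_p > hwe_p_min:
            reasons.append("hwe")
        rows.append((snp, cr, maf, hwe_p, not reasons, ";".join(reasons)))
    table = pd.DataFrame(
        rows, columns=["snp", "call_rate", "maf", "hwe_p", "kept", "reason"]
    ).set_index("snp")
    kept_snps = table.index[table["kept"]]
    filtered = GenotypeDataset(
        gd.dosages.loc[sample_keep, kept_snps], gd.snps.loc[kept_snps]
    )
    report = QCReport(snps=table, samples_dropped=dropped_samples)
    return report, filtered


# ---------------------------------------------------------------------------
# population-structure outliers (Tracy-Widom gated PCA)

# Shifted-gamma approximation of the Tracy-Widom beta=1 distribution
# (Chiani 2014): TW1 + _TW_ALPHA ~ Gamma(k=_TW_K, scale=_TW_THETA).
_TW_K = 46.44604884387787
_TW_THETA = 0.18605402228279682
_TW_ALPHA = 9.848007781128567


def tracy_widom_sf(x: float) -> float:
    """Upper-tail probability of the Tracy-Widom (beta=1) distribution."""
    return float(stats.gamma.sf(x + _TW_ALPHA, a=_TW_K, scale=_TW_THETA))


def _tw_pvalues(eigvals: np.ndarray) -> list[float]:
    """Sequential Tracy-Widom P values for ordered covariance eigenvalues,
    using the moment-matched effective number of markers at each step."""
    lam = np.sort(np.asarray(eigvals, dtype=float))[::-1]
    pvals = []
    for k in range(len(lam)):
        tail = lam[k:]
        m = tail.size
        if m < 3 or tail.sum() <= 0:
            pvals.append(1.0)
            continue
        s1, s2 = tail.sum(), (tail**2).sum()
        denom = (m - 1) * s2 - s1**2 / 1.0
        n_eff = (m + 1) * s1**2 / denom if denom > 0 else np.inf
        if not np.isfinite(n_eff) or n_eff <= 1:
            pvals.append(1.0)
            continue
        ell = m * tail[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_m = np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1 / sq_n + 1 / sq_m) ** (1 / 3)
        pvals.append(tracy_widom_sf((ell - mu) / sigma))
    return pvals


def _ld_residualize(gd: GenotypeDataset) -> np.ndarray:
    """Residualize each SNP's standardized dosage on the 2 preceding SNPs of
    the same chromosome (position order) to damp local LD; the first SNPs of
    a chromosome are used raw. Missing dosages are mean-imputed."""
    dos = gd.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    dos[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    snps = gd.snps
    out = np.empty_like(dos)
    order_all = []
    for chrom, sub in snps.groupby("chromosome", sort=False):
        order = sub.sort_values("position").index
        cols = [gd.snp_ids.get_loc(s) for s in order]
        order_all.extend(cols)
        for i, c in enumerate(cols):
            y = dos[:, c]
            if i >= 2:
                X = np.column_stack(
                    [np.ones_like(y), dos[:, cols[i - 1]], dos[:, cols[i - 2]]]
                )
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
            else:
                resid = y - y.mean()
            sd = resid.std()
            out[:, c] = resid / sd if sd > 0 else 0.0
    return out


def pca_outliers(
    gd: GenotypeDataset, sd_threshold: float = 8.0, tw_alpha: float = 0.01
) -> tuple[list, QCReport]:
    """Flag samples beyond ``sd_threshold`` standard deviations along any
    Tracy-Widom-significant principal component of the LD-residualized
    genotype matrix. Returns (outlier sample ids, report)."""
    if gd.dosages.shape[0] < 10:
        raise ValueError("PCA outlier detection needs >= 10 samples")
    X = _ld_residualize(gd)
    X = X - X.mean(axis=0, keepdims=True)
    # sample-sample covariance spectrum via SVD
    u, svals, _ = np.linalg.svd(X, full_matrices=False)
    eigvals = svals**2 / X.shape[1]
    pvals = _tw_pvalues(eigvals)
    scores = u * svals  # samples x components

    outliers: set = set()
    n_sig = 0
    for k, p in enumerate(pvals):
        if p >= tw_alpha:
            break
        n_sig += 1
        s = scores[:, k]
        sd = s.std()
        if sd == 0:
            continue
        flagged = np.abs(s) / sd > sd_threshold
        outliers.update(gd.samples[flagged])
    report = QCReport(pca_outliers=sorted(outliers), tw_pvalues=pvals[: max(n_sig, 1)])
    return sorted(outliers), report
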