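"""Expression quantitative trait locus (eQTL) scans.

A SNP is *cis* to a probe when it lies within 1 Mb of the probe midpoint on
the same chromosome and *trans* when it is more than 5 Mb away or on
another chromosome; the ambiguous 1-5 Mb band is excluded from both scans.
Cis SNPs are tested by simple linear regression of log2 expression on
minor-allele dosage, with significance calibrated by permuting expression
relative to genotypes (10,000 permutations by default, empirical alpha
0.05 on the per-probe minimum nominal P). Trans SNPs are tested with the
Spearman rank correlation at a fixed nominal threshold of 5.0e-7, since a
genome-wide permutation null is not recomputed for every probe. Module-
level tests regress all member probes on a SNP jointly and report Wilks'
lambda.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import spearman_test, wilks_lambda
from .datatypes import GenotypeDataset

__all__ = [
    "CIS_WINDOW",
    "TRANS_MIN_DISTANCE",
    "classify_snp",
    "cis_scan",
    "permutation_calibrate",
    "trans_scan",
    "module_eqtl",
]

CIS_WINDOW = 1_000_000  # bp, SNP to probe midpoint
TRANS_MIN_DISTANCE = 5_000_000  # bp


def classify_snp(
    snp_chrom: str,
    snp_pos: int,
    probe_chrom: str,
    probe_pos: int,
    cis_window: int = CIS_WINDOW,
    trans_min: int = TRANS_MIN_DISTANCE,
) -> str:
    """Return 'cis', 'trans', or 'excluded' (the 1-5 Mb ambiguity band)."""
    if str(snp_chrom) != str(probe_chrom):
        return "trans"
    d = abs(int(snp_pos) - int(probe_pos))
    if d <= cis_window:
        return "cis"
    if d > trans_min:
        return "trans"
    return "excluded"


def _snp_window(
    genotypes: GenotypeDataset, probe_chrom: str, probe_pos: int, mode: str,
    cis_window: int = CIS_WINDOW, trans_min: int = TRANS_MIN_DISTANCE,
) -> pd.Index:
    cls = genotypes.snps.apply(
        lambda row: classify_snp(
            row["chromosome"], row["position"], probe_chrom, probe_pos,
            cis_window, trans_min,
        ),
        axis=1,
    )
    return genotypes.snp_ids[(cls == mode).to_numpy()]


def cis_scan(
    expression: pd.Series,
    genotypes: GenotypeDataset,
    probe_chrom: str,
    probe_pos: int,
    window: int = CIS_WINDOW,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-SNP simple linear regression of one probe's expression on dosage.

    Missing genotypes are dropped pairwise; monomorphic SNPs and SNPs with
    fewer than ``min_pairs`` complete pairs are skipped with a reason.
    Returns a table indexed by SNP with slope, SE, nominal P and position.
    """
    snp_ids = _snp_window(genotypes, probe_chrom, probe_pos, "cis", window)
    y_all = expression.loc[genotypes.samples].to_numpy(dtype=float)
    rows = []
    for snp in snp_ids:
        g = genotypes.dosages[snp].to_numpy(dtype=float)
        ok = ~np.isnan(g)
        g_ok, y = g[ok], y_all[ok]
        n = g_ok.size
        if n < min_pairs:
            rows.append((snp, n, np.nan, np.nan, np.nan, "too_few_pairs"))
            continue
        if np.ptp(g_ok) == 0:
            rows.append((snp, n, np.nan, np.nan, np.nan, "monomorphic"))
            continue
        sxx = np.sum((g_ok - g_ok.mean()) ** 2)
        slope = np.sum((g_ok - g_ok.mean()) * (y - y.mean())) / sxx
        resid = y - y.mean() - slope * (g_ok - g_ok.mean())
        se = np.sqrt(resid @ resid / (n - 2) / sxx)
        if se == 0:
            p = 0.0
        else:
            p = 2.0 * stats.t.sf(abs(slope / se), df=n - 2)
        rows.append((snp, n, slope, se, p, ""))
    out = pd.DataFrame(
        rows, columns=["snp", "n", "slope", "se", "p", "reason"]
    ).set_index("snp")
    if len(out):
        out["position"] = genotypes.snps.loc[out.index, "position"]
    return out


def permutation_calibrate(
    expression: pd.Series,
    genotypes: GenotypeDataset,
    cis_snps,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation-based empirical P for a probe's best cis association.

    Expression is permuted relative to genotypes; for each permutation the
    minimum nominal P across the probe's cis SNPs is recorded, and the
    empirical P is (1 + #{permuted min-P <= observed min-P}) / (n_perm + 1).
    Missing dosages are mean-imputed for this scan so all SNPs share a
    common sample set. Returns observed min-P, the empirical P, and the
    verdict at the permutation threshold ``alpha``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse empirical P resolution")
    cis_snps = list(cis_snps)
    if not cis_snps:
        raise ValueError("no cis SNPs supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    G = genotypes.dosages[cis_snps].to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all cis SNPs monomorphic")
    G = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    n = G.shape[0]

    y = expression.loc[genotypes.samples].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std()

    def min_p(Y):
        # |r| -> two-sided t P with n-2 df; columns of Y are (permuted) probes
        R = G.T @ Y / n
        R = np.clip(np.abs(R), 0, 1 - 1e-15)
        T = R * np.sqrt((n - 2) / (1 - R**2))
        return 2.0 * stats.t.sf(T, df=n - 2).min(axis=0)

    obs = float(min_p(y[:, None])[0])
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]
    null_min_p = min_p(perms)
    emp = (1.0 + np.sum(null_min_p <= obs)) / (n_perm + 1.0)
    return {
        "observed_min_p": obs,
        "empirical_p": float(emp),
        "n_perm": n_perm,
        "significant": emp < alpha,
    }


def trans_scan(
    expression: pd.Series,
    genotypes: GenotypeDataset,
    probe_chrom: str,
    probe_pos: int,
    threshold: float = 5.0e-7,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman rank test of one probe against every trans SNP.

    Genotype ranks use midranks over the 0/1/2 dosages. Returns the full
    per-SNP table with a ``significant`` flag at nominal P < ``threshold``.
    """
    y_all = expression.loc[genotypes.samples].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        warnings.warn("constant expression: no trans tests performed")
        return pd.DataFrame(columns=["rho", "p", "n", "significant"])
    snp_ids = _snp_window(genotypes, probe_chrom, probe_pos, "trans")
    rows = []
    for snp in snp_ids:
        g = genotypes.dosages[snp].to_numpy(dtype=float)
        ok = ~np.isnan(g)
        if ok.sum() < min_pairs or np.ptp(g[ok]) == 0:
            continue
        rho, p = spearman_test(g[ok], y_all[ok])
        rows.append((snp, rho, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["snp", "rho", "p", "n"]).set_index("snp")
    out["significant"] = out["p"] < threshold
    return out


def module_eqtl(
    module_expression: pd.DataFrame, dosage: pd.Series
) -> dict:
    """Multivariate test of one SNP against all module probes jointly.

    Y (samples x probes) is regressed on [1, dosage]; the dosage term is
    tested with Wilks' lambda. Samples with missing dosage are dropped.
    A single-probe module reduces exactly to the univariate regression.
    """
    samples = module_expression.columns.intersection(dosage.index)
    g = dosage.loc[samples].to_numpy(dtype=float)
    ok = ~np.isnan(g)
    g = g[ok]
    Y = module_expression[samples[ok]].to_numpy(dtype=float).T
    if np.ptp(g) == 0:
        raise ValueError("monomorphic SNP")
    X = np.column_stack([np.ones(g.size), g])
    return wilks_lambda(Y, X, term_cols=[1])
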