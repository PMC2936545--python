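"""Trait-expression association: univariate OLS with covariates and
Bonferroni control, the multivariate "meta-lipid" model tested with Wilks'
lambda, rank-based Spearman tests, and cell-type marker covariates.

The univariate model regresses a gender-stratified trait Z-score on one
probe's log2 expression plus per-trait covariates (age, medications,
alcohol); significance is gated at a Bonferroni-adjusted nominal level
0.05 / m_tests. The multivariate model treats all lipid traits jointly as
the response matrix Y = XB + E and tests the expression regressor with
Wilks' lambda (Rao's F approximation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bonferroni",
    "spearman_test",
    "build_design",
    "fit_trait_expression",
    "celltype_covariates",
    "wilks_lambda",
    "fit_meta_lipids",
]


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P value: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, p * m))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties, tested with a
    t statistic on n-2 degrees of freedom (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("spearman_test needs n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def build_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Assemble a covariate design matrix (no intercept column).

    Numeric columns pass through; two-level object/categorical columns are
    dummy-coded; collinear columns are dropped with a warning.
    """
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0))
    cols, names = [], []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = pd.unique(col)
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    # drop columns that do not increase rank (collinearity guard)
    keep: list[int] = []
    base = np.ones((n, 1))
    for j in range(X.shape[1]):
        trial = np.column_stack([base] + [X[:, k] for k in keep] + [X[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {names[j]!r}")
    return X[:, keep]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, C] (Frisch-Waugh projection)."""
    X = np.column_stack([np.ones(M.shape[0]), C])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def fit_trait_expression(
    trait: pd.Series,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    m_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe OLS of a standardized trait on expression plus covariates.

    Returns a table with the slope on expression, its 95% CI, nominal and
    Bonferroni-corrected P values, and the significance verdict at nominal
    P < alpha / m_tests. Probes are rows of ``expression``; samples are
    aligned on the trait's index.
    """
    samples = trait.index
    E = expression[samples].to_numpy(dtype=float).T  # samples x probes
    y = trait.to_numpy(dtype=float)
    n, n_probes = E.shape
    if m_tests is None:
        m_tests = n_probes
    C = build_design(covariates.loc[samples] if covariates is not None else None, n)
    k = C.shape[1] + 2  # intercept + expression + covariates
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters")

    ey = _residualize(y[:, None], C)[:, 0]
    EE = _residualize(E, C)
    df = n - k
    sxx = (EE**2).sum(axis=0)
    sxx[sxx == 0] = np.nan
    beta = (EE * ey[:, None]).sum(axis=0) / sxx
    rss = (ey**2).sum() - beta**2 * sxx
    se = np.sqrt(rss / df / sxx)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    tq = stats.t.ppf(0.975, df=df)
    gate = alpha / m_tests
    out = pd.DataFrame(
        {
            "probe": expression.index,
            "trait": trait.name,
            "beta": beta,
            "ci_low": beta - tq * se,
            "ci_high": beta + tq * se,
            "se": se,
            "p": p,
            "p_corrected": np.minimum(1.0, p * m_tests),
            "n": n,
            "significant": p < gate,
        }
    ).set_index("probe")
    out.attrs["nominal_gate"] = gate
    return out


def celltype_covariates(
    expression: pd.DataFrame, marker_sets: dict[str, list]
) -> pd.DataFrame:
    """Average standard score across each cell type's marker probes.

    Each marker probe is Z-scored across samples; the covariate for a cell
    type is the per-sample mean of its markers' Z-scores. Markers absent
    from the matrix are skipped with a warning; an entirely empty set is an
    error.
    """
    out = {}
    for cell_type, markers in marker_sets.items():
        if not markers:
            raise ValueError(f"empty marker set for {cell_type!r}")
        present = [m for m in markers if m in expression.index]
        missing = set(markers) - set(present)
        if missing:
            warnings.warn(
                f"{cell_type}: {len(missing)} marker(s) absent, e.g. "
                f"{sorted(missing)[0]!r}"
            )
        if not present:
            raise ValueError(f"no markers of {cell_type!r} present in the matrix")
        M = expression.loc[present].to_numpy(dtype=float)
        z = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
        out[cell_type] = z.mean(axis=0)
    return pd.DataFrame(out, index=expression.columns)


def wilks_lambda(
    Y: np.ndarray, X_full: np.ndarray, term_cols: list[int]
) -> dict:
    """Wilks' lambda test of a model term in the multivariate regression
    Y = XB + E, with P value from Rao's F approximation.

    ``term_cols`` indexes the columns of ``X_full`` under test (Type III:
    the reduced model drops exactly those columns). Returns a dict with
    lambda, F, df1, df2 and p. Exact when min(k, q) <= 2.
    """
    Y = np.asarray(Y, dtype=float)
    X_full = np.asarray(X_full, dtype=float)
    n, k = Y.shape
    q = len(term_cols)
    rank_full = np.linalg.matrix_rank(X_full)

    def sscp_resid(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    E = sscp_resid(X_full)
    reduced = np.delete(X_full, term_cols, axis=1)
    H = sscp_resid(reduced) - E

    sign, logdet_e = np.linalg.slogdet(E)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular residual covariance")
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdet_e - logdet_t))
    lam = min(max(lam, 0.0), 1.0)

    v = n - rank_full  # error df
    s = 1.0
    if k * k + q * q - 5 > 0:
        s = np.sqrt((k**2 * q**2 - 4) / (k**2 + q**2 - 5))
    m = v - (k - q + 1) / 2.0
    df1 = k * q
    df2 = m * s - k * q / 2.0 + 1.0
    if df2 <= 0:
        raise ValueError("insufficient error degrees of freedom")
    lam_s = lam ** (1.0 / s)
    F = np.inf if lam_s == 0 else (1 - lam_s) / lam_s * df2 / df1
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {"lambda": lam, "F": float(F), "df1": df1, "df2": float(df2), "p": p}


def fit_meta_lipids(
    traits: pd.DataFrame,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Joint multivariate test of one predictor against all lipid traits.

    ``traits`` is the samples x traits matrix of standardized lipid values,
    ``predictor`` the probe's expression (or a SNP dosage), ``covariates``
    the meta-lipid covariate set. Reports Wilks' lambda for the predictor
    term.
    """
    samples = traits.index
    Y = traits.to_numpy(dtype=float)
    x = predictor.loc[samples].to_numpy(dtype=float)
    n = Y.shape[0]
    C = build_design(covariates.loc[samples] if covariates is not None else None, n)
    X = np.column_stack([np.ones(n), x, C])
    return wilks_lambda(Y, X, term_cols=[1])
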