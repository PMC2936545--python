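"""Small maximum-likelihood structural equation modeling engine.

Models are recursive path diagrams over a handful of observed variables
(plus optional latent variables with fixed unit variance), parameterized in
RAM form: a path matrix A (A[i, j] = coefficient of j -> i), a diagonal
matrix S of exogenous/residual variances, and a filter F selecting the
observed rows of the implied covariance

    Sigma = F (I - A)^-1 S (I - A)^-T F^T.

Fitting minimizes the ML discrepancy

    F_ML(theta) = log det Sigma + tr(S_obs Sigma^-1) - log det S_obs - p,

so the model chi-square is (n - 1) * F_min with df = #distinct moments -
#free parameters. Standard errors come from the inverse numerical Hessian
of the log-likelihood at the optimum; path Z statistics are estimate / SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["PathModel", "SemFit", "fit_sem"]

_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class PathModel:
    """A directed acyclic path diagram.

    Parameters
    ----------
    observed
        Names of observed variables, in the order of the covariance matrix
        handed to :func:`fit_sem`.
    edges
        Directed free paths ``(source, target)``.
    latents
        Latent variable names; each latent gets a fixed unit variance
        (its scale) unless it appears in ``fixed_variances``.
    fixed_variances
        Mapping variable -> fixed (residual) variance. Variables not listed
        get a free variance parameter.
    name
        Label used in reports.
    """

    observed: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    latents: tuple[str, ...] = ()
    fixed_variances: dict = field(default_factory=dict)
    residual_covariances: tuple[tuple[str, str], ...] = ()
    name: str = "model"

    def __post_init__(self) -> None:
        order = self.variables
        for s, t in self.edges:
            if s not in order or t not in order:
                raise ValueError(f"edge {s}->{t} references unknown variable")
        # reject cycles (recursive models only)
        import collections

        children = collections.defaultdict(list)
        indeg = {v: 0 for v in order}
        for s, t in self.edges:
            children[s].append(t)
            indeg[t] += 1
        queue = [v for v in order if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(order):
            raise ValueError("path diagram contains a cycle")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.observed) + tuple(self.latents)

    @property
    def free_variances(self) -> tuple[str, ...]:
        fixed = set(self.fixed_variances)
        default_fixed = {v for v in self.latents if v not in self.fixed_variances}
        return tuple(
            v for v in self.variables if v not in fixed and v not in default_fixed
        )

    @property
    def n_parameters(self) -> int:
        return (
            len(self.edges)
            + len(self.free_variances)
            + len(self.residual_covariances)
        )

    def degrees_of_freedom(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_parameters


@dataclass
class SemFit:
    model: PathModel
    chi_square: float
    df: int
    p: float
    estimates: dict
    standard_errors: dict
    converged: bool
    implied: np.ndarray
    n: int

    def z(self, source: str, target: str) -> float:
        """Z statistic (estimate / SE) of a fitted path."""
        key = f"{source}->{target}"
        se = self.standard_errors.get(key, np.nan)
        if not np.isfinite(se) or se == 0:
            return np.nan
        return self.estimates[key] / se


def _implied_sigma(model: PathModel, theta: np.ndarray) -> np.ndarray:
    order = model.variables
    idx = {v: i for i, v in enumerate(order)}
    m = len(order)
    A = np.zeros((m, m))
    ne = len(model.edges)
    for (s, t), coef in zip(model.edges, theta[:ne]):
        A[idx[t], idx[s]] = coef
    svec = np.zeros(m)
    for v, val in model.fixed_variances.items():
        svec[idx[v]] = val
    for v in model.latents:
        if v not in model.fixed_variances:
            svec[idx[v]] = 1.0
    nv = len(model.free_variances)
    for v, val in zip(model.free_variances, theta[ne : ne + nv]):
        svec[idx[v]] = val
    Smat = np.diag(svec)
    for (u, v), val in zip(model.residual_covariances, theta[ne + nv :]):
        Smat[idx[u], idx[v]] = Smat[idx[v], idx[u]] = val
    inv = np.linalg.inv(np.eye(m) - A)
    sigma_all = inv @ Smat @ inv.T
    p = len(model.observed)
    return sigma_all[:p, :p]


def _discrepancy(model: PathModel, theta, S, logdet_s) -> float:
    sigma = _implied_sigma(model, theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    try:
        solved = np.linalg.solve(sigma, S)
    except np.linalg.LinAlgError:
        return 1e10
    return float(logdet + np.trace(solved) - logdet_s - S.shape[0])


def _start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Regression-flavoured startup: each path starts at the simple slope of
    target on source (0.3 when a latent is involved); free variances start
    at the observed variance (or half of it for endogenous variables)."""
    obs_idx = {v: i for i, v in enumerate(model.observed)}
    endogenous = {t for _, t in model.edges}
    theta = []
    for s, t in model.edges:
        if s in obs_idx and t in obs_idx:
            theta.append(S[obs_idx[t], obs_idx[s]] / S[obs_idx[s], obs_idx[s]])
        else:
            theta.append(0.3)
    for v in model.free_variances:
        var = S[obs_idx[v], obs_idx[v]] if v in obs_idx else 1.0
        theta.append(var * (0.5 if v in endogenous else 1.0))
    for u, v in model.residual_covariances:
        if u in obs_idx and v in obs_idx:
            theta.append(0.5 * S[obs_idx[u], obs_idx[v]])
        else:
            theta.append(0.0)
    return np.asarray(theta, dtype=float)


def fit_sem(
    model: PathModel,
    cov: np.ndarray,
    n: int,
    compute_se: bool = True,
    tol: float = 1e-10,
) -> SemFit:
    """Fit a path model to an observed covariance matrix by ML.

    ``cov`` rows/columns follow ``model.observed``. Raises on a
    non-identified spec (df < 0); non-convergence is flagged on the result
    rather than raised.
    """
    S = np.asarray(cov, dtype=float)
    p = len(model.observed)
    if S.shape != (p, p):
        raise ValueError("covariance shape does not match observed variables")
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("observed covariance not positive-definite")
    df = model.degrees_of_freedom()
    if df < 0:
        raise ValueError(f"model {model.name!r} not identified (df={df})")

    ne = len(model.edges)
    bounds = (
        [(None, None)] * ne
        + [(_VAR_FLOOR, None)] * len(model.free_variances)
        + [(None, None)] * len(model.residual_covariances)
    )
    x0 = _start_values(model, S)
    nv = len(model.free_variances)
    x0[ne : ne + nv] = np.maximum(x0[ne : ne + nv], _VAR_FLOOR * 10)

    res = optimize.minimize(
        lambda th: _discrepancy(model, th, S, logdet_s),
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": tol, "gtol": 1e-9, "maxiter": 500},
    )
    fmin = max(float(res.fun), 0.0)
    chi2 = (n - 1) * fmin
    pval = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))

    names = (
        [f"{s}->{t}" for s, t in model.edges]
        + [f"var({v})" for v in model.free_variances]
        + [f"cov({u},{v})" for u, v in model.residual_covariances]
    )
    estimates = dict(zip(names, res.x))
    ses: dict[str, float] = {k: np.nan for k in names}
    if compute_se:
        H = _numerical_hessian(
            lambda th: 0.5 * (n - 1) * _discrepancy(model, th, S, logdet_s), res.x
        )
        try:
            cov_theta = np.linalg.inv(H)
            d = np.diag(cov_theta)
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.where(d > 0, d, np.nan))
            ses = dict(zip(names, se))
        except np.linalg.LinAlgError:
            pass

    return SemFit(
        model=model,
        chi_square=chi2,
        df=df,
        p=pval,
        estimates=estimates,
        standard_errors=ses,
        converged=bool(res.success),
        implied=_implied_sigma(model, res.x),
        n=n,
    )


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth ML discrepancy."""
    k = x.size
    H = np.empty((k, k))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H
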