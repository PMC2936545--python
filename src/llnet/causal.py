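"""SEM-based network edge orientation with genetic anchors.

Genotype cannot be caused by phenotype, so a SNP robustly associated with a
node ("causal anchor") breaks the symmetry of an undirected correlation
edge. For an edge A-B with orthogonal anchors M_A and M_B, five competing
path models are fitted to the (M_A, A, B, M_B) covariance:

    1. causal      M_A -> A -> B <- M_B
    2. reactive    M_A -> A <- B <- M_B
    3. confounded  M_A -> A <- C -> B <- M_B   (hidden confounder C, fitted
       as a free residual covariance between A and B, the identified
       equivalent of a unit-variance latent with free loadings)
    4. pleiotropy  M_A -> A, M_B -> B, M_A -> B   (no A-B edge)
    5. pleiotropy  M_A -> A, M_B -> B, M_B -> A   (no A-B edge)

The LEO.NB.OCA score is log10 of the causal model's fit P value over the
best (largest-P) competing model; a score >= 0.3 orients the edge A -> B.
An edge exists when |Pearson(A, B)| > 0.3, and the orientation additionally
requires the fitted A -> B path Z statistic to exceed 1.96 in magnitude;
when the causal model's own fit P is <= 0.05 the orientation is flagged as
resting on a poorly fitting model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sem import PathModel, SemFit, fit_sem

__all__ = [
    "LEOResult",
    "oca_models",
    "leo_nb_oca",
    "orient_network",
    "anchor_autoselect",
]

EDGE_THRESHOLD = 0.3
LEO_THRESHOLD = 0.3
PATH_Z_THRESHOLD = 1.96
_P_FLOOR = 1e-300


def oca_models() -> dict[str, PathModel]:
    """The five competing models over (M_A, A, B, M_B); generic names."""
    obs = ("MA", "A", "B", "MB")
    return {
        "causal": PathModel(obs, (("MA", "A"), ("A", "B"), ("MB", "B")), name="causal"),
        "reactive": PathModel(obs, (("MA", "A"), ("B", "A"), ("MB", "B")), name="reactive"),
        "confounded": PathModel(
            obs,
            (("MA", "A"), ("MB", "B")),
            residual_covariances=(("A", "B"),),
            name="confounded",
        ),
        "pleiotropy_a": PathModel(
            obs, (("MA", "A"), ("MB", "B"), ("MA", "B")), name="pleiotropy_a"
        ),
        "pleiotropy_b": PathModel(
            obs, (("MA", "A"), ("MB", "B"), ("MB", "A")), name="pleiotropy_b"
        ),
    }


@dataclass
class LEOResult:
    edge: tuple[str, str]  # (A, B) meaning A -> B
    leo: float
    causal_p: float
    pearson: float
    path_z: float
    verdict: str  # causal / inconclusive / rejected
    weak_anchor: bool
    poor_fit: bool
    model_p: dict
    fits: dict

    def as_row(self) -> dict:
        return {
            "edge": f"{self.edge[0]}->{self.edge[1]}",
            "leo": self.leo,
            "model_p": self.causal_p,
            "pearson": self.pearson,
            "path_z": self.path_z,
            "verdict": self.verdict,
            "weak_anchor": self.weak_anchor,
            "poor_fit": self.poor_fit,
        }


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std()


def leo_nb_oca(
    a,
    b,
    m_a,
    m_b,
    names: tuple[str, str] = ("A", "B"),
    edge_threshold: float = EDGE_THRESHOLD,
    leo_threshold: float = LEO_THRESHOLD,
    compute_se: bool = True,
) -> LEOResult:
    """Score the orientation A -> B from data vectors and anchor dosages.

    All four variables are standardized before fitting (reported Pearson
    and path statistics are therefore on the correlation scale). Returns
    the LEO.NB.OCA score, the causal-model fit P, the edge score, the
    A -> B path Z, and the verdict at the stated thresholds.
    """
    cols = [np.asarray(v, dtype=float) for v in (m_a, a, b, m_b)]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("all variables must share the sample index")
    X = np.column_stack([_standardize(c) for c in cols])
    S = np.cov(X, rowvar=False, ddof=1)

    pearson = float(S[1, 2] / np.sqrt(S[1, 1] * S[2, 2]))
    weak = abs(S[0, 1]) < edge_threshold or abs(S[3, 2]) < edge_threshold

    fits: dict[str, SemFit] = {}
    for key, model in oca_models().items():
        fits[key] = fit_sem(model, S, n, compute_se=(compute_se and key == "causal"))
    model_p = {k: f.p for k, f in fits.items()}
    p_causal = max(model_p["causal"], _P_FLOOR)
    p_next = max(max(v for k, v in model_p.items() if k != "causal"), _P_FLOOR)
    leo = float(np.log10(p_causal / p_next))
    path_z = fits["causal"].z("A", "B") if compute_se else np.nan

    poor_fit = model_p["causal"] <= 0.05
    if abs(pearson) <= edge_threshold:
        verdict = "rejected"
    elif leo >= leo_threshold and (not compute_se or abs(path_z) > PATH_Z_THRESHOLD):
        verdict = "causal"
    else:
        verdict = "inconclusive"
    return LEOResult(
        edge=names,
        leo=leo,
        causal_p=model_p["causal"],
        pearson=pearson,
        path_z=path_z,
        verdict=verdict,
        weak_anchor=weak,
        poor_fit=poor_fit,
        model_p=model_p,
        fits=fits,
    )


def orient_network(
    nodes: dict[str, pd.Series],
    anchors: dict[str, pd.Series],
    edge_threshold: float = EDGE_THRESHOLD,
    leo_threshold: float = LEO_THRESHOLD,
) -> pd.DataFrame:
    """Orient every node pair passing the edge score threshold.

    ``nodes`` maps node name -> per-sample values (trait Z-scores or
    expression); ``anchors`` maps node name -> its anchor SNP dosages on
    the same samples. Both directions of each qualifying edge are scored;
    the report also classifies edges for display: ``causal`` (solid),
    ``inconclusive`` (grey), with ``poor_fit`` marking orientations whose
    causal model itself fits at P < 0.05 (dotted).
    """
    missing = [k for k in nodes if k not in anchors]
    if missing:
        raise ValueError(f"nodes without anchors: {missing}")
    names = list(nodes)
    index = None
    for s in nodes.values():
        index = s.index if index is None else index.intersection(s.index)
    rows = []
    for na, nb in itertools.combinations(names, 2):
        a = nodes[na].loc[index]
        b = nodes[nb].loc[index]
        r = float(np.corrcoef(a, b)[0, 1])
        if abs(r) <= edge_threshold:
            continue
        for src, dst in ((na, nb), (nb, na)):
            res = leo_nb_oca(
                nodes[src].loc[index],
                nodes[dst].loc[index],
                anchors[src].loc[index],
                anchors[dst].loc[index],
                names=(src, dst),
                edge_threshold=edge_threshold,
                leo_threshold=leo_threshold,
            )
            rows.append(res.as_row())
    return pd.DataFrame(
        rows,
        columns=[
            "edge", "leo", "model_p", "pearson", "path_z", "verdict",
            "weak_anchor", "poor_fit",
        ],
    )


def anchor_autoselect(
    node: pd.Series,
    candidates: pd.DataFrame,
    method: str = "greedy",
    alpha: float = 0.05,
    other_nodes: dict[str, pd.Series] | None = None,
) -> dict:
    """Select anchor SNPs for a node from a candidate pool.

    ``greedy`` picks the single best-P SNP by simple regression of the node
    on dosage; ``forward-stepwise`` keeps adding the SNP with the smallest
    partial-F P value while that P is below ``alpha``. When
    ``other_nodes`` is given, each selected SNP is checked to associate
    most strongly (smallest P) with this node; offenders are flagged.
    """
    if candidates.shape[1] == 0:
        raise ValueError("empty candidate SNP pool")
    if method not in ("greedy", "forward-stepwise"):
        raise ValueError(f"unknown method {method!r}")
    y = node.to_numpy(dtype=float)
    n = y.size

    def marginal_p(series) -> float:
        g = np.asarray(series, dtype=float)
        if np.ptp(g) == 0:
            return 1.0
        r = float(np.corrcoef(g, y)[0, 1])
        r = min(abs(r), 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r * r))
        return 2.0 * stats.t.sf(t, df=n - 2)

    pvals = {snp: marginal_p(candidates[snp]) for snp in candidates.columns}
    if method == "greedy":
        selected = [min(pvals, key=pvals.get)]
    else:
        selected = []
        X = np.ones((n, 1))
        remaining = list(candidates.columns)
        while remaining:
            best_snp, best_p = None, 1.0
            rss0 = float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
            for snp in remaining:
                Xt = np.column_stack([X, candidates[snp].to_numpy(float)])
                beta, *_ = np.linalg.lstsq(Xt, y, rcond=None)
                rss1 = float(((y - Xt @ beta) ** 2).sum())
                df2 = n - Xt.shape[1]
                if rss1 <= 0 or df2 <= 0:
                    continue
                F = (rss0 - rss1) / (rss1 / df2)
                p = float(stats.f.sf(F, 1, df2))
                if p < best_p:
                    best_snp, best_p = snp, p
            if best_snp is None or best_p >= alpha:
                break
            selected.append(best_snp)
            X = np.column_stack([X, candidates[best_snp].to_numpy(float)])
            remaining.remove(best_snp)
        if not selected:  # fall back to the marginal best, flagged weak
            selected = [min(pvals, key=pvals.get)]

    flags = []
    if other_nodes:
        for snp in selected:
            g = candidates[snp]
            own = pvals[snp]
            for other_name, other in other_nodes.items():
                r = float(np.corrcoef(g, other.to_numpy(float))[0, 1])
                r = min(abs(r), 1 - 1e-15)
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p_other = 2.0 * stats.t.sf(t, df=n - 2)
                if p_other < own:
                    flags.append((snp, other_name))
    return {
        "anchors": selected,
        "marginal_p": {s: pvals[s] for s in selected},
        "cross_assignment_flags": flags,
    }
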