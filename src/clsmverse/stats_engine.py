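"""The statistical multiverse: similarity, add-one delta-R2 grids, sparse CCA.

Every brain-behaviour cell follows the same recipe. A base OLS model predicts
the outcome (naming or Token score) from total lesion size and a dummy-coded
scanner covariate. One candidate metric is then added, and the cell records
the R-squared improvement, the F-test p-value of the added term, and a
significance class at the conventional uncorrected thresholds:

* significant: p < 0.05
* marginal:    0.05 <= p < 0.10
* ns:          otherwise

Missing-data policy is per-metric complete cases: the base model is refit on
exactly the rows where the metric is observed, so the nested models always
compare on identical data (direct tract metrics can be missing when a tract
was unreconstructable). No familywise correction is applied anywhere -- the
point of a multiverse grid is the pattern of cells, not any single p-value.

Sparse CCA relates a vectorized connectome edge matrix to lesion-size- and
scanner-residualised behaviour via a penalized-matrix-decomposition sparse
weight vector; model fit is judged by 4-fold cross-validation, pooling the
held-out predictions and correlating them with the observed scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core_io import Connectome

logger = logging.getLogger("clsmverse")

SIGNIFICANT, MARGINAL, NS = "significant", "marginal", "ns"
GRAPH_NETWORKS = ("direct_whole", "direct_roi", "indirect_whole", "indirect_roi")


def classify_p(p: float) -> str:
    if np.isnan(p):
        return NS
    if p < 0.05:
        return SIGNIFICANT
    if p < 0.10:
        return MARGINAL
    return NS


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected); NaN for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.kendalltau(x, y).statistic)


@dataclass
class SimilarityReport:
    """Per-participant direct-vs-indirect edge correlations per scale."""

    taus: dict[str, np.ndarray]
    medians: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    n_edges: dict[str, int]
    paired_t: float = float("nan")
    paired_p: float = float("nan")


def connectome_similarity(
    pairs_by_scale: dict[str, tuple[Sequence[Connectome], Sequence[Connectome]]],
) -> SimilarityReport:
    """Edge-wise Kendall tau between each participant's direct and indirect
    connectomes, per scale, plus a paired t-test across participants
    comparing the scales (when exactly two scales are given).

    ``pairs_by_scale`` maps scale name -> (direct list, indirect list), one
    connectome per participant in matching order. Participants missing one
    of the two connectomes (None entries) are dropped with a log message.
    """
    taus: dict[str, np.ndarray] = {}
    medians, ranges, n_edges = {}, {}, {}
    for scale, (directs, indirects) in pairs_by_scale.items():
        if len(directs) != len(indirects):
            raise ValueError(f"scale {scale!r}: direct/indirect participant lists differ")
        vals = []
        for i, (d, ind) in enumerate(zip(directs, indirects)):
            if d is None or ind is None:
                logger.info("stage=similarity scale=%s participant=%d dropped", scale, i)
                continue
            if d.node_ids != ind.node_ids:
                raise ValueError("direct/indirect connectomes must share node sets")
            vals.append(kendall_tau(d.upper_values(), ind.upper_values()))
            n_edges[scale] = len(d.upper_values())
        arr = np.asarray(vals)
        taus[scale] = arr
        ok = arr[~np.isnan(arr)]
        medians[scale] = float(np.median(ok)) if len(ok) else float("nan")
        ranges[scale] = (
            (float(ok.min()), float(ok.max())) if len(ok) else (float("nan"), float("nan"))
        )
    report = SimilarityReport(taus=taus, medians=medians, ranges=ranges, n_edges=n_edges)
    if len(pairs_by_scale) == 2:
        a, b = (taus[s] for s in pairs_by_scale)
        if len(a) == len(b) and len(a) >= 2:
            diff = a - b
            if np.allclose(diff, 0):
                report.paired_t, report.paired_p = 0.0, float("nan")
            else:
                t = sps.ttest_rel(a, b, nan_policy="omit")
                report.paired_t, report.paired_p = float(t.statistic), float(t.pvalue)
    return report


def metric_correlations(df: pd.DataFrame, method: str = "kendall") -> pd.DataFrame:
    """Pairwise-complete correlation matrix over metric columns.

    Cells with fewer than 3 complete pairs are NaN. ``method`` is
    ``"kendall"`` (tau-b, default: connectivity metrics are often skewed) or
    ``"pearson"``.
    """
    if method not in ("pearson", "kendall"):
        raise ValueError("method must be 'pearson' or 'kendall'")
    return df.corr(method=method, min_periods=3)


# ---------------------------------------------------------------------------
# base model and add-one cells
# ---------------------------------------------------------------------------


@dataclass
class BaseFit:
    result: object  # statsmodels RegressionResults
    design: pd.DataFrame
    rows: np.ndarray  # boolean mask into the original table

    @property
    def r2(self) -> float:
        return float(self.result.rsquared)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)


def _base_design(lesion_size: np.ndarray, scanner: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"lesion_size": np.asarray(lesion_size, dtype=float)})
    dummies = pd.get_dummies(pd.Series(scanner).astype(str), prefix="scanner", drop_first=True)
    X = pd.concat([X, dummies.set_index(X.index).astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_base(
    outcome: Sequence[float],
    lesion_size: Sequence[float],
    scanner: Sequence[str],
    rows: np.ndarray | None = None,
) -> BaseFit:
    """OLS of the outcome on intercept + lesion size + scanner dummies.

    Scanner uses reference-level coding on the levels present in the rows
    actually used; with a single level the dummy block is empty and the
    model reduces to lesion size only. A rank-deficient design raises.
    """
    y = np.asarray(outcome, dtype=float)
    lesion_size = np.asarray(lesion_size, dtype=float)
    scanner = np.asarray(scanner, dtype=object)
    if rows is None:
        rows = np.isfinite(y) & np.isfinite(lesion_size)
    y, lesion_size, scanner = y[rows], lesion_size[rows], scanner[rows]
    X = _base_design(lesion_size, scanner)
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few observations for the base model")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular base design (collinear covariates)")
    res = sm.OLS(y, X).fit()
    return BaseFit(result=res, design=X, rows=rows)


def residualize(
    outcome: Sequence[float],
    lesion_size: Sequence[float],
    scanner: Sequence[str],
) -> np.ndarray:
    """OLS residuals of the outcome after lesion size and scanner."""
    return fit_base(outcome, lesion_size, scanner).residuals


@dataclass
class MultiverseCell:
    outcome: str
    metric_id: str
    n: int
    delta_r2: float
    p_value: float
    klass: str


def add_one(
    outcome: Sequence[float],
    lesion_size: Sequence[float],
    scanner: Sequence[str],
    metric: Sequence[float],
    outcome_name: str = "outcome",
    metric_id: str = "metric",
) -> MultiverseCell:
    """One multiverse cell: refit base on the metric's complete cases, add
    the metric, record delta R-squared and the F-test p of the added term.

    A metric collinear with the base covariates yields delta_r2 = 0 and class
    ``ns`` with a warning.
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(metric, dtype=float)
    lesion_size = np.asarray(lesion_size, dtype=float)
    rows = np.isfinite(y) & np.isfinite(m) & np.isfinite(lesion_size)
    base = fit_base(y, lesion_size, scanner, rows=rows)
    X_full = base.design.copy()
    X_full["metric"] = m[rows]
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        warnings.warn(f"metric {metric_id!r} collinear with base covariates")
        return MultiverseCell(outcome_name, metric_id, int(rows.sum()), 0.0, float("nan"), NS)
    full = sm.OLS(y[rows], X_full).fit()
    delta = max(0.0, float(full.rsquared) - base.r2)
    fstat, p, _ = full.compare_f_test(base.result)
    p = float(p)
    return MultiverseCell(
        outcome=outcome_name,
        metric_id=metric_id,
        n=int(rows.sum()),
        delta_r2=delta,
        p_value=p,
        klass=classify_p(p),
    )


def _cells_to_frame(cells: list[MultiverseCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": [c.outcome for c in cells],
            "metric_id": [c.metric_id for c in cells],
            "n": [c.n for c in cells],
            "delta_r2": [c.delta_r2 for c in cells],
            "p_value": [c.p_value for c in cells],
            "class": [c.klass for c in cells],
        }
    )


def multiverse_grid_tracts(
    metrics: pd.DataFrame,
    behavior: pd.DataFrame,
    outcomes: Sequence[str] = ("naming", "token"),
) -> pd.DataFrame:
    """Tract-based multiverse: one cell per (outcome, tract, metric).

    ``metrics`` is the participants x (tract, metric) matrix; ``behavior``
    carries ``naming``, ``token``, ``lesion_cc`` and ``scanner`` aligned to
    the same participants. With the six default tracts and eight measures
    this emits 6 x 8 x 2 = 96 cells.
    """
    cells = []
    for outcome in outcomes:
        for tract, metric in metrics.columns:
            cells.append(
                add_one(
                    behavior[outcome],
                    behavior["lesion_cc"],
                    behavior["scanner"],
                    metrics[(tract, metric)],
                    outcome_name=outcome,
                    metric_id=f"{tract}:{metric}",
                )
            )
    return _cells_to_frame(cells)


def multiverse_grid_graph(
    graph_metrics: pd.DataFrame,
    behavior: pd.DataFrame,
    outcomes: Sequence[str] = ("naming", "token"),
) -> pd.DataFrame:
    """Network-based multiverse: one cell per (outcome, network, graph metric).

    ``graph_metrics`` has MultiIndex columns (network, metric) with networks
    like direct/indirect x whole/roi; 4 networks x 6 metrics x 2 outcomes
    gives 48 cells.
    """
    cells = []
    for outcome in outcomes:
        for network, metric in graph_metrics.columns:
            cells.append(
                add_one(
                    behavior[outcome],
                    behavior["lesion_cc"],
                    behavior["scanner"],
                    graph_metrics[(network, metric)],
                    outcome_name=outcome,
                    metric_id=f"{network}:{metric}",
                )
            )
    return _cells_to_frame(cells)


def plot_multiverse(cells: pd.DataFrame, path: str) -> None:
    """Grid plot of delta-R2 cells coloured by significance class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {SIGNIFICANT: "#2c7fb8", MARGINAL: "#fec44f", NS: "#756bb1"}
    outcomes = list(dict.fromkeys(cells["outcome"]))
    fig, axes = plt.subplots(1, len(outcomes), figsize=(6 * len(outcomes), 4), squeeze=False)
    for ax, outcome in zip(axes[0], outcomes):
        sub = cells[cells["outcome"] == outcome]
        ax.bar(
            range(len(sub)),
            sub["delta_r2"],
            color=[colors[k] for k in sub["class"]],
        )
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["metric_id"], rotation=90, fontsize=6)
        ax.set_ylabel("delta R2")
        ax.set_title(outcome)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# sparse CCA
# ---------------------------------------------------------------------------


@dataclass
class SparseCcaResult:
    weights: np.ndarray  # full-data X-side weight vector
    edge_names: list[str]
    fold_of: np.ndarray  # fold index per participant
    predicted: np.ndarray  # pooled held-out predictions
    cv_r: float
    p_value: float


def _pmd_weights_batch(A: np.ndarray, sparsity: float) -> np.ndarray:
    """Column-wise X-side weights of a rank-1 penalized matrix decomposition.

    Each column a of A (p x m) is the covariance vector X' y for one response;
    the solution maximises w' a subject to ||w||_2 = 1 and ||w||_1 <= c, with
    the L1 budget c interpolating between 1 (sparsest) and sqrt(p) (dense) as
    ``sparsity`` goes from 0 to 1. The soft threshold per column is found by
    vectorised bisection.
    """
    A = np.atleast_2d(A)
    p = A.shape[0]
    c = 1.0 + sparsity * (np.sqrt(p) - 1.0)
    absA = np.abs(A)
    norm = np.linalg.norm(A, axis=0)
    dead = norm == 0
    norm[dead] = 1.0
    W = A / norm
    need = np.abs(W).sum(axis=0) > c
    if need.any():
        a = absA[:, need]
        lo = np.zeros(a.shape[1])
        hi = a.max(axis=0)
        for _ in range(50):
            mid = (lo + hi) / 2
            ws = np.maximum(a - mid, 0.0)
            l2 = np.linalg.norm(ws, axis=0)
            l2[l2 == 0] = np.inf
            too_dense = np.abs(ws).sum(axis=0) / l2 > c
            lo = np.where(too_dense, mid, lo)
            hi = np.where(too_dense, hi, mid)
        ws = np.maximum(a - hi, 0.0) * np.sign(A[:, need])
        l2 = np.linalg.norm(ws, axis=0)
        l2[l2 == 0] = 1.0
        W[:, need] = ws / l2
    W[:, dead] = 0.0
    return W


def _pmd_weights(X: np.ndarray, y: np.ndarray, sparsity: float) -> np.ndarray:
    return _pmd_weights_batch((X.T @ y)[:, None], sparsity)[:, 0]


def _columnwise_corr(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    Yc = Y - Y.mean(axis=0)
    Pc = P - P.mean(axis=0)
    denom = np.linalg.norm(Yc, axis=0) * np.linalg.norm(Pc, axis=0)
    out = np.zeros(Y.shape[1])
    ok = denom > 0
    out[ok] = (Yc * Pc).sum(axis=0)[ok] / denom[ok]
    return out


def sparse_cca(
    X: np.ndarray,
    y: Sequence[float],
    sparsity: float = 0.3,
    folds: int = 4,
    seed: int = 0,
    n_permutations: int = 499,
    edge_names: Sequence[str] | None = None,
) -> SparseCcaResult:
    """Sparse CCA of an edge matrix against residualised behaviour.

    Columns of X are standardised on each training split; the held-out
    predictions X_test @ w are pooled over folds and the cross-validated fit
    is the Pearson correlation between observed and predicted scores.

    Significance comes from a permutation test: the behaviour vector is
    permuted and the *entire* cross-validation is re-run for each permutation
    (two-sided on |r|). A parametric Pearson p-value on the pooled
    predictions is anticonservative here, because predictions in different
    folds share training data; the permutation null accounts for that
    dependence exactly. ``seed`` controls fold assignment and permutations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    if n < folds:
        raise ValueError(f"need at least {folds} participants for {folds}-fold CV")
    if edge_names is None:
        edge_names = [f"e{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % folds

    def standardise(A: np.ndarray):
        mu = A.mean(axis=0)
        sd = A.std(axis=0)
        sd[sd == 0] = 1.0
        return mu, sd

    # column 0 is the observed outcome; the rest are permutations of it
    Y = np.empty((n, 1 + n_permutations))
    Y[:, 0] = y
    for j in range(n_permutations):
        Y[:, j + 1] = y[rng.permutation(n)]

    P = np.zeros_like(Y)
    for k in range(folds):
        test = fold_of == k
        mu, sd = standardise(X[~test])
        Xs_tr = (X[~test] - mu) / sd
        Xs_te = (X[test] - mu) / sd
        Ytr = Y[~test]
        W = _pmd_weights_batch(Xs_tr.T @ (Ytr - Ytr.mean(axis=0)), sparsity)
        P[test] = Xs_te @ W
    r_all = _columnwise_corr(Y, P)
    cv_r = float(r_all[0])
    if n_permutations:
        p_value = float((1 + np.sum(np.abs(r_all[1:]) >= abs(cv_r))) / (n_permutations + 1))
    else:
        p_value = float(sps.pearsonr(y, P[:, 0]).pvalue) if np.std(P[:, 0]) > 0 else 1.0
    mu, sd = standardise(X)
    w_full = _pmd_weights((X - mu) / sd, y - y.mean(), sparsity)
    return SparseCcaResult(
        weights=w_full,
        edge_names=list(edge_names),
        fold_of=fold_of,
        predicted=P[:, 0],
        cv_r=cv_r,
        p_value=p_value,
    )
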