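"""Connectome-based predictive modelling (CPM) core.

The CPM pipeline per cross-validation fold:

1. *edge selection* — mass-univariate (partial) correlation of every
   unique edge with the target in the training subjects; edges with
   ``p < threshold`` split by correlation sign into a positive-tail and a
   negative-tail mask;
2. *network strength* — per subject, the sum of connectivity over each
   selected edge set (full-matrix sum halved, i.e. each unique edge
   counted once); combined strength = positive minus negative strength;
3. *model fitting* — a simple linear model target ~ strength per tail;
4. *model application* — held-out subjects' strengths pushed through the
   fold's lines;
5. *model evaluation* — Pearson r, R-squared and MAE of out-of-fold
   predictions against the observed target.

Cross-validation schemes: leave-one-out and repeated k-fold. A trained
model can be aggregated across folds (consensus masks, averaged line
parameters) and applied to an external cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectivityMatrix

__all__ = [
    "EdgeMaskPair",
    "FoldModel",
    "CPMFoldModels",
    "AggregateModel",
    "PredictionSet",
    "MetricsTriple",
    "ExternalResult",
    "RepeatedKFoldResult",
    "OptimizationResult",
    "TAILS",
    "DEFAULT_THRESHOLD_GRID",
    "edge_matrix",
    "select_edges",
    "network_strength",
    "combined_strength",
    "fit_strength_model",
    "run_loocv",
    "run_repeated_kfold",
    "optimize_threshold",
    "aggregate_model",
    "apply_external",
    "evaluate",
]

TAILS = ("positive", "negative", "combined")

#: Default p-value grid for edge-selection-threshold optimisation.
DEFAULT_THRESHOLD_GRID = (0.0001, 0.0005, 0.0009, 0.001, 0.005, 0.01, 0.05)

EDGE_ORDER = "upper-triangle row-major (i<j)"


# ---------------------------------------------------------------------------
# edge vectorisation
# ---------------------------------------------------------------------------

def edge_matrix(
    matrices: Sequence[ConnectivityMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject matrices into a unique-edge x subject matrix.

    Edges are ordered row-major over the upper triangle (i < j) of the
    node-label-sorted matrix; all subjects must share one node roster.

    Returns
    -------
    (X, node_ids) : (ndarray of shape (n_edges, n_subjects), ndarray)
    """
    if not matrices:
        raise ValueError("no connectivity matrices given")
    node_ids = matrices[0].node_ids
    for m in matrices[1:]:
        if not np.array_equal(m.node_ids, node_ids):
            raise ValueError("connectivity matrices have mismatching node rosters")
    X = np.column_stack([m.edge_vector() for m in matrices])
    return X, node_ids.copy()


def _as_covariate_array(
    covariates, n: int
) -> tuple[np.ndarray | None, list[str]]:
    if covariates is None:
        return None, []
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"cov_{j}" for j in range(C.shape[1])]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match number of subjects")
    if not np.isfinite(C).all():
        raise ValueError("covariates contain non-finite values")
    return C, names


def _edge_stats(
    X: np.ndarray, y: np.ndarray, C: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised per-edge (partial) Pearson r and two-sided p vs target.

    With covariates, both each edge and the target are residualised on
    [1, C] and the residuals correlated; degrees of freedom are
    ``n - 2 - n_covariates``. p-values come from the exact t
    transformation ``t = r sqrt(df / (1 - r^2))``.
    """
    n = y.shape[0]
    n_cov = 0 if C is None else C.shape[1]
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError("too few subjects for the requested correlation test")
    if np.ptp(y) == 0:
        raise ValueError("target is constant")

    if C is None:
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
    else:
        design = np.column_stack([np.ones(n), C])
        q, _ = np.linalg.qr(design)
        yc = y - q @ (q.T @ y)
        if np.ptp(yc) == 0 or float(yc @ yc) < 1e-12 * n * np.var(y):
            raise ValueError("target is collinear with the covariates")
        xc = X - (X @ q) @ q.T

    ynorm = np.sqrt(yc @ yc)
    xnorm = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (xnorm * ynorm)
    r = np.where(xnorm == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    t = np.where(np.abs(r) == 1.0, np.inf * np.sign(r), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(xnorm == 0, 1.0, p)
    return r, p, df


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EdgeMaskPair:
    """Signed edge-selection result over unique edges.

    ``pos``/``neg`` are disjoint boolean vectors in upper-triangle
    row-major order; ``r`` and ``p`` hold the per-edge statistic used for
    selection.
    """

    pos: np.ndarray
    neg: np.ndarray
    r: np.ndarray
    p: np.ndarray
    threshold: float
    node_ids: np.ndarray | None

    def __post_init__(self) -> None:
        if np.any(self.pos & self.neg):
            raise ValueError("positive and negative masks must be disjoint")

    @property
    def n_nodes(self) -> int:
        if self.node_ids is None:
            raise ValueError("mask pair has no node roster")
        return int(self.node_ids.shape[0])

    @property
    def n_pos(self) -> int:
        return int(self.pos.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg.sum())

    def _to_matrix(self, vec: np.ndarray) -> np.ndarray:
        n = self.n_nodes
        m = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        m[iu, ju] = vec
        m[ju, iu] = vec
        return m

    @property
    def positive_matrix(self) -> np.ndarray:
        """Symmetric binary n x n matrix of the positive tail."""
        return self._to_matrix(self.pos.astype(float))

    @property
    def negative_matrix(self) -> np.ndarray:
        return self._to_matrix(self.neg.astype(float))


@dataclass
class FoldModel:
    """One cross-validation fold: masks, per-tail line, held-out indices."""

    masks: EdgeMaskPair
    params: dict  # tail -> (intercept, slope) or None when undefined
    fallback: dict  # tail -> training-target mean used when params is None
    test_indices: np.ndarray


@dataclass
class CPMFoldModels:
    """All folds of one cross-validated CPM run."""

    folds: list[FoldModel]
    fold_assignment: np.ndarray
    threshold: float
    covariate_names: list[str]
    node_ids: np.ndarray

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class PredictionSet:
    """Observed target and out-of-fold predictions per network-strength tail."""

    observed: np.ndarray
    predicted: dict  # tail -> ndarray aligned with observed
    subject_ids: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        data = {"observed": self.observed}
        for tail in TAILS:
            data[f"predicted_{tail}"] = self.predicted[tail]
        if self.subject_ids is not None:
            data = {"subject_id": self.subject_ids, **data}
        return pd.DataFrame(data)


@dataclass
class MetricsTriple:
    """Prediction accuracy: Pearson r, R-squared, mean absolute error.

    ``r2`` is the coefficient of determination from regressing observed
    on predicted; with a single predictor and intercept it equals the
    squared Pearson correlation, so the two conventions coincide here.
    ``r`` and ``r2`` are None (with ``note`` giving the reason) when
    either input is constant; ``mae`` is always defined.
    """

    r: float | None
    r2: float | None
    mae: float
    p: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return {"r": self.r, "r2": self.r2, "mae": self.mae, "p": self.p,
                "note": self.note}


@dataclass
class AggregateModel:
    """Cross-fold aggregate: consensus masks plus averaged line parameters."""

    node_ids: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    freq_pos: np.ndarray
    freq_neg: np.ndarray
    params: dict  # tail -> (intercept, slope) or None
    fallback: dict
    rule: str
    threshold: float
    n_folds: int
    covariate_names: list[str] = field(default_factory=list)
    edge_order: str = EDGE_ORDER
    notes: list[str] = field(default_factory=list)

    def mask_frame(self) -> pd.DataFrame:
        """Selected edges as (node_i, node_j, sign, selection_frequency)."""
        n = self.node_ids.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        rows = []
        for sign, mask, freq in (("positive", self.pos_mask, self.freq_pos),
                                 ("negative", self.neg_mask, self.freq_neg)):
            for e in np.flatnonzero(mask):
                rows.append({
                    "node_i": int(self.node_ids[iu[e]]),
                    "node_j": int(self.node_ids[ju[e]]),
                    "sign": sign,
                    "selection_frequency": float(freq[e]),
                })
        return pd.DataFrame(rows,
                            columns=["node_i", "node_j", "sign",
                                     "selection_frequency"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "edge_order": self.edge_order,
            "rule": self.rule,
            "threshold": self.threshold,
            "n_folds": self.n_folds,
            "covariates": self.covariate_names,
            "node_ids": self.node_ids.tolist(),
            "pos_edges": np.flatnonzero(self.pos_mask).tolist(),
            "neg_edges": np.flatnonzero(self.neg_mask).tolist(),
            "freq_pos": {int(e): float(self.freq_pos[e])
                         for e in np.flatnonzero(self.freq_pos)},
            "freq_neg": {int(e): float(self.freq_neg[e])
                         for e in np.flatnonzero(self.freq_neg)},
            "params": {t: (list(v) if v is not None else None)
                       for t, v in self.params.items()},
            "fallback": self.fallback,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AggregateModel":
        d = json.loads(Path(path).read_text())
        node_ids = np.asarray(d["node_ids"], dtype=int)
        n_edges = node_ids.size * (node_ids.size - 1) // 2
        pos = np.zeros(n_edges, dtype=bool)
        pos[d["pos_edges"]] = True
        neg = np.zeros(n_edges, dtype=bool)
        neg[d["neg_edges"]] = True
        freq_pos = np.zeros(n_edges)
        for e, f in d["freq_pos"].items():
            freq_pos[int(e)] = f
        freq_neg = np.zeros(n_edges)
        for e, f in d["freq_neg"].items():
            freq_neg[int(e)] = f
        return cls(
            node_ids=node_ids, pos_mask=pos, neg_mask=neg,
            freq_pos=freq_pos, freq_neg=freq_neg,
            params={t: (tuple(v) if v is not None else None)
                    for t, v in d["params"].items()},
            fallback=d.get("fallback", {}),
            rule=d["rule"], threshold=d["threshold"], n_folds=d["n_folds"],
            covariate_names=d.get("covariates", []),
            edge_order=d.get("edge_order", EDGE_ORDER),
            notes=d.get("notes", []),
        )


@dataclass
class ExternalResult:
    """External application of an aggregate model to a new cohort."""

    predictions: PredictionSet
    metrics: dict | None  # tail -> MetricsTriple
    meaningful: dict | None  # tail -> bool; False when r < 0

    def metrics_dict(self) -> dict:
        if self.metrics is None:
            return {}
        return {t: m.to_dict() for t, m in self.metrics.items()}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def select_edges(
    edge_values: np.ndarray,
    target: np.ndarray,
    p_threshold: float,
    covariates=None,
    node_ids: np.ndarray | None = None,
) -> EdgeMaskPair:
    """Mass-univariate edge selection against the target.

    Parameters
    ----------
    edge_values : ndarray, shape (n_edges, n_subjects)
        Unique-edge values in upper-triangle row-major order.
    target : ndarray, shape (n_subjects,)
    p_threshold : float
        Two-sided p-value cut-off; the positive mask holds edges with
        ``r > 0, p < threshold``, the negative mask ``r < 0, p < threshold``.
    covariates : DataFrame or ndarray, optional
        When given, partial correlation: edge and target are both
        residualised on the covariates (plus intercept) first.
    """
    X = np.asarray(edge_values, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[1] != y.shape[0]:
        raise ValueError("edge_values must be n_edges x n_subjects, matching target")
    C, _ = _as_covariate_array(covariates, y.shape[0])
    n_cov = 0 if C is None else C.shape[1]
    if y.shape[0] < 4 + n_cov:
        raise ValueError("need at least 4 subjects plus one per covariate")
    if not 0.0 <= p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in [0, 1]")
    r, p, _ = _edge_stats(X, y, C)
    if node_ids is None:
        # infer a roster when the edge count is triangular; otherwise the
        # mask pair stays vector-only (matrix views unavailable)
        try:
            node_ids = np.arange(1, _nodes_from_edges(X.shape[0]) + 1)
        except ValueError:
            node_ids = None
    return EdgeMaskPair(
        pos=(r > 0) & (p < p_threshold),
        neg=(r < 0) & (p < p_threshold),
        r=r, p=p, threshold=float(p_threshold), node_ids=np.asarray(node_ids),
    )


def _nodes_from_edges(n_edges: int) -> int:
    """Node count whose unique-edge count is ``n_edges``; errors otherwise."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n * (n - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a valid unique-edge count")
    return n


def network_strength(m, mask) -> float:
    """Network strength: masked full-matrix sum halved.

    Halving compensates for the symmetric matrix, so the result equals
    the sum over unique (upper-triangle) selected edges.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if values.shape != mask.shape:
        raise ValueError("matrix and mask shapes do not match")
    return float((values * mask).sum() / 2.0)


def combined_strength(pos: float, neg: float) -> float:
    """Combined network strength: positive minus negative strength."""
    return pos - neg


def fit_strength_model(strengths, target) -> tuple[float, float]:
    """OLS line ``target = intercept + slope * strength``.

    Raises
    ------
    ValueError
        If fewer than 3 subjects or the strengths are constant.
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(target, dtype=float)
    if s.shape[0] != y.shape[0] or s.shape[0] < 3:
        raise ValueError("need equal-length strength/target vectors of length >= 3")
    if np.ptp(s) == 0:
        raise ValueError("strengths are constant; line is undefined")
    slope, intercept = np.polyfit(s, y, 1)
    return float(intercept), float(slope)


def evaluate(pred, obs) -> MetricsTriple:
    """Pearson r, R-squared and MAE of predictions against observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("pred and obs must be equal-length vectors of length >= 3")
    mae = float(np.abs(pred - obs).mean())
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        which = "predictions" if np.ptp(pred) == 0 else "observations"
        return MetricsTriple(r=None, r2=None, mae=mae,
                             note=f"r undefined: {which} are constant")
    r, p = stats.pearsonr(pred, obs)
    return MetricsTriple(r=float(r), r2=float(r * r), mae=mae, p=float(p))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_stats(X, y, folds, C):
    """Per-fold edge statistics computed on the training subjects only."""
    n = y.shape[0]
    out = []
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        Ctr = C[train] if C is not None else None
        r, p, _ = _edge_stats(X[:, train], y[train], Ctr)
        out.append((train, np.asarray(test_idx), r, p))
    return out


def _strengths(X, pos, neg):
    s_pos = pos.astype(float) @ X
    s_neg = neg.astype(float) @ X
    return {"positive": s_pos, "negative": s_neg, "combined": s_pos - s_neg}


def _fit_tail(strength_train, y_train):
    if np.ptp(strength_train) == 0:
        return None, float(y_train.mean())
    slope, intercept = np.polyfit(strength_train, y_train, 1)
    return (float(intercept), float(slope)), float(y_train.mean())


def _predict_from_stats(
    X, y, stats_per_fold, threshold, node_ids, covariate_names, subject_ids=None
):
    n = y.shape[0]
    predicted = {t: np.full(n, np.nan) for t in TAILS}
    folds = []
    assignment = np.full(n, -1, dtype=int)
    empty_folds = 0
    for f, (train, test, r, p) in enumerate(stats_per_fold):
        pos = (r > 0) & (p < threshold)
        neg = (r < 0) & (p < threshold)
        masks = EdgeMaskPair(pos=pos, neg=neg, r=r, p=p,
                             threshold=float(threshold), node_ids=node_ids)
        if not pos.any() and not neg.any():
            empty_folds += 1
        s = _strengths(X, pos, neg)
        params, fallback = {}, {}
        for tail in TAILS:
            par, fb = _fit_tail(s[tail][train], y[train])
            params[tail], fallback[tail] = par, fb
            if par is None:
                predicted[tail][test] = fb
            else:
                intercept, slope = par
                predicted[tail][test] = intercept + slope * s[tail][test]
        folds.append(FoldModel(masks=masks, params=params, fallback=fallback,
                               test_indices=test))
        assignment[test] = f
    if empty_folds:
        warnings.warn(
            f"{empty_folds} fold(s) selected no edges at p < {threshold}; "
            "their predictions fall back to the fold training-target mean",
            stacklevel=3,
        )
    pred_set = PredictionSet(observed=y.copy(), predicted=predicted,
                             subject_ids=subject_ids)
    fold_models = CPMFoldModels(folds=folds, fold_assignment=assignment,
                                threshold=float(threshold),
                                covariate_names=covariate_names,
                                node_ids=node_ids)
    return pred_set, fold_models


def _resolve_inputs(matrices, target):
    if isinstance(matrices, tuple) and len(matrices) == 2:
        X, node_ids = matrices
        X = np.asarray(X, dtype=float)
    else:
        X, node_ids = edge_matrix(matrices)
    y = np.asarray(target, dtype=float)
    if X.shape[1] != y.shape[0]:
        raise ValueError("number of matrices must match target length")
    return X, node_ids, y


def run_loocv(
    matrices, target, p_threshold: float, covariates=None, subject_ids=None
) -> tuple[PredictionSet, CPMFoldModels]:
    """CPM with leave-one-out cross-validation.

    Each subject is predicted by models whose edge selection and line
    fitting saw only the other ``n - 1`` subjects; the held-out target
    never enters selection or fitting.

    Parameters
    ----------
    matrices : sequence of ConnectivityMatrix, or (edge_values, node_ids)
        Per-subject matrices, or a pre-vectorised unique-edge matrix.
    target : ndarray
        Per-subject value to predict (here, the reserve residual).
    p_threshold : float
        Edge-selection p-value threshold.
    covariates : DataFrame or ndarray, optional
        Covariates for partial-correlation edge selection.
    """
    X, node_ids, y = _resolve_inputs(matrices, target)
    n = y.shape[0]
    if n < 10:
        raise ValueError("leave-one-out CPM needs at least 10 subjects")
    C, cov_names = _as_covariate_array(covariates, n)
    folds = [np.array([i]) for i in range(n)]
    stats_per_fold = _fold_stats(X, y, folds, C)
    return _predict_from_stats(X, y, stats_per_fold, p_threshold, node_ids,
                               cov_names, subject_ids)


def _kfold_partition(n: int, k: int, rng: np.random.Generator):
    """Seeded shuffle into k folds with sizes differing by at most one."""
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


@dataclass
class RepeatedKFoldResult:
    """Per-repeat predictions and metrics plus across-repeat summary."""

    predictions: list  # per-repeat PredictionSet
    fold_models: list  # per-repeat CPMFoldModels
    metrics: pd.DataFrame  # rows: repeat x tail
    summary: pd.DataFrame  # mean/sd per tail and metric
    k: int
    repeats: int


def run_repeated_kfold(
    matrices, target, k: int, repeats: int, p_threshold: float,
    covariates=None, seed: int = 0, subject_ids=None,
) -> RepeatedKFoldResult:
    """CPM with repeated k-fold cross-validation.

    Subjects are re-partitioned into ``k`` seeded folds each repeat
    (sizes differing by at most one; repeats use sequential sub-streams
    of the root seed). With ``k = n`` the scheme reduces exactly to
    leave-one-out.
    """
    X, node_ids, y = _resolve_inputs(matrices, target)
    n = y.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    C, cov_names = _as_covariate_array(covariates, n)

    children = np.random.SeedSequence(seed).spawn(repeats)
    predictions, fold_models, rows = [], [], []
    for rep in range(repeats):
        rng = np.random.default_rng(children[rep])
        folds = _kfold_partition(n, k, rng)
        stats_per_fold = _fold_stats(X, y, folds, C)
        pred, fm = _predict_from_stats(X, y, stats_per_fold, p_threshold,
                                       node_ids, cov_names, subject_ids)
        predictions.append(pred)
        fold_models.append(fm)
        for tail in TAILS:
            m = evaluate(pred.predicted[tail], y)
            rows.append({"repeat": rep, "tail": tail, "r": m.r, "r2": m.r2,
                         "mae": m.mae})
    metrics = pd.DataFrame(rows)
    summary = (metrics.groupby("tail")[["r", "r2", "mae"]]
               .agg(["mean", "std"]))
    return RepeatedKFoldResult(predictions=predictions, fold_models=fold_models,
                               metrics=metrics, summary=summary, k=k,
                               repeats=repeats)


@dataclass
class OptimizationResult:
    """Edge-selection-threshold grid search result."""

    best_threshold: float
    trace: pd.DataFrame  # threshold x per-tail out-of-fold r
    significant: bool
    best_predictions: PredictionSet
    best_fold_models: CPMFoldModels


def optimize_threshold(
    matrices, target, threshold_grid=DEFAULT_THRESHOLD_GRID,
    scheme: str = "loocv", k: int | None = None, repeats: int = 1,
    covariates=None, seed: int = 0,
) -> OptimizationResult:
    """Data-driven edge-selection threshold search.

    Runs the stated cross-validation scheme at every grid value and
    returns the threshold maximising the combined-tail out-of-fold
    Pearson r (ties resolved toward the smaller threshold). The per-fold
    edge statistics do not depend on the threshold, so they are computed
    once and re-thresholded per grid point. A best result whose combined
    correlation is not significantly positive (two-sided p >= 0.05) is
    flagged ``significant=False``.
    """
    grid = sorted(float(t) for t in threshold_grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    for t in grid:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"grid threshold {t} outside (0, 1]")
    X, node_ids, y = _resolve_inputs(matrices, target)
    n = y.shape[0]
    C, cov_names = _as_covariate_array(covariates, n)

    if scheme == "loocv":
        fold_sets = [[np.array([i]) for i in range(n)]]
    elif scheme == "kfold":
        if k is None:
            raise ValueError("scheme 'kfold' requires k")
        if not 2 <= k <= n:
            raise ValueError(f"k must lie in [2, {n}]")
        children = np.random.SeedSequence(seed).spawn(repeats)
        fold_sets = [_kfold_partition(n, k, np.random.default_rng(c))
                     for c in children]
    else:
        raise ValueError("scheme must be 'loocv' or 'kfold'")

    stats_sets = [_fold_stats(X, y, folds, C) for folds in fold_sets]

    rows = []
    best = None  # (r, threshold, pred, fm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask folds expected at strict grid points
        for t in grid:
            per_rep = [
                _predict_from_stats(X, y, s, t, node_ids, cov_names)
                for s in stats_sets
            ]
            tail_r = {}
            for tail in TAILS:
                rs = [evaluate(p.predicted[tail], y).r for p, _ in per_rep]
                rs = [r for r in rs if r is not None]
                tail_r[tail] = float(np.mean(rs)) if rs else np.nan
            rows.append({"threshold": t, **{f"r_{tail}": tail_r[tail]
                                            for tail in TAILS}})
            score = tail_r["combined"]
            if not np.isnan(score) and (best is None or score > best[0]):
                best = (score, t, *per_rep[0])
    trace = pd.DataFrame(rows)
    if best is None:
        # no grid point produced a defined combined correlation
        t = grid[0]
        pred, fm = _predict_from_stats(X, y, stats_sets[0], t, node_ids,
                                       cov_names)
        return OptimizationResult(best_threshold=t, trace=trace,
                                  significant=False, best_predictions=pred,
                                  best_fold_models=fm)
    _, t_best, pred_best, fm_best = best
    m = evaluate(pred_best.predicted["combined"], y)
    significant = m.r is not None and m.r > 0 and (m.p is not None and m.p < 0.05)
    return OptimizationResult(best_threshold=t_best, trace=trace,
                              significant=bool(significant),
                              best_predictions=pred_best,
                              best_fold_models=fm_best)


# ---------------------------------------------------------------------------
# aggregation and external application
# ---------------------------------------------------------------------------

def aggregate_model(
    fold_models: CPMFoldModels, rule: str = "intersection",
    min_frequency: float = 0.5,
) -> AggregateModel:
    """Aggregate fold masks and line parameters for external application.

    Mask rules: ``intersection`` keeps edges selected in every fold (the
    consensus network), ``union`` keeps edges selected in any fold,
    ``frequency`` keeps edges selected in at least ``min_frequency`` of
    folds. Line parameters are averaged arithmetically over the folds in
    which they were defined.
    """
    if not fold_models.folds:
        raise ValueError("no folds to aggregate")
    if rule not in ("intersection", "union", "frequency"):
        raise ValueError("rule must be 'intersection', 'union' or 'frequency'")
    k = fold_models.n_folds
    freq_pos = np.mean([f.masks.pos for f in fold_models.folds], axis=0)
    freq_neg = np.mean([f.masks.neg for f in fold_models.folds], axis=0)
    if rule == "intersection":
        pos, neg = freq_pos >= 1.0, freq_neg >= 1.0
    elif rule == "union":
        pos, neg = freq_pos > 0.0, freq_neg > 0.0
    else:
        pos, neg = freq_pos >= min_frequency, freq_neg >= min_frequency
        rule = f"frequency>={min_frequency}"

    params, fallback, notes = {}, {}, []
    for tail in TAILS:
        defined = [f.params[tail] for f in fold_models.folds
                   if f.params[tail] is not None]
        fallback[tail] = float(np.mean([f.fallback[tail]
                                        for f in fold_models.folds]))
        params[tail] = (
            (float(np.mean([p[0] for p in defined])),
             float(np.mean([p[1] for p in defined])))
            if defined else None
        )
        if not defined:
            notes.append(f"{tail}: line undefined in every fold; "
                         "external predictions fall back to the training mean")
    for sign, mask in (("positive", pos), ("negative", neg)):
        if not mask.any():
            msg = (f"aggregated {sign} mask is empty under rule '{rule}'; "
                   f"{sign} network strength will be 0")
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
    return AggregateModel(
        node_ids=fold_models.node_ids, pos_mask=pos, neg_mask=neg,
        freq_pos=freq_pos, freq_neg=freq_neg, params=params,
        fallback=fallback, rule=rule, threshold=fold_models.threshold,
        n_folds=k, covariate_names=fold_models.covariate_names, notes=notes,
    )


def apply_external(
    model: AggregateModel, matrices, target=None, subject_ids=None
) -> ExternalResult:
    """Apply an aggregated CPM to an external cohort.

    Network strengths come from the aggregated masks and predictions from
    the averaged lines. When observed targets are supplied, accuracy
    metrics are computed per tail; a tail with negative out-of-sample r
    is flagged not meaningful as prediction (an anti-correlated model has
    no predictive interpretation even when p is small).
    """
    if isinstance(matrices, tuple) and len(matrices) == 2:
        X, node_ids = np.asarray(matrices[0], dtype=float), matrices[1]
    else:
        X, node_ids = edge_matrix(matrices)
    if not np.array_equal(node_ids, model.node_ids):
        raise ValueError("external cohort node roster differs from the model's")
    s = _strengths(X, model.pos_mask, model.neg_mask)
    n = X.shape[1]
    predicted = {}
    for tail in TAILS:
        par = model.params[tail]
        if par is None:
            predicted[tail] = np.full(n, model.fallback.get(tail, 0.0))
        else:
            intercept, slope = par
            predicted[tail] = intercept + slope * s[tail]
    obs = (np.asarray(target, dtype=float) if target is not None
           else np.full(n, np.nan))
    pred_set = PredictionSet(observed=obs, predicted=predicted,
                             subject_ids=subject_ids)
    if target is None:
        return ExternalResult(predictions=pred_set, metrics=None,
                              meaningful=None)
    metrics, meaningful = {}, {}
    for tail in TAILS:
        m = evaluate(predicted[tail], obs)
        metrics[tail] = m
        meaningful[tail] = bool(m.r is not None and m.r >= 0)
        if m.r is not None and m.r < 0:
            m.note = ("negative association: not meaningful as prediction"
                      if m.note is None else m.note)
    return ExternalResult(predictions=pred_set, metrics=metrics,
                          meaningful=meaningful)
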