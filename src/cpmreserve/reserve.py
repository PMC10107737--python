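"""Global-cognition composite and the residual-based cognitive-reserve score.

The reserve score is the residual from an ordinary least-squares
regression of a global-cognition composite on age, sex, grey-matter
volume, hippocampal volume and mean cortical thickness: subjects whose
cognition is better than predicted from demographics and brain structure
get positive residuals (higher reserve).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import SUBTEST_COLUMNS

__all__ = [
    "ResidualModel",
    "composite_cognition",
    "fit_cr_residual",
    "minmax_normalize",
    "RESIDUAL_PREDICTORS",
]

RESIDUAL_PREDICTORS = [
    "age",
    "sex",
    "gm_volume",
    "hippocampal_volume",
    "cortical_thickness",
]


@dataclass
class ResidualModel:
    """Fitted reserve-residual regression.

    ``residuals`` (the reserve measure) are aligned with ``subject_ids``;
    rows dropped for missing data are counted in ``n_dropped``.
    """

    intercept: float
    coefficients: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    fit_r2: float
    subject_ids: np.ndarray
    n_dropped: int = 0
    predictors: list[str] = field(default_factory=lambda: list(RESIDUAL_PREDICTORS))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "fit_r2": self.fit_r2,
            "n_dropped": self.n_dropped,
            "predictors": self.predictors,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def residual_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "cr_residual": self.residuals}
        )


def composite_cognition(
    subtests: pd.DataFrame | np.ndarray,
    method: str = "mean",
    columns: Sequence[str] | None = None,
) -> np.ndarray:
    """Global-cognition composite from the five subtest scores.

    Each subtest is z-scored within the sample (mean 0, sample SD 1,
    ``ddof=1``) and the composite is the mean of the five z-scores
    (``method='sum'`` gives their sum instead; the two differ only by a
    constant factor and yield identical reserve residuals up to scale).

    Raises
    ------
    ValueError
        If any subtest has zero variance (the column is named).
    """
    if isinstance(subtests, pd.DataFrame):
        cols = list(columns) if columns is not None else [
            c for c in SUBTEST_COLUMNS if c in subtests.columns
        ]
        if not cols:
            raise ValueError("no subtest columns found")
        values = subtests[cols].to_numpy(dtype=float)
        names = cols
    else:
        values = np.asarray(subtests, dtype=float)
        names = [f"subtest_{j}" for j in range(values.shape[1])]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects to standardise")
    if method not in ("mean", "sum"):
        raise ValueError("method must be 'mean' or 'sum'")
    sd = values.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance subtest(s): {', '.join(names[j] for j in flat)}")
    z = (values - values.mean(axis=0)) / sd
    return z.mean(axis=1) if method == "mean" else z.sum(axis=1)


def fit_cr_residual(
    cohort: pd.DataFrame,
    cognition: np.ndarray | None = None,
    predictors: Sequence[str] = RESIDUAL_PREDICTORS,
) -> ResidualModel:
    """OLS of global cognition on demographics and brain structure.

    Parameters
    ----------
    cohort : DataFrame
        Phenotype table; must contain the predictor columns and, when
        ``cognition`` is not given, the five subtest columns from which
        the composite is built.
    cognition : ndarray, optional
        Pre-computed per-subject global cognition, aligned with
        ``cohort`` rows.
    predictors : sequence of str
        Predictor columns (default: age, sex, grey-matter volume,
        hippocampal volume, cortical thickness).

    Returns
    -------
    ResidualModel
        Residuals are the cognitive-reserve measure; rows with missing
        values in any variable entering the fit are dropped and counted.
    """
    predictors = list(predictors)
    missing_cols = [c for c in predictors if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks predictor column(s): {missing_cols}")
    work = cohort.reset_index(drop=True)
    if cognition is None:
        y_full = composite_cognition(work)
    else:
        y_full = np.asarray(cognition, dtype=float)
        if y_full.shape[0] != len(work):
            raise ValueError("cognition length must match cohort rows")

    X_full = work[predictors].to_numpy(dtype=float)
    keep = np.isfinite(X_full).all(axis=1) & np.isfinite(y_full)
    n_dropped = int((~keep).sum())
    X, y = X_full[keep], y_full[keep]
    n = X.shape[0]
    if n <= len(predictors) + 1:
        raise ValueError("too few complete cases for the residual fit")

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + predictors)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0

    ids = (work.loc[keep, "subject_id"].to_numpy()
           if "subject_id" in work.columns else np.flatnonzero(keep))
    return ResidualModel(
        intercept=float(coef[0]),
        coefficients=pd.Series(coef[1:], index=predictors),
        residuals=resid,
        fitted=fitted,
        fit_r2=r2,
        subject_ids=ids,
        n_dropped=n_dropped,
        predictors=predictors,
    )


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy diagnosis)."""
    bad = []
    rank = np.linalg.matrix_rank(design)
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(names[j])
    return bad


def minmax_normalize(values) -> np.ndarray:
    """Min-max normalisation ``(x - min) / (max - min)`` onto [0, 1].

    Used to put proxy scores from instruments with different maxima on a
    common scale before cross-cohort comparison.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("cannot min-max normalise a constant input")
    return (x - lo) / (hi - lo)
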