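"""Theoretical-validity testing of a candidate reserve measure.

A valid reserve measure should (a) correlate positively with an
established socio-behavioural proxy such as verbal intelligence (face
validity), and (b) show a protective effect on cognition: either an
independent positive association with cognition over and above brain
structure (independence effect, delta R-squared step 1 -> 2 of a
hierarchical regression) or a moderation of the brain-structure ->
cognition relationship (interaction term, step 2 -> 3).

Also provided: summary-statistic group comparisons (pooled two-sample t
from n/mean/SD triplets, 2x2 chi-square) of the kind used to compare two
cohorts' demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupSummary",
    "HierRegResult",
    "FaceValidity",
    "face_validity",
    "hierarchical_regression",
    "pooled_t",
    "chi2_2x2",
]


@dataclass
class GroupSummary:
    """Per-group sufficient statistics for a two-sample comparison."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("sd cannot be negative")


@dataclass
class FaceValidity:
    """Pearson association of a candidate measure with a reserve proxy."""

    r: float
    p: float
    valid: bool
    alpha: float = 0.05


def face_validity(measure, proxy, alpha: float = 0.05) -> FaceValidity:
    """Face validity: positive Pearson correlation with a reserve proxy.

    The verdict is positive iff ``r > 0`` and the two-sided p-value is
    below ``alpha``.
    """
    x = np.asarray(measure, dtype=float)
    y = np.asarray(proxy, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("measure and proxy must be equal-length vectors, n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("face validity undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return FaceValidity(r=float(r), p=float(p),
                        valid=bool(r > 0 and p < alpha), alpha=alpha)


@dataclass
class HierRegResult:
    """Three-step hierarchical regression of cognition.

    Step 1: cognition ~ age + sex + cortical thickness.
    Step 2: + candidate reserve measure (independence effect).
    Step 3: + thickness x measure interaction (moderation effect).
    """

    r2: list  # R-squared per step
    coefficients: list  # per-step coefficient DataFrame
    delta_r2: dict  # {"step2": ..., "step3": ...}
    f_tests: dict  # {"step2": (F, p), "step3": (F, p)}
    n: int
    centered_interaction: bool = True
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r2": self.r2,
            "delta_r2": self.delta_r2,
            "f_tests": {k: {"F": v[0], "p": v[1]}
                        for k, v in self.f_tests.items()},
            "centered_interaction": self.centered_interaction,
        }


def hierarchical_regression(
    cohort: pd.DataFrame,
    measure,
    cognition=None,
    center_interaction: bool = True,
) -> HierRegResult:
    """Nested OLS models testing independence and moderation effects.

    Parameters
    ----------
    cohort : DataFrame
        Must provide ``age``, ``sex`` and ``cortical_thickness`` columns
        (and the five subtest columns when ``cognition`` is not given).
    measure : ndarray
        The candidate reserve measure, aligned with ``cohort`` rows.
    cognition : ndarray, optional
        Global cognition; computed from the subtests when omitted.
    center_interaction : bool
        Build the step-3 product from mean-centred thickness and measure
        (decouples the interaction from main-effect location/scale); the
        raw product is available for sensitivity analysis.

    Returns
    -------
    HierRegResult
        Per-step R-squared and coefficients, delta R-squared per
        increment, and the nested-model F-test per increment.
    """
    m = np.asarray(measure, dtype=float)
    if len(cohort) != m.shape[0]:
        raise ValueError("measure length must match cohort rows")
    if cognition is None:
        from .reserve import composite_cognition
        y = composite_cognition(cohort)
    else:
        y = np.asarray(cognition, dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    thick = cohort["cortical_thickness"].to_numpy(dtype=float)
    if center_interaction:
        inter = (thick - thick.mean()) * (m - m.mean())
    else:
        inter = thick * m

    steps = [
        pd.DataFrame({"age": age, "sex": sex, "cortical_thickness": thick}),
    ]
    steps.append(steps[0].assign(measure=m))
    steps.append(steps[1].assign(thickness_x_measure=inter))

    fits = []
    for i, Xdf in enumerate(steps, start=1):
        X = sm.add_constant(Xdf, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"rank-deficient design at step {i}")
        fits.append(sm.OLS(y, X).fit())

    r2 = [float(f.rsquared) for f in fits]
    f12, p12, _ = fits[1].compare_f_test(fits[0])
    f23, p23, _ = fits[2].compare_f_test(fits[1])
    coefs = [
        pd.DataFrame({"coef": f.params, "se": f.bse, "t": f.tvalues,
                      "p": f.pvalues})
        for f in fits
    ]
    return HierRegResult(
        r2=r2,
        coefficients=coefs,
        delta_r2={"step2": max(r2[1] - r2[0], 0.0),
                  "step3": max(r2[2] - r2[1], 0.0)},
        f_tests={"step2": (float(f12), float(p12)),
                 "step3": (float(f23), float(p23))},
        n=int(len(y)),
        centered_interaction=center_interaction,
    )


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from per-group (n, mean, sd).

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2`` and a two-sided p.
    Pooled (not Welch) variance is the default because it reproduces the
    printed group-comparison statistics this module is tested against;
    Welch is available via :func:`scipy.stats.ttest_ind_from_stats`
    directly.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, a.n + b.n - 2, 1.0
        raise ValueError("both groups degenerate (sd = 0) with unequal means")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(t), a.n + b.n - 2, float(p)


def chi2_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(chi2, df, p)`` with ``df = 1``.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts cannot be negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count of zero in the 2x2 table")
    return float(chi2), int(dof), float(p)
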