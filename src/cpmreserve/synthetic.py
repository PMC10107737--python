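"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a two-site ageing-cohort connectome study:
a phenotype table (demographics, five cognitive subtests, brain-structure
summaries, head motion, a verbal-intelligence proxy), one symmetric
Fisher-z connectivity matrix per subject, and a latent reserve variable
that drives both cognition and a small set of planted signed edges.

The generative model, in order:

1. latent reserve ``R ~ Normal(0, sigma_reserve)``;
2. demographics (age uniform, sex Bernoulli(0.5)) and brain structure
   (linear in age plus noise);
3. a composite cognition signal = linear function of demographics and
   structure (``structural_coefficients``) + ``R`` + Normal(0,
   sigma_cog_noise); each of the five subtests adds independent noise;
4. every unique edge is i.i.d. Normal baseline noise on the Fisher-z
   scale; each planted edge additionally gains (positive sign) or loses
   (negative sign) a reserve term scaled so that the population
   edge-reserve Pearson correlation equals ``gamma``.

Because the latent reserve and the planted edge indices are returned as
ground truth, every downstream stage (residual construction, edge
selection, cross-validated prediction) has a parameter-recovery surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, MotionRecord, n_unique_edges

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_motion",
    "SUBTEST_COLUMNS",
    "STRUCTURAL_PREDICTORS",
]

SUBTEST_COLUMNS = [
    "verbal_fluency",
    "processing_speed",
    "executive_function",
    "immediate_memory",
    "delayed_memory",
]

#: Predictor order matched by ``GeneratorConfig.structural_coefficients``.
STRUCTURAL_PREDICTORS = [
    "age",
    "sex",
    "gm_volume",
    "hippocampal_volume",
    "cortical_thickness",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects, n_nodes : int
        Cohort size and parcellation size (default 205 nodes, the roster
        after cerebellum/brainstem removal from a 268-node atlas).
    n_pos_edges, n_neg_edges : int
        Counts of planted positively / negatively reserve-coupled edges.
    gamma : float
        Target population Pearson correlation between each planted edge
        and the latent reserve, in (-1, 1).
    sigma_reserve : float
        SD of the latent reserve variable.
    sigma_cog_noise : float
        SD of the noise shared by all five subtests (composite-level).
    sigma_subtest_noise : float
        SD of the per-subtest independent noise.
    structural_coefficients : sequence of 5 floats
        Effects of age, sex, grey-matter volume, hippocampal volume and
        mean cortical thickness on the cognition signal.
    edge_mean, sigma_edge : float
        Mean and SD of the i.i.d. baseline edge distribution (Fisher-z).
    age_range : (float, float)
        Uniform age support in years.
    motion_params : (float, float)
        Location (mm) and log-scale of the per-subject mean-FWD
        distribution.
    high_motion_fraction : float
        Probability that a subject is drawn from the high-motion regime
        (mean FWD above 0.4 mm).
    n_frames : int
        Frames per motion series.
    seed : int
        Root seed for all draws.
    """

    n_subjects: int = 200
    n_nodes: int = 205
    n_pos_edges: int = 10
    n_neg_edges: int = 10
    gamma: float = 0.4
    sigma_reserve: float = 1.0
    sigma_cog_noise: float = 0.3
    sigma_subtest_noise: float = 0.5
    structural_coefficients: Sequence[float] = (-0.02, 0.1, 8.0, 100.0, 0.8)
    edge_mean: float = 0.1
    sigma_edge: float = 0.3
    age_range: tuple[float, float] = (20.0, 80.0)
    motion_params: tuple[float, float] = (0.15, 0.4)
    high_motion_fraction: float = 0.0
    n_frames: int = 100
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated constraint."""
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.n_pos_edges < 0 or self.n_neg_edges < 0:
            raise ValueError("planted edge counts must be non-negative")
        if self.n_pos_edges + self.n_neg_edges > n_unique_edges(self.n_nodes):
            raise ValueError(
                "n_pos_edges + n_neg_edges exceeds the number of unique edges "
                f"({n_unique_edges(self.n_nodes)})"
            )
        if not -1.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (-1, 1)")
        for name in ("sigma_reserve", "sigma_cog_noise", "sigma_subtest_noise",
                     "sigma_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(tuple(self.structural_coefficients)) != len(STRUCTURAL_PREDICTORS):
            raise ValueError("structural_coefficients must have 5 entries "
                             "(age, sex, gm_volume, hippocampal_volume, "
                             "cortical_thickness)")
        if self.motion_params[0] <= 0 or self.motion_params[1] <= 0:
            raise ValueError("motion_params location and scale must be positive")
        if not 0.0 <= self.high_motion_fraction <= 1.0:
            raise ValueError("high_motion_fraction must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["structural_coefficients"] = list(self.structural_coefficients)
        d["age_range"] = list(self.age_range)
        d["motion_params"] = list(self.motion_params)
        return d


@dataclass
class SyntheticCohort:
    """Generated phenotype table, matrices and ground truth."""

    cohort: pd.DataFrame
    matrices: list[ConnectivityMatrix]
    reserve: np.ndarray
    pos_edges: np.ndarray  # unique-edge indices, upper-triangle row-major
    neg_edges: np.ndarray
    config: GeneratorConfig
    motion: list[MotionRecord] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.cohort)

    def edge_matrix(self) -> np.ndarray:
        """Unique-edge x subject matrix in upper-triangle row-major order."""
        return np.column_stack([m.edge_vector() for m in self.matrices])

    def truth_frame(self) -> pd.DataFrame:
        """Ground truth as a tidy table (one row per subject)."""
        return pd.DataFrame(
            {"subject_id": self.cohort["subject_id"], "latent_reserve": self.reserve}
        )

    def planted_frame(self) -> pd.DataFrame:
        """Planted edges as (edge_index, node_i, node_j, sign) rows."""
        n = self.config.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        rows = []
        for sign, idx in (("positive", self.pos_edges), ("negative", self.neg_edges)):
            for e in idx:
                rows.append(
                    {"edge_index": int(e), "node_i": int(iu[e] + 1),
                     "node_j": int(ju[e] + 1), "sign": sign}
                )
        return pd.DataFrame(rows)


def _edge_coupling(config: GeneratorConfig) -> float:
    """Reserve coefficient beta giving corr(edge, reserve) = gamma.

    For edge = noise + beta*R with noise ~ N(0, sigma_edge^2) and
    R ~ N(0, sigma_reserve^2), corr = beta*sigma_R / sqrt(beta^2 sigma_R^2
    + sigma_edge^2); inverting gives beta below.
    """
    g = config.gamma
    if g == 0.0:
        return 0.0
    return (g / np.sqrt(1.0 - g * g)) * config.sigma_edge / config.sigma_reserve


def generate_motion(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[MotionRecord]:
    """Per-subject framewise-displacement series (mm).

    Each subject's target mean FWD is drawn from a lognormal centred at
    ``motion_params[0]``; with probability ``high_motion_fraction`` the
    draw is resampled into the high-motion regime (> 0.4 mm), otherwise
    into the low-motion regime (<= 0.4 mm). Frame values are gamma-
    distributed and rescaled so the series mean equals the target exactly,
    which makes the regime assignment a construction guarantee.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loc, scale = config.motion_params
    records = []
    for s in range(config.n_subjects):
        high = rng.random() < config.high_motion_fraction
        mu = _draw_mean_fwd(rng, loc, scale, high=high)
        raw = rng.gamma(shape=3.0, scale=mu / 3.0, size=config.n_frames)
        raw = np.maximum(raw, 1e-12)
        fwd = raw * (mu / raw.mean())
        records.append(MotionRecord(fwd=fwd, subject_id=f"sub-{s + 1:04d}"))
    return records


def _draw_mean_fwd(rng: np.random.Generator, loc: float, scale: float,
                   high: bool, threshold: float = 0.4) -> float:
    """Rejection-sample a mean FWD strictly in the requested regime."""
    for _ in range(1000):
        mu = loc * np.exp(scale * rng.standard_normal())
        if high and mu > threshold:
            return mu
        if not high and mu <= threshold:
            return mu
    # fall back deterministically if the lognormal mass barely reaches
    # the requested regime
    return threshold * 1.5 if high else threshold * 0.5


def generate_cohort(
    config: GeneratorConfig,
    planted_edges: tuple[np.ndarray, np.ndarray] | None = None,
    flip_coupling: bool = False,
) -> SyntheticCohort:
    """Generate a cohort with known latent reserve and planted edges.

    Parameters
    ----------
    config : GeneratorConfig
    planted_edges : optional (pos_indices, neg_indices)
        Reuse an existing cohort's planted edge sets (unique-edge indices)
        instead of drawing fresh ones — this is how an external cohort
        sharing the training cohort's ground truth is built.
    flip_coupling : bool
        Reverse the sign of the edge-reserve coupling on the planted
        edges, emulating a population in which the same edges relate to
        reserve in the opposite direction.

    Returns
    -------
    SyntheticCohort
        Phenotype table, per-subject connectivity matrices, latent
        reserve, and the signed planted-edge index sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_nodes
    n_edges = n_unique_edges(p)

    # --- latent reserve -------------------------------------------------
    reserve = rng.normal(0.0, config.sigma_reserve, size=n)

    # --- demographics and brain structure -------------------------------
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    gm_volume = 0.46 - 0.0008 * age + rng.normal(0.0, 0.012, size=n)
    hippocampal_volume = 0.006 - 1e-5 * age + rng.normal(0.0, 4e-4, size=n)
    cortical_thickness = 2.8 - 0.004 * age + rng.normal(0.0, 0.06, size=n)
    education = np.clip(rng.normal(16.0, 2.4, size=n), 8.0, None)

    # --- cognition ------------------------------------------------------
    beta = np.asarray(config.structural_coefficients, dtype=float)
    design = np.column_stack([age, sex, gm_volume, hippocampal_volume,
                              cortical_thickness])
    signal = design @ beta + reserve + rng.normal(0.0, config.sigma_cog_noise,
                                                  size=n)
    subtests = signal[:, None] + rng.normal(
        0.0, config.sigma_subtest_noise, size=(n, len(SUBTEST_COLUMNS))
    )

    # proxy: verbal-intelligence-like count, positively loaded on reserve
    proxy = 33.0 + 6.0 * reserve / config.sigma_reserve + rng.normal(0.0, 4.0, size=n)

    # --- planted edges --------------------------------------------------
    if planted_edges is None:
        k = config.n_pos_edges + config.n_neg_edges
        chosen = rng.choice(n_edges, size=k, replace=False)
        pos_edges = np.sort(chosen[: config.n_pos_edges])
        neg_edges = np.sort(chosen[config.n_pos_edges:])
    else:
        pos_edges = np.asarray(planted_edges[0], dtype=int)
        neg_edges = np.asarray(planted_edges[1], dtype=int)
        if np.intersect1d(pos_edges, neg_edges).size:
            raise ValueError("planted edge sets must be disjoint")
        if pos_edges.size and pos_edges.max() >= n_edges:
            raise ValueError("planted edge index out of range")
        if neg_edges.size and neg_edges.max() >= n_edges:
            raise ValueError("planted edge index out of range")

    # --- connectivity ---------------------------------------------------
    edge_beta = _edge_coupling(config)
    if flip_coupling:
        edge_beta = -edge_beta
    X = config.edge_mean + rng.normal(0.0, config.sigma_edge, size=(n_edges, n))
    X[pos_edges] += edge_beta * reserve
    X[neg_edges] -= edge_beta * reserve

    iu, ju = np.triu_indices(p, k=1)
    node_ids = np.arange(1, p + 1)
    matrices = []
    for s in range(n):
        m = np.zeros((p, p))
        m[iu, ju] = X[:, s]
        m[ju, iu] = X[:, s]
        matrices.append(ConnectivityMatrix(values=m, node_ids=node_ids.copy()))

    # --- motion (separate stream seeded from the root stream) ------------
    motion = generate_motion(config, rng=rng)
    mean_fwd = np.array([rec.mean_fwd for rec in motion])

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{s + 1:04d}" for s in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "proxy_score": proxy,
            **{c: subtests[:, j] for j, c in enumerate(SUBTEST_COLUMNS)},
            "gm_volume": gm_volume,
            "hippocampal_volume": hippocampal_volume,
            "cortical_thickness": cortical_thickness,
            "mean_fwd": mean_fwd,
        }
    )
    return SyntheticCohort(
        cohort=cohort,
        matrices=matrices,
        reserve=reserve,
        pos_edges=pos_edges,
        neg_edges=neg_edges,
        config=config,
        motion=motion,
    )
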