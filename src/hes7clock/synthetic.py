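"""Synthetic observations with the statistical structure the estimators
assume: noisy expression traces, phase-offset cell populations, and
reference-gene-normalized relative-quantification (qPCR-style) samples.

All generators are pure functions of their inputs and a seed; the same seed
reproduces outputs exactly.  The phase-offset population is a deliberate
caricature of the travelling PSM wave — independent cells with shifted
phases, no coupling and no spatial mechanism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError, InvalidParameterError
from .model import ClockParameters, Trajectory, integrate

__all__ = [
    "NoiseModel",
    "RelativeExpressionSample",
    "RelativeExpressionResult",
    "add_noise",
    "simulate_cell_population",
    "relative_expression",
    "generate_qpcr_samples",
]

logger = logging.getLogger(__name__)

#: Group sizes of the reference relative-quantification experiment
#: (wild-type and mutant PSMs).
DEFAULT_N_WILD_TYPE = 14
DEFAULT_N_MUTANT = 13

#: Default lognormal dispersion of synthetic qPCR quantities.  The source
#: data report only mean +- s.e.m., so this is a package convention,
#: recorded in every generated output.
DEFAULT_QPCR_SIGMA = 0.1


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description applied per sample."""

    kind: str = "multiplicative-gaussian"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")


def add_noise(traj: Trajectory, noise: NoiseModel) -> Trajectory:
    """Apply seeded measurement noise to both channels of a trajectory.

    Multiplicative noise scales each sample by ``1 + sigma * eps``; additive
    noise adds ``sigma * eps``.  Values pushed below zero are truncated at
    zero and the truncation count is logged.
    """
    rng = np.random.default_rng(noise.seed)
    out = {}
    truncated = 0
    for name in ("mrna", "protein"):
        y = traj.channel(name)
        eps = rng.standard_normal(len(y))
        if noise.kind == "multiplicative-gaussian":
            noisy = y * (1.0 + noise.sigma * eps)
        else:
            noisy = y + noise.sigma * eps
        below = noisy < 0
        truncated += int(below.sum())
        noisy[below] = 0.0
        out[name] = noisy
    if truncated:
        logger.info(
            "add_noise truncated %d negative sample(s) at zero (seed=%d)",
            truncated,
            noise.seed,
        )
    return Trajectory(
        traj.times.copy(),
        out["mrna"],
        out["protein"],
        params_fingerprint=traj.params_fingerprint,
    )


def simulate_cell_population(
    params: ClockParameters,
    n_cells: int,
    phase_spread_min: float,
    noise: NoiseModel,
    t_end: float = 1200.0,
    dt: float = 0.05,
) -> list[Trajectory]:
    """Independent cells sharing one deterministic trajectory, each shifted
    by a seeded uniform phase draw in ``[0, phase_spread_min]`` plus noise.

    A fixed-time snapshot across cells shows a graded profile when the
    spread is about one period (the wave caricature) and a uniform profile
    when the underlying trajectory is non-oscillatory.
    """
    if n_cells < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    if phase_spread_min < 0:
        raise InvalidParameterError("phase_spread_min must be >= 0")
    base = integrate(params, t_end=t_end + phase_spread_min, dt=dt)
    rng = np.random.default_rng(noise.seed)
    shifts = rng.uniform(0.0, phase_spread_min, size=n_cells) if phase_spread_min > 0 else np.zeros(n_cells)
    n_keep = int(round(t_end / dt)) + 1
    times = np.arange(n_keep) * dt
    cells = []
    for i, shift in enumerate(shifts):
        # sample the shared trajectory at t + shift per cell
        m = np.interp(times + shift, base.times, base.mrna)
        p = np.interp(times + shift, base.times, base.protein)
        cell = Trajectory(times.copy(), m, p, params_fingerprint=base.params_fingerprint)
        if noise.sigma > 0:
            # derive an independent per-cell stream from the master seed
            cell = add_noise(
                cell,
                NoiseModel(noise.kind, noise.sigma, seed=int(rng.integers(2**31))),
            )
        cells.append(cell)
    return cells


@dataclass(frozen=True)
class RelativeExpressionSample:
    """One reference-normalized expression measurement."""

    group: str
    target_quantity: float
    reference_quantity: float
    normalized_value: float

    def __post_init__(self) -> None:
        if self.target_quantity <= 0 or self.reference_quantity <= 0:
            raise InvalidInputError("quantities must be strictly positive")


@dataclass
class RelativeExpressionResult:
    """Group summary of reference-normalized expression measurements."""

    samples: list[RelativeExpressionSample]
    group_means: dict[str, float]
    group_sems: dict[str, float]
    p_value: float

    def as_dict(self) -> dict:
        return {
            "group_means": self.group_means,
            "group_sems": self.group_sems,
            "p_value": self.p_value,
            "n_per_group": {
                g: sum(1 for s in self.samples if s.group == g)
                for g in self.group_means
            },
        }


def relative_expression(
    wild_type_target: np.ndarray,
    wild_type_reference: np.ndarray,
    mutant_target: np.ndarray,
    mutant_reference: np.ndarray,
) -> RelativeExpressionResult:
    """Reference-gene normalization with rescaling to the wild-type mean.

    Each sample's target quantity is divided by its reference quantity;
    all ratios are rescaled so the wild-type group mean is exactly 1.
    Group means, standard errors, and a two-sample (Student's) t-test
    p-value are reported.
    """
    arrays = {
        "wild-type": (np.asarray(wild_type_target, float), np.asarray(wild_type_reference, float)),
        "mutant": (np.asarray(mutant_target, float), np.asarray(mutant_reference, float)),
    }
    for g, (t, r) in arrays.items():
        if len(t) != len(r):
            raise InvalidInputError(f"{g}: target and reference lengths differ")
        if len(t) < 2:
            raise InvalidInputError(f"{g}: need at least 2 samples, got {len(t)}")
        if np.any(t <= 0) or np.any(r <= 0):
            raise InvalidInputError(f"{g}: quantities must be strictly positive")

    ratios = {g: t / r for g, (t, r) in arrays.items()}
    scale = ratios["wild-type"].mean()
    normalized = {g: v / scale for g, v in ratios.items()}

    samples = [
        RelativeExpressionSample(g, float(t_i), float(r_i), float(n_i))
        for g, (t, r) in arrays.items()
        for t_i, r_i, n_i in zip(t, r, normalized[g])
    ]
    means = {g: float(v.mean()) for g, v in normalized.items()}
    sems = {g: float(stats.sem(v)) for g, v in normalized.items()}
    p = float(
        stats.ttest_ind(normalized["wild-type"], normalized["mutant"]).pvalue
    )
    return RelativeExpressionResult(samples, means, sems, p)


def generate_qpcr_samples(
    true_ratio: float = 0.7,
    n_wild_type: int = DEFAULT_N_WILD_TYPE,
    n_mutant: int = DEFAULT_N_MUTANT,
    sigma: float = DEFAULT_QPCR_SIGMA,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Synthetic target/reference quantity pairs with lognormal dispersion.

    The mutant group's expected target level is ``true_ratio`` times the
    wild-type level; reference quantities share the same dispersion and
    unit mean.  Returns arrays keyed by group and role.
    """
    if true_ratio <= 0:
        raise InvalidParameterError("true_ratio must be > 0")
    rng = np.random.default_rng(seed)

    def lognorm(n: int, mean_level: float) -> np.ndarray:
        return mean_level * np.exp(sigma * rng.standard_normal(n))

    return {
        "wild_type_target": lognorm(n_wild_type, 1.0),
        "wild_type_reference": lognorm(n_wild_type, 1.0),
        "mutant_target": lognorm(n_mutant, true_ratio),
        "mutant_reference": lognorm(n_mutant, 1.0),
    }
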