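"""Recording and weight types, terminal computation and the fitness score.

Potentials are stored in volts throughout.  The minimized terminal is the
weighted mean ``alpha*phi_L + beta*phi_R + gamma*phi_F`` with weights on the
open 2-simplex; the classic terminal is the special case of uniform weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConstraintViolationError,
    ParameterError,
    StructuralInputError,
)

#: Sum-to-one tolerance for a valid weight tern.
SUM_TOLERANCE = 1e-9

#: Open-interval bounds enforced by :func:`repair_weights`.  "Positive, not
#: null" needs an explicit numeric floor; the ceiling keeps the two other
#: components above the floor after renormalization.
WEIGHT_FLOOR = 1e-6
WEIGHT_CEIL = 1.0 - 2e-6

#: Base of the logarithmic fitness score, on the volt scale (1e-5 V).
FITNESS_LOG_BASE = 1e-5

#: Amplitude floor keeping the fitness finite on exactly-null traces.
DEFAULT_FITNESS_FLOOR = 1e-12


def _as_trace_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise StructuralInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise StructuralInputError(f"{name} contains non-finite samples")
    return arr


@dataclass(frozen=True)
class WeightTern:
    """One candidate solution: weights ``(alpha, beta, gamma)`` for the
    left-arm, right-arm and left-leg potentials.

    Each component lies strictly inside ``(0, 1)`` and the three sum to one
    within :data:`SUM_TOLERANCE`.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        w = (self.alpha, self.beta, self.gamma)
        if not all(math.isfinite(x) for x in w):
            raise ConstraintViolationError(f"non-finite weights {w}")
        if not all(0.0 < x < 1.0 for x in w):
            raise ConstraintViolationError(
                f"weights {w} must lie strictly inside (0, 1)"
            )
        if abs(sum(w) - 1.0) > SUM_TOLERANCE:
            raise ConstraintViolationError(
                f"weights {w} sum to {sum(w)!r}, not 1 within {SUM_TOLERANCE}"
            )

    @classmethod
    def uniform(cls) -> "WeightTern":
        """The classic-terminal chromosome ``(1/3, 1/3, 1/3)``."""
        third = 1.0 / 3.0
        return cls(third, third, third)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    def __iter__(self):
        return iter((self.alpha, self.beta, self.gamma))


def repair_weights(raw) -> WeightTern:
    """Project a raw weight triple onto the valid open simplex.

    Components are clipped into ``[WEIGHT_FLOOR, WEIGHT_CEIL]`` and divided
    by their sum; the two steps are iterated until both constraints hold
    (renormalization can push an extreme component back below the floor).
    """
    w = np.asarray(raw, dtype=float)
    if w.shape != (3,):
        raise ConstraintViolationError("a weight tern has exactly 3 components")
    if not np.all(np.isfinite(w)):
        raise ConstraintViolationError(f"non-finite raw weights {w.tolist()}")
    for _ in range(50):
        w = np.clip(w, WEIGHT_FLOOR, WEIGHT_CEIL)
        w = w / w.sum()
        if (
            w.min() >= WEIGHT_FLOOR
            and w.max() <= WEIGHT_CEIL
            and abs(w.sum() - 1.0) <= SUM_TOLERANCE
        ):
            return WeightTern(float(w[0]), float(w[1]), float(w[2]))
    raise ConstraintViolationError(f"could not repair weights {raw!r}")


@dataclass(frozen=True)
class PotentialTrace:
    """A single potential time series in volts at a fixed sample rate."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_trace_array(self.values, "trace"))
        if not (self.sample_rate > 0):
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass(frozen=True)
class LimbPotentialRecording:
    """Three synchronized limb-electrode potential traces.

    ``phi_L``, ``phi_R`` and ``phi_F`` are the raw potentials of the
    left-arm, right-arm and left-leg electrodes, in volts.
    """

    phi_L: np.ndarray
    phi_R: np.ndarray
    phi_F: np.ndarray
    sample_rate: float
    subject_id: str = field(default="")

    def __post_init__(self) -> None:
        for name in ("phi_L", "phi_R", "phi_F"):
            object.__setattr__(self, name, _as_trace_array(getattr(self, name), name))
        n = len(self.phi_L)
        if len(self.phi_R) != n or len(self.phi_F) != n:
            raise StructuralInputError(
                "phi_L, phi_R, phi_F must have identical lengths, got "
                f"{n}, {len(self.phi_R)}, {len(self.phi_F)}"
            )
        if n < 2:
            raise StructuralInputError("recording must have at least 2 samples")
        if not (self.sample_rate > 0):
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.phi_L)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def compute_mwct(rec: LimbPotentialRecording, w: WeightTern) -> PotentialTrace:
    """Weighted mean of the limb potentials, per sample."""
    if not isinstance(w, WeightTern):
        w = WeightTern(*w)  # validates the constraints
    values = w.alpha * rec.phi_L + w.beta * rec.phi_R + w.gamma * rec.phi_F
    return PotentialTrace(values=values, sample_rate=rec.sample_rate)


def compute_wct(rec: LimbPotentialRecording) -> PotentialTrace:
    """Classic terminal: the simple average of the three limb potentials.

    Implemented as the uniform-weight case of :func:`compute_mwct` so the
    two agree bit-for-bit.
    """
    return compute_mwct(rec, WeightTern.uniform())


def derive_lead_ii(rec: LimbPotentialRecording) -> PotentialTrace:
    """Einthoven lead II: left leg minus right arm."""
    return PotentialTrace(values=rec.phi_F - rec.phi_R, sample_rate=rec.sample_rate)


def fitness_from_amplitude(amplitude: float, floor: float = DEFAULT_FITNESS_FLOOR) -> float:
    """Fitness score of a mean absolute amplitude (volts).

    ``log`` base :data:`FITNESS_LOG_BASE` of ``max(amplitude, floor)``:
    strictly decreasing in the amplitude, so larger fitness means a smaller
    terminal.  The optimizer maximizes this score.
    """
    if not (floor > 0):
        raise ParameterError(f"fitness floor must be > 0, got {floor}")
    if amplitude < 0 or not math.isfinite(amplitude):
        raise ParameterError(f"amplitude must be finite and >= 0, got {amplitude}")
    return math.log(max(amplitude, floor)) / math.log(FITNESS_LOG_BASE)


def fitness(trace: PotentialTrace, floor: float = DEFAULT_FITNESS_FLOOR) -> float:
    """Fitness of a trace: log_{1e-5} of its mean absolute value (floored)."""
    if len(trace.values) == 0:
        raise StructuralInputError("fitness of an empty trace is undefined")
    return fitness_from_amplitude(float(np.mean(np.abs(trace.values))), floor)
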