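"""Synthetic limb-potential recordings with a planted ground-truth tern.

A 3-D equivalent cardiac dipole is built as a sum of Gaussian wavelets
(P, Q, R, S, T) per beat; each limb potential is the projection of the
dipole onto a per-electrode lead vector plus independent baseline drift and
white noise.  The left-leg lead vector is constructed so that the planted
weight tern exactly nulls the dipole contribution of the weighted mean,
making the tern a recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import LimbPotentialRecording, WeightTern, repair_weights
from .errors import GeometryError, ParameterError

#: Fraction of the beat period at which the R wavelet is centered.
R_CENTER_FRACTION = 0.375


@dataclass(frozen=True)
class Wavelet:
    """One Gaussian component of the dipole trajectory.

    ``center`` is a fraction of the beat period from the beat onset,
    ``width`` is the Gaussian sigma in seconds, ``amplitude`` the 3-axis
    dipole amplitude in volts.
    """

    name: str
    center: float
    width: float
    amplitude: tuple[float, float, float]


#: P-QRS-T morphology with a dominant R deflection, amplitudes in volts.
#: The per-wave dipole directions are deliberately non-collinear so the
#: dipole trajectory spans all three axes and the planted tern is the
#: unique null of the weighted mean (identifiability of the ground truth).
#: The weighted mean's sensitivity to the weights lives in the plane
#: spanned by the two arm lead vectors (the leg vector is a linear
#: combination of them by construction), so the P and T waves are pointed
#: along the in-plane direction orthogonal to the R wave to keep the
#: planted tern identifiable in every direction.
DEFAULT_WAVELETS: tuple[Wavelet, ...] = (
    Wavelet("P", 0.200, 0.040, (1.0e-4, 2.0e-4, 5.0e-5)),
    Wavelet("Q", 0.345, 0.012, (-1.3e-4, 5.0e-5, 6.0e-5)),
    Wavelet("R", R_CENTER_FRACTION, 0.018, (1.1e-3, 4.5e-4, -2.0e-4)),
    Wavelet("S", 0.405, 0.014, (-2.6e-4, -2.2e-4, 1.4e-4)),
    Wavelet("T", 0.700, 0.105, (-1.0e-4, -3.3e-4, 1.2e-4)),
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults give a 10 s, 800 Hz recording."""

    heart_rate: float = 60.0
    duration: float = 10.0
    sample_rate: float = 800.0
    planted_tern: WeightTern = field(default_factory=lambda: WeightTern(0.2, 0.2, 0.6))
    lead_vector_L: tuple[float, float, float] = (0.3, 1.0, 0.2)
    lead_vector_R: tuple[float, float, float] = (-1.2, 0.3, 0.1)
    wavelets: tuple[Wavelet, ...] = DEFAULT_WAVELETS
    baseline_drift_amplitude: float = 5.0e-5
    noise_sd: float = 1.0e-5
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not (self.heart_rate > 0):
            raise ParameterError(f"heart_rate must be > 0, got {self.heart_rate}")
        if not (self.duration > 0):
            raise ParameterError(f"duration must be > 0, got {self.duration}")
        if not (self.sample_rate > 0):
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.baseline_drift_amplitude < 0:
            raise ParameterError("baseline_drift_amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate


def derive_leg_lead_vector(params: SyntheticParams) -> np.ndarray:
    """Lead vector of the left-leg electrode that makes the planted tern
    null the dipole part of the weighted mean."""
    w = params.planted_tern
    l_L = np.asarray(params.lead_vector_L, dtype=float)
    l_R = np.asarray(params.lead_vector_R, dtype=float)
    l_F = -(w.alpha * l_L + w.beta * l_R) / w.gamma
    if np.linalg.norm(l_F) < 1e-9:
        raise GeometryError("left-leg lead vector is null; choose other arm vectors")
    if np.linalg.norm(l_F - l_R) < 1e-9:
        raise GeometryError("lead II vector is null; degenerate geometry")
    return l_F


def r_peak_schedule(params: SyntheticParams) -> np.ndarray:
    """Scheduled R-peak times (seconds) of the generated recording."""
    starts = np.arange(0.0, params.duration, params.beat_period)
    times = starts + R_CENTER_FRACTION * params.beat_period
    return times[times < params.duration]


def dipole_trajectory(params: SyntheticParams) -> np.ndarray:
    """The (3, n_samples) noise-free dipole signal."""
    t = np.arange(params.n_samples) / params.sample_rate
    d = np.zeros((3, params.n_samples))
    for start in np.arange(0.0, params.duration, params.beat_period):
        for wav in params.wavelets:
            center = start + wav.center * params.beat_period
            bump = np.exp(-0.5 * ((t - center) / wav.width) ** 2)
            for axis in range(3):
                if wav.amplitude[axis] != 0.0:
                    d[axis] += wav.amplitude[axis] * bump
    return d


def generate_recording(
    params: SyntheticParams,
) -> tuple[LimbPotentialRecording, WeightTern]:
    """Generate one recording and return it with its planted tern."""
    rng = np.random.default_rng(params.seed)
    l_L = np.asarray(params.lead_vector_L, dtype=float)
    l_R = np.asarray(params.lead_vector_R, dtype=float)
    l_F = derive_leg_lead_vector(params)

    d = dipole_trajectory(params)
    t = np.arange(params.n_samples) / params.sample_rate

    traces = []
    for lead_vector in (l_L, l_R, l_F):
        phi = lead_vector @ d
        if params.baseline_drift_amplitude > 0:
            freq = rng.uniform(0.1, 0.45)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            phi = phi + params.baseline_drift_amplitude * np.sin(
                2.0 * np.pi * freq * t + phase
            )
        if params.noise_sd > 0:
            phi = phi + rng.normal(0.0, params.noise_sd, params.n_samples)
        traces.append(phi)

    rec = LimbPotentialRecording(
        phi_L=traces[0],
        phi_R=traces[1],
        phi_F=traces[2],
        sample_rate=params.sample_rate,
        subject_id=params.subject_id,
    )
    return rec, params.planted_tern


def lead_ii_peak_to_peak(params: SyntheticParams) -> float:
    """Noise- and drift-free peak-to-peak excursion of lead II (volts)."""
    clean = dataclasses.replace(params, noise_sd=0.0, baseline_drift_amplitude=0.0)
    l_R = np.asarray(clean.lead_vector_R, dtype=float)
    l_F = derive_leg_lead_vector(clean)
    lead_ii = (l_F - l_R) @ dipole_trajectory(clean)
    return float(np.ptp(lead_ii))


def draw_planted_tern(
    rng: np.random.Generator,
    gamma_alpha_range: tuple[float, float] = (0.78, 5.69),
    gamma_beta_range: tuple[float, float] = (0.62, 5.69),
) -> WeightTern:
    """Draw a planted tern with the left-leg weight biased upward and the
    gamma/alpha and gamma/beta ratios confined to configurable ranges."""
    for _ in range(10_000):
        tern = repair_weights(rng.dirichlet((2.0, 2.0, 3.0)))
        ra = tern.gamma / tern.alpha
        rb = tern.gamma / tern.beta
        if (
            gamma_alpha_range[0] <= ra <= gamma_alpha_range[1]
            and gamma_beta_range[0] <= rb <= gamma_beta_range[1]
        ):
            return tern
    raise ParameterError("could not draw a tern inside the ratio ranges")


def generate_cohort(
    n: int,
    base: SyntheticParams,
    seed: int,
    gamma_alpha_range: tuple[float, float] = (0.78, 5.69),
    gamma_beta_range: tuple[float, float] = (0.62, 5.69),
    noise_fraction_of_lead_ii: float | None = None,
) -> list[tuple[LimbPotentialRecording, WeightTern]]:
    """Generate ``n`` independent subjects: per-subject planted tern, heart
    rate in [50, 100] bpm, and noise level jittered around the base.

    When ``noise_fraction_of_lead_ii`` is given, each subject's noise
    standard deviation is that fraction of its noise-free lead II
    peak-to-peak instead of the jittered base value.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n):
        params = dataclasses.replace(
            base,
            planted_tern=draw_planted_tern(rng, gamma_alpha_range, gamma_beta_range),
            heart_rate=float(rng.uniform(50.0, 100.0)),
            noise_sd=float(base.noise_sd * rng.uniform(0.5, 1.5)),
            seed=int(rng.integers(2**31)),
            subject_id=f"synthetic-{k:03d}",
        )
        if noise_fraction_of_lead_ii is not None:
            params = dataclasses.replace(
                params,
                noise_sd=noise_fraction_of_lead_ii * lead_ii_peak_to_peak(params),
            )
        cohort.append(generate_recording(params))
    return cohort
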