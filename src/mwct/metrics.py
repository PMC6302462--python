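"""Measurement protocol: beat detection on lead II, five-beat amplitude of a
trace as a percentage of lead II, and QRS-orientation polarity labels.

The beat detector is fixture-grade (band-limited energy + adaptive
threshold + refractory period), validated on synthetic recordings only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import PotentialTrace
from .errors import DegenerateReferenceError, ParameterError, StructuralInputError

#: Polarity labels.
POSITIVE = "positive"
NEGATIVE = "negative"
UNCLEAR = "N"
UNCLASSIFIABLE = "unclassifiable"

#: Minimum spacing between fiducials (seconds).
REFRACTORY_S = 0.250
#: QRS window half-width around each fiducial (seconds).
QRS_HALF_WINDOW_S = 0.060
#: Segment length at each window edge used for the deflection baseline.
BASELINE_EDGE_S = 0.010
#: A deflection dominates when it exceeds the opposite one by this ratio;
#: otherwise the polarity is reported as unclear ("N").
POLARITY_RATIO = 1.2
#: Number of consecutive beats averaged by the amplitude protocol.
N_BEATS_PROTOCOL = 5


@dataclass(frozen=True)
class BeatSet:
    """R-peak fiducials on lead II with per-beat QRS windows."""

    fiducials: np.ndarray
    qrs_windows: tuple
    quality_ok: bool = True

    def __post_init__(self) -> None:
        fid = np.asarray(self.fiducials, dtype=int)
        object.__setattr__(self, "fiducials", fid)
        if len(fid) > 1 and not np.all(np.diff(fid) > 0):
            raise StructuralInputError("fiducials must be strictly increasing")
        if len(fid) != len(self.qrs_windows):
            raise StructuralInputError("one QRS window per fiducial is required")

    @property
    def n_beats(self) -> int:
        return len(self.fiducials)


def detect_beats(lead_ii: PotentialTrace) -> BeatSet:
    """Locate R-peak candidates on lead II.

    Pipeline: band-pass 5-30 Hz, squared derivative, 120 ms moving-window
    integration, adaptive-threshold peak picking with a 250 ms refractory
    period.  QRS windows are fiducial +/- 60 ms, clipped to the trace.
    Returns an empty, flagged :class:`BeatSet` when no peaks are found.
    """
    fs = lead_ii.sample_rate
    x = lead_ii.values
    if len(x) / fs < 2.0:
        raise ParameterError("beat detection needs at least 2 s of signal")

    empty = BeatSet(fiducials=np.array([], dtype=int), qrs_windows=(), quality_ok=False)
    if np.max(np.abs(x)) == 0.0:
        return empty

    high = min(30.0, 0.45 * fs)
    sos = signal.butter(2, [5.0, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(round(0.120 * fs)))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    threshold = max(0.30 * integrated.max(), 8.0 * np.median(integrated))
    peaks, _ = signal.find_peaks(
        integrated, height=threshold, distance=max(1, int(round(REFRACTORY_S * fs)))
    )
    if len(peaks) == 0:
        return empty

    # refine each candidate to the local extremum of the band-passed signal
    half = int(round(QRS_HALF_WINDOW_S * fs))
    fiducials = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        fiducials.append(lo + int(np.argmax(np.abs(filtered[lo:hi]))))
    fiducials = np.unique(fiducials)
    keep = [int(fiducials[0])]
    for f in fiducials[1:]:
        if f - keep[-1] >= REFRACTORY_S * fs:
            keep.append(int(f))
    windows = tuple(
        (max(0, f - half), min(len(x), f + half + 1)) for f in keep
    )
    return BeatSet(fiducials=np.array(keep, dtype=int), qrs_windows=windows)


def _cycles(beats: BeatSet, n_max: int) -> list[tuple[int, int]]:
    fid = beats.fiducials
    return [(int(fid[k]), int(fid[k + 1])) for k in range(min(n_max, len(fid) - 1))]


def amplitude_percent_of_lead_ii(
    trace: PotentialTrace, lead_ii: PotentialTrace, beats: BeatSet
) -> float:
    """Peak-to-peak amplitude of ``trace`` over the first five full beat
    cycles, as a percentage of the lead II peak-to-peak over the same
    cycles (fewer cycles are used when fewer are available)."""
    cycles = _cycles(beats, N_BEATS_PROTOCOL)
    if not cycles:
        raise StructuralInputError("no full beat cycles available")
    trace_pp, lead_pp = [], []
    for lo, hi in cycles:
        seg_t = trace.values[lo:hi]
        seg_l = lead_ii.values[lo:hi]
        trace_pp.append(np.ptp(seg_t))
        lead_pp.append(np.ptp(seg_l))
    mean_lead = float(np.mean(lead_pp))
    if mean_lead == 0.0:
        raise DegenerateReferenceError("lead II excursion is zero")
    return 100.0 * float(np.mean(trace_pp)) / mean_lead


def classify_polarity(trace: PotentialTrace, beats: BeatSet) -> str:
    """QRS-orientation polarity of a trace.

    Per QRS window, deflections are measured from a baseline taken as the
    median of the first and last 10 ms of the window; per-beat maxima are
    aggregated by the median.  The label is unclear ("N") when neither
    deflection dominates by :data:`POLARITY_RATIO`.
    """
    if len(beats.qrs_windows) == 0:
        return UNCLASSIFIABLE
    fs = trace.sample_rate
    edge = max(1, int(round(BASELINE_EDGE_S * fs)))
    pos, neg = [], []
    for lo, hi in beats.qrs_windows:
        seg = trace.values[lo:hi]
        if len(seg) == 0:
            continue
        baseline = float(np.median(np.concatenate([seg[:edge], seg[-edge:]])))
        pos.append(max(0.0, float(np.max(seg - baseline))))
        neg.append(max(0.0, float(np.max(baseline - seg))))
    if not pos:
        return UNCLASSIFIABLE
    p, n = float(np.median(pos)), float(np.median(neg))
    if p > POLARITY_RATIO * n and p > 0:
        return POSITIVE
    if n > POLARITY_RATIO * p and n > 0:
        return NEGATIVE
    return UNCLEAR


@dataclass(frozen=True)
class AmplitudeReport:
    """Five-beat amplitude comparison of the classic and minimized
    terminals against lead II."""

    wct_percent_of_lead_ii: float
    mwct_percent_of_lead_ii: float
    n_beats_used: int
    wct_polarity: str
    mwct_polarity: str
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.wct_percent_of_lead_ii < 0 or self.mwct_percent_of_lead_ii < 0:
            raise StructuralInputError("percentages must be non-negative")


def build_amplitude_report(
    wct: PotentialTrace,
    mwct: PotentialTrace,
    lead_ii: PotentialTrace,
    beats: BeatSet,
) -> AmplitudeReport:
    """Assemble the full amplitude/polarity report for one recording."""
    n_cycles = max(0, beats.n_beats - 1)
    n_used = min(N_BEATS_PROTOCOL, n_cycles)
    return AmplitudeReport(
        wct_percent_of_lead_ii=amplitude_percent_of_lead_ii(wct, lead_ii, beats),
        mwct_percent_of_lead_ii=amplitude_percent_of_lead_ii(mwct, lead_ii, beats),
        n_beats_used=n_used,
        wct_polarity=classify_polarity(wct, beats),
        mwct_polarity=classify_polarity(mwct, beats),
        quality_ok=beats.quality_ok and n_used == N_BEATS_PROTOCOL,
    )
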