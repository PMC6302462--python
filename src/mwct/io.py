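"""CSV recording dialect and JSON result documents.

Recording files are UTF-8 CSV with the exact header
``time_s,phi_L_V,phi_R_V,phi_F_V``; potentials are in volts and the time
column must be strictly increasing and uniformly spaced (the sample rate is
inferred from the spacing).  Result documents are schema-versioned JSON
serialized deterministically so identical runs produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LimbPotentialRecording, WeightTern
from .errors import FormatError, SamplingError

RECORDING_COLUMNS = ("time_s", "phi_L_V", "phi_R_V", "phi_F_V")
RELATIVE_JITTER_TOLERANCE = 1e-9
SCHEMA_VERSION = "1"


def read_recording(path, subject_id: str | None = None) -> LimbPotentialRecording:
    """Read a dialect-conformant CSV recording, inferring the sample rate."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a parseable CSV file ({exc})") from exc
    for column in RECORDING_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column '{column}'")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: a recording needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time_s must be strictly increasing")
    dt0 = float(np.median(dt))
    if np.max(np.abs(dt - dt0)) > RELATIVE_JITTER_TOLERANCE * dt0 + 1e-15:
        raise SamplingError(f"{path}: time_s is not uniformly spaced")
    return LimbPotentialRecording(
        phi_L=frame["phi_L_V"].to_numpy(dtype=float),
        phi_R=frame["phi_R_V"].to_numpy(dtype=float),
        phi_F=frame["phi_F_V"].to_numpy(dtype=float),
        sample_rate=1.0 / dt0,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_recording(rec: LimbPotentialRecording, path) -> None:
    """Write a recording in the CSV dialect with full float precision."""
    path = Path(path)
    lines = [",".join(RECORDING_COLUMNS)]
    for i in range(rec.n_samples):
        lines.append(
            f"{i / rec.sample_rate:.17g},{rec.phi_L[i]:.17g},"
            f"{rec.phi_R[i]:.17g},{rec.phi_F[i]:.17g}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ResultDocument:
    """Per-recording minimization result, serialized as JSON."""

    subject_id: str
    alpha: float
    beta: float
    gamma: float
    fitness: float
    generations_used: int
    wct_percent_of_lead_ii: float
    mwct_percent_of_lead_ii: float
    wct_polarity: str
    mwct_polarity: str
    n_beats_used: int
    quality_ok: bool
    mode: str
    config: dict
    tool_version: str
    schema_version: str = SCHEMA_VERSION

    @property
    def best_tern(self) -> WeightTern:
        return WeightTern(self.alpha, self.beta, self.gamma)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ResultDocument":
        payload = json.loads(text)
        try:
            return cls(**payload)
        except TypeError as exc:
            raise FormatError(f"malformed result document: {exc}") from exc


def write_result(doc: ResultDocument, path) -> None:
    Path(path).write_text(doc.to_json(), encoding="utf-8")


def read_result(path) -> ResultDocument:
    return ResultDocument.from_json(Path(path).read_text(encoding="utf-8"))
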