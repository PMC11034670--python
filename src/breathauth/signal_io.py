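"""Reading and writing exhaled-breath time series and cohort manifests.

A breath recording is a single exhalation captured by a hot-wire anemometer:
a positive voltage (or calibrated velocity) sampled at high rate, nominally
10 kHz for 1.5 s. Signals are exchanged as single-column text files (one
sample per line, ``#`` comment lines allowed); a cohort is described by a CSV
manifest with columns ``user_id,trial_id,file``.

An order-4 polynomial calibration utility converts anemometer voltage to
velocity; the analysis pipeline itself runs on raw voltage, so calibration
is optional and only establishes that voltage and velocity are monotonically
related over the calibrated range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreathSignal",
    "CohortManifest",
    "CalibrationFit",
    "MalformedSignalError",
    "read_signal",
    "write_signal",
    "load_manifest",
    "save_manifest",
    "fit_calibration",
]

#: Minimum number of samples for which the default segmentation (window of
#: one tenth of the record, slide of half a window) is well defined.
MIN_SIGNAL_LENGTH = 20


class MalformedSignalError(ValueError):
    """Raised for unreadable, empty, non-numeric or too-short signal files."""


@dataclass(frozen=True)
class BreathSignal:
    """One exhalation trial.

    Parameters
    ----------
    values
        Sample values (voltage or velocity, arbitrary units).
    sampling_rate_hz
        Acquisition rate; nominally 10000.
    user_id, trial_id
        Identity of the subject and of the recording.
    """

    values: np.ndarray
    sampling_rate_hz: float
    user_id: str
    trial_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise MalformedSignalError("signal must be one-dimensional")
        if values.size < MIN_SIGNAL_LENGTH:
            raise MalformedSignalError(
                f"signal has {values.size} samples; at least "
                f"{MIN_SIGNAL_LENGTH} required"
            )
        if not np.all(np.isfinite(values)):
            raise MalformedSignalError("signal contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise MalformedSignalError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return self.values.size / self.sampling_rate_hz


@dataclass
class CohortManifest:
    """Mapping from (user, trial) to signal files, plus free-form metadata."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(u, t) for u, t, _ in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (user_id, trial_id) pairs: {dupes}")

    @property
    def user_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for u, _, _ in self.entries:
            seen.setdefault(u)
        return list(seen)

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    def trials_of(self, user_id: str) -> list[tuple[str, str]]:
        """(trial_id, file) pairs of one user, in manifest order."""
        return [(t, f) for u, t, f in self.entries if u == user_id]

    def trial_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for u, _, _ in self.entries:
            counts[u] = counts.get(u, 0) + 1
        return counts


@dataclass(frozen=True)
class CalibrationFit:
    """Order-4 voltage-to-velocity polynomial (ascending coefficients)."""

    coefficients: np.ndarray
    fit_residual: float
    monotone: bool = True

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (5,):
            raise ValueError("calibration requires exactly 5 coefficients")
        object.__setattr__(self, "coefficients", coef)
        if self.fit_residual < 0:
            raise ValueError("fit_residual must be non-negative")

    def __call__(self, voltage: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(voltage, float),
                                                self.coefficients)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "coefficients": self.coefficients.tolist(),
            "fit_residual": self.fit_residual,
            "monotone": self.monotone,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationFit":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["coefficients"], float),
                   float(d["fit_residual"]), bool(d["monotone"]))


def read_signal(path: str | Path, sampling_rate_hz: float = 10_000.0,
                user_id: str = "", trial_id: str = "") -> BreathSignal:
    """Read a single-column text file into a :class:`BreathSignal`.

    One numeric sample per line; lines starting with ``#`` are ignored.
    """
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise MalformedSignalError(f"cannot read {path}: {exc}") from exc
    values = []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise MalformedSignalError(
                f"{path}:{lineno}: non-numeric sample {line!r}") from exc
    if not values:
        raise MalformedSignalError(f"{path}: no samples")
    return BreathSignal(np.asarray(values), sampling_rate_hz,
                        user_id=user_id, trial_id=trial_id)


def write_signal(signal: BreathSignal | Sequence[float],
                 path: str | Path) -> None:
    """Write samples as one value per line at full float precision."""
    values = signal.values if isinstance(signal, BreathSignal) else np.asarray(signal)
    Path(path).write_text(
        "\n".join(repr(float(v)) for v in values) + "\n")


def load_manifest(path: str | Path,
                  metadata: Mapping | None = None) -> CohortManifest:
    """Load a cohort manifest CSV (columns ``user_id,trial_id,file``).

    Relative file paths are resolved against the manifest's directory.
    Raises if a referenced file does not exist or a (user, trial) pair
    repeats.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    required = {"user_id", "trial_id", "file"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    entries = []
    for _, row in table.iterrows():
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file: {fpath}")
        entries.append((row["user_id"], row["trial_id"], str(fpath)))
    return CohortManifest(entries, dict(metadata or {}))


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(manifest.entries,
                 columns=["user_id", "trial_id", "file"]).to_csv(path, index=False)


def fit_calibration(voltages: Sequence[float],
                    velocities: Sequence[float]) -> CalibrationFit:
    """Least-squares order-4 polynomial fit of velocity against voltage.

    Monotonicity of the fitted curve over the input voltage range is checked
    on a 1000-point grid of the derivative polynomial; a non-monotone fit is
    returned with ``monotone=False`` rather than rejected, since it signals
    a probe or data problem the caller should inspect.
    """
    v = np.asarray(voltages, dtype=float)
    u = np.asarray(velocities, dtype=float)
    if v.size != u.size:
        raise ValueError("voltages and velocities must have equal length")
    if v.size < 5:
        raise ValueError("order-4 fit needs at least 5 points")
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be strictly increasing")
    coef, diag = np.polynomial.polynomial.polyfit(v, u, 4, full=True)
    resid_list = diag[0]
    residual = float(resid_list[0]) if len(resid_list) else 0.0
    deriv = np.polynomial.polynomial.polyder(coef)
    grid = np.linspace(v.min(), v.max(), 1000)
    monotone = bool(np.all(np.polynomial.polynomial.polyval(grid, deriv) > 0))
    return CalibrationFit(coef, residual, monotone)
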