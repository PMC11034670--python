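"""Sliding-window segmentation and z-score normalization.

A 1.5 s record sampled at 10 kHz is split into overlapping windows of one
tenth of the record length, slid by half a window, yielding 19 segments of
1500 samples in the nominal design; every interior sample then appears in
exactly two segments. Each segment is standardized to zero mean and unit
(population) standard deviation, making all downstream features unitless
and independent of the sensor's absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import BreathSignal

__all__ = [
    "Segment",
    "NormalizedSegment",
    "DegenerateSegmentError",
    "segment",
    "zscore_normalize",
    "prepare_trial",
]


class DegenerateSegmentError(ValueError):
    """A constant segment cannot be z-scored (zero standard deviation)."""


@dataclass(frozen=True)
class Segment:
    values: np.ndarray
    start_index: int
    parent_trial_id: str = ""
    user_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class NormalizedSegment:
    """Unitless, zero-mean, unit-variance view of a :class:`Segment`."""

    values: np.ndarray
    source: Segment

    def __len__(self) -> int:
        return int(self.values.size)


def segment(signal: BreathSignal, window_fraction: float = 1 / 10,
            slide_fraction_of_window: float = 1 / 2) -> list[Segment]:
    """Split a trial into overlapping fixed-width segments.

    The window is ``floor(N * window_fraction)`` samples and consecutive
    segments start ``floor(window * slide_fraction_of_window)`` samples
    apart; trailing samples that do not fill a window are dropped (padding
    would fabricate data). A 15000-sample record with the defaults yields
    19 segments of 1500 samples.
    """
    x = signal.values
    n = x.size
    w = int(n * window_fraction)
    if w < 2:
        raise ValueError(f"window of {w} samples is too short (need >= 2)")
    s = int(w * slide_fraction_of_window)
    if s < 1:
        raise ValueError("slide width must be at least 1 sample")
    starts = range(0, n - w + 1, s)
    return [Segment(x[i:i + w], i, signal.trial_id, signal.user_id)
            for i in starts]


def zscore_normalize(seg: Segment) -> NormalizedSegment:
    """Standardize a segment: z(i) = (x(i) - mean) / sd, population sd."""
    x = seg.values
    sd = float(x.std())  # ddof=0
    if sd == 0.0:
        raise DegenerateSegmentError(
            f"segment at {seg.start_index} is constant; cannot normalize")
    return NormalizedSegment((x - x.mean()) / sd, seg)


def prepare_trial(signal: BreathSignal, window_fraction: float = 1 / 10,
                  slide_fraction_of_window: float = 1 / 2,
                  normalize_scope: str = "segment") -> list[NormalizedSegment]:
    """Segment a trial and z-score each segment.

    ``normalize_scope="trial"`` standardizes the whole record first and then
    segments it (each returned segment re-wrapped without further scaling);
    the default ``"segment"`` standardizes each window independently so that
    every feature-extraction unit is self-normalized. Constant segments are
    silently excluded — they carry no temporal structure.
    """
    if normalize_scope not in ("segment", "trial"):
        raise ValueError("normalize_scope must be 'segment' or 'trial'")
    if normalize_scope == "trial":
        sd = float(signal.values.std())
        if sd == 0.0:
            raise DegenerateSegmentError("constant trial; cannot normalize")
        signal = BreathSignal((signal.values - signal.values.mean()) / sd,
                              signal.sampling_rate_hz, signal.user_id,
                              signal.trial_id)
    out = []
    for seg in segment(signal, window_fraction, slide_fraction_of_window):
        if normalize_scope == "trial":
            out.append(NormalizedSegment(seg.values, seg))
            continue
        try:
            out.append(zscore_normalize(seg))
        except DegenerateSegmentError:
            continue
    return out
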