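"""Breath counting and respiration-rate estimation.

Waveforms are first normalised to [-1, 1].  Counting then uses amplitude
thresholding at +-0.2 with two ordering rules: a leading trough is
discarded, and consecutive peaks without an intervening trough collapse to
the first of them — each retained trough closes one full breath with the
pending peak that precedes it.  A trailing unpaired peak does not count
(only the closing trough completes a breath).

The respiration rate is available from three independent estimators (breath
counting, spectral peak, autocorrelation), which agree on clean signals and
provide a built-in consistency check on real ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .vitals_dsp import RespWaveform, spectral_estimate

__all__ = [
    "NormalizedWaveform",
    "Extremum",
    "BreathCount",
    "normalize",
    "find_extrema",
    "scan_extrema_sequence",
    "count_breaths",
    "respiration_rate",
]

logger = logging.getLogger(__name__)

#: Normalised-amplitude threshold for breath counting: peaks above +0.2 and
#: troughs below -0.2 count as candidate events, excluding inconspicuous
#: ripples.
COUNT_THRESHOLD = 0.2


@dataclass
class NormalizedWaveform:
    """Waveform scaled so that max |value| = 1 (zero input stays zero)."""

    values: np.ndarray
    sampling_rate: float
    normalization_factor: float
    degenerate: bool = False

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate


@dataclass(frozen=True)
class Extremum:
    """A candidate counting event: a thresholded local peak or trough."""

    index: int
    time: float
    value: float
    kind: str                 # "peak" | "trough"


@dataclass
class BreathCount:
    """Closed-breath count with the paired events and the discard log."""

    count: int
    peak_times: list[float]
    trough_times: list[float]
    discarded_events: list[tuple[float, str]] = field(default_factory=list)


def normalize(waveform: RespWaveform) -> NormalizedWaveform:
    """Scale to [-1, 1] by the max absolute value; flags all-zero input."""
    values = np.asarray(waveform.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty waveform")
    factor = float(np.max(np.abs(values)))
    if factor == 0:
        logger.warning("normalize: all-zero waveform")
        return NormalizedWaveform(values=values.copy(),
                                  sampling_rate=waveform.sampling_rate,
                                  normalization_factor=1.0, degenerate=True)
    return NormalizedWaveform(values=values / factor,
                              sampling_rate=waveform.sampling_rate,
                              normalization_factor=factor)


def find_extrema(values: np.ndarray, sampling_rate: float,
                 threshold: float) -> list[Extremum]:
    """Thresholded local extrema in time order.

    A peak is a strict three-point local maximum with value > +threshold; a
    trough a strict local minimum with value < -threshold.  Plateaus (runs
    of equal samples) count once, at their midpoint sample.
    """
    values = np.asarray(values, dtype=float)
    events: list[Extremum] = []
    n = len(values)
    if n < 3:
        return events

    # Collapse runs of equal values to single plateau nodes.
    starts = [0]
    for i in range(1, n):
        if values[i] != values[starts[-1]]:
            starts.append(i)
    for j in range(1, len(starts) - 1):
        s = starts[j]
        e = starts[j + 1] - 1                 # plateau [s, e]
        v = values[s]
        left, right = values[starts[j - 1]], values[starts[j + 1]]
        mid = (s + e) // 2
        if left < v > right and v > threshold:
            events.append(Extremum(mid, mid / sampling_rate, v, "peak"))
        elif left > v < right and v < -threshold:
            events.append(Extremum(mid, mid / sampling_rate, v, "trough"))
    return events


def scan_extrema_sequence(events: list[Extremum]) -> BreathCount:
    """Ordering rules applied to a time-ordered candidate-event sequence.

    Leading troughs (no peak yet) are discarded; repeated peaks keep only
    the first pending one; each trough after a pending peak closes a
    breath; a trailing unpaired peak is discarded.
    """
    count = 0
    pending: Extremum | None = None
    peak_times: list[float] = []
    trough_times: list[float] = []
    discarded: list[tuple[float, str]] = []
    for ev in events:
        if ev.kind == "trough":
            if pending is None:
                discarded.append((ev.time, "leading trough"))
            else:
                count += 1
                peak_times.append(pending.time)
                trough_times.append(ev.time)
                pending = None
        else:
            if pending is None:
                pending = ev
            else:
                discarded.append((ev.time, "repeated peak"))
    if pending is not None:
        discarded.append((pending.time, "trailing unpaired peak"))
    return BreathCount(count=count, peak_times=peak_times,
                       trough_times=trough_times, discarded_events=discarded)


def count_breaths(waveform: NormalizedWaveform,
                  threshold: float = COUNT_THRESHOLD) -> BreathCount:
    """Count full breaths in a normalised waveform."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    events = find_extrema(waveform.values, waveform.sampling_rate, threshold)
    return scan_extrema_sequence(events)


# ---------------------------------------------------------------------------
# Respiration rate
# ---------------------------------------------------------------------------

#: Autocorrelation peaks must exceed this normalised value to count as a
#: significant breathing period.
AUTOCORR_SIGNIFICANCE = 0.2


def _autocorr_rate(values: np.ndarray, fs: float) -> float:
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    if not np.any(x != 0):
        return float("nan")
    r = np.correlate(x, x, mode="full")[len(x) - 1:]
    r = r / r[0]
    min_lag = int(np.ceil(2.0 * fs)) + 1      # beyond 1/(0.5 Hz)
    # first significant local maximum beyond min_lag
    for k in range(max(min_lag, 1), len(r) - 1):
        if r[k] >= r[k - 1] and r[k] > r[k + 1] and r[k] > AUTOCORR_SIGNIFICANCE:
            denom = r[k - 1] - 2 * r[k] + r[k + 1]
            delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
            lag = k + float(np.clip(delta, -0.5, 0.5))
            return 60.0 * fs / lag
    return float("nan")


def respiration_rate(waveform: RespWaveform | NormalizedWaveform,
                     method: str = "spectral",
                     threshold: float = COUNT_THRESHOLD) -> float:
    """Respiration rate in breaths per minute.

    ``method`` selects the estimator:

    * ``"peaks"``  — 60 * counted breaths / record duration;
    * ``"spectral"`` — 60 * dominant periodogram frequency;
    * ``"autocorrelation"`` — 60 / (first significant autocorrelation
      period beyond 2 s).

    Requires at least 10 s of signal.  Degenerate signals yield ``nan``
    with a warning.
    """
    if isinstance(waveform, NormalizedWaveform):
        norm = waveform
        resp = RespWaveform(values=waveform.values,
                            sampling_rate=waveform.sampling_rate)
    else:
        resp = waveform
        norm = normalize(waveform)
    if resp.duration < 10.0:
        raise ValueError("need at least 10 s of signal for a rate estimate")
    if norm.degenerate:
        logger.warning("respiration_rate: degenerate signal")
        return float("nan")

    if method == "peaks":
        return 60.0 * count_breaths(norm, threshold).count / norm.duration
    if method == "spectral":
        freq = spectral_estimate(resp)
        return 60.0 * freq
    if method == "autocorrelation":
        return _autocorr_rate(norm.values, norm.sampling_rate)
    raise ValueError(f"unknown method {method!r}")
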