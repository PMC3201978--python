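"""Spike detection by detrend-and-threshold, and four-class response
classification of long-term recordings.

The ratio trace is detrended by subtracting a centred moving average
(default width 6.25 s), which removes slow drift and sustained plateaus
while leaving fast transients.  Maximal runs of the detrended trace above
a fixed threshold (default 0.4) that last at least a minimum width
(default 5 s) are counted as spikes.  Responding cells are then sorted
into four classes from the spike count n, the mean interspike interval
(ISI) and the AUC:

=================  =========================================
single spike SS    n = 1 and AUC < 500
burst BS           n > 1, ISI*n <= 300 and AUC > 1000
repetitive RS      n > 1 and ISI*n > 300
sustained SU       n = 1 and AUC > 500
=================  =========================================

Combinations matching none of the rules (including n = 0 and the exact
boundaries) are UNCLASSIFIED.  Everything here is deterministic.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_io import (
    AnalysisConfig,
    InsufficientDataError,
    NormalizedTrace,
    long_term_config,
)
from . import kinetics

__all__ = [
    "ResponseClass",
    "SpikeTrain",
    "smooth_detrend",
    "detect_spikes",
    "classify",
    "classify_trace",
    "classify_population",
]


class ResponseClass(str, enum.Enum):
    """The four response categories plus the catch-all."""

    SS = "SS"           # single spike
    BS = "BS"           # burst of spikes
    RS = "RS"           # repetitive spikes
    SU = "SU"           # sustained response
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SpikeTrain:
    """Detected spikes for one cell."""

    cell_id: str
    spike_peak_times_s: np.ndarray
    onsets_s: np.ndarray
    offsets_s: np.ndarray

    @property
    def count(self) -> int:
        return len(self.spike_peak_times_s)

    @property
    def mean_isi_s(self) -> float | None:
        """Mean spacing of successive spike peaks; None below 2 spikes."""
        if self.count < 2:
            return None
        return float(np.mean(np.diff(self.spike_peak_times_s)))


def _window_samples(smooth_window_s: float, dt: float) -> int:
    w = int(round(smooth_window_s / dt))
    if w % 2 == 0:  # a centred window needs odd length
        w += 1
    return max(w, 3)


def smooth_detrend(ntrace: NormalizedTrace,
                   config: AnalysisConfig | None = None) -> np.ndarray:
    """Subtract a centred moving average from the ratio trace.

    The window is specified in seconds and converted to an odd number of
    samples per trace (13 samples at 2 Hz, 51 at 8 Hz for the default
    6.25 s).  At the edges the window shrinks symmetrically, so a
    constant trace detrends to exactly zero everywhere and a straight
    line detrends to zero in the interior.
    """
    config = config or AnalysisConfig()
    ratio = ntrace.ratio
    n = len(ratio)
    w = _window_samples(config.smooth_window_s, ntrace.dt)
    if n <= w:
        raise InsufficientDataError(
            f"cell {ntrace.cell_id!r}: trace of {n} samples is shorter "
            f"than the {w}-sample smoothing window")
    half = w // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(ratio)))
    smoothed = (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)
    return ratio - smoothed


def detect_spikes(times: np.ndarray, detrended: np.ndarray,
                  config: AnalysisConfig | None = None,
                  cell_id: str = "") -> SpikeTrain:
    """Find maximal supra-threshold runs lasting at least the minimum width.

    A spike is a maximal contiguous run of samples with detrended value
    strictly above ``spike_threshold`` whose time span (last minus first
    sample of the run) is at least ``spike_min_width_s``; its peak time
    is the time of the run maximum.
    """
    config = config or AnalysisConfig()
    times = np.asarray(times, dtype=float)
    detrended = np.asarray(detrended, dtype=float)
    above = detrended > config.spike_threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above.size and above[0]:
        starts = np.concatenate(([0], starts))
    if above.size and above[-1]:
        ends = np.concatenate((ends, [above.size - 1]))
    peaks, onsets, offsets = [], [], []
    for i0, i1 in zip(starts, ends):
        if times[i1] - times[i0] < config.spike_min_width_s:
            continue
        j = i0 + int(np.argmax(detrended[i0:i1 + 1]))
        peaks.append(times[j])
        onsets.append(times[i0])
        offsets.append(times[i1])
    return SpikeTrain(
        cell_id=cell_id,
        spike_peak_times_s=np.asarray(peaks, dtype=float),
        onsets_s=np.asarray(onsets, dtype=float),
        offsets_s=np.asarray(offsets, dtype=float))


def classify(count: int, mean_isi_s: float | None, auc: float,
             config: AnalysisConfig | None = None) -> ResponseClass:
    """Apply the four classification rules to one cell's features.

    Boundary combinations (AUC exactly at a cutoff, or a multi-spike
    cell with ISI*n <= 300 but AUC <= 1000) satisfy no rule and map to
    UNCLASSIFIED rather than being forced into a nearest class.
    """
    config = config or AnalysisConfig()
    if count < 0 or auc < 0 or (mean_isi_s is not None and mean_isi_s < 0):
        raise ValueError("spike count, ISI and AUC must be non-negative")
    if count == 1:
        if auc < config.class_auc_low:
            return ResponseClass.SS
        if auc > config.class_auc_low:
            return ResponseClass.SU
        return ResponseClass.UNCLASSIFIED
    if count > 1:
        if mean_isi_s is None:
            raise ValueError("mean ISI required when count > 1")
        product = mean_isi_s * count
        if product > config.class_isi_product:
            return ResponseClass.RS
        if auc > config.class_auc_high:
            return ResponseClass.BS
        return ResponseClass.UNCLASSIFIED
    return ResponseClass.UNCLASSIFIED


def classify_trace(ntrace: NormalizedTrace,
                   config: AnalysisConfig | None = None
                   ) -> tuple[SpikeTrain, ResponseClass | None, float | None]:
    """Run detrend -> spike detection -> classification on one cell.

    Returns the spike train, the class label and the AUC used.  The
    label is None for non-responders (which are not classified).  The
    default configuration is the long-term one (baseline-subtracted
    AUC): the 500/1000 fold*s cutoffs are only meaningful once the
    resting ratio of ~1 is removed from the integral.
    """
    config = config or long_term_config()
    detrended = smooth_detrend(ntrace, config)
    train = detect_spikes(ntrace.times, detrended, config, ntrace.cell_id)
    if not kinetics.is_responder(ntrace, config):
        return train, None, None
    auc = kinetics.area_under_curve(ntrace, config)
    return train, classify(train.count, train.mean_isi_s, auc, config), auc


def classify_population(ntraces: Iterable[NormalizedTrace],
                        config: AnalysisConfig | None = None
                        ) -> tuple[pd.DataFrame, dict[ResponseClass, int]]:
    """Classify every responding cell of a population.

    Returns a per-cell table (``cell_id, spike_count, mean_isi_s, auc,
    label``; non-responders have an empty label) and a count table over
    the five labels covering the responding cells only.
    """
    config = config or long_term_config()
    rows = []
    counts: Counter = Counter({cls: 0 for cls in ResponseClass})
    for nt in ntraces:
        train, label, auc = classify_trace(nt, config)
        if label is not None:
            counts[label] += 1
        rows.append({
            "cell_id": nt.cell_id,
            "spike_count": train.count,
            "mean_isi_s": train.mean_isi_s,
            "auc": auc,
            "label": label.value if label is not None else "",
        })
    frame = pd.DataFrame(
        rows, columns=["cell_id", "spike_count", "mean_isi_s", "auc",
                       "label"])
    return frame, dict(counts)
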