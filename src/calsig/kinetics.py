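"""Per-cell kinetic feature extraction from normalized traces.

Four kinetic parameters summarize each responding cell's F/F0 time
course after agonist addition:

* **peak** - the largest fold change Fmax/F0 at or after the stimulus;
* **rise time** - the time to climb from 10% to 90% of the
  baseline-subtracted peak amplitude;
* **latency** - the time from agonist addition to the first 10%-of-peak
  crossing;
* **AUC** - the trapezoidal integral of the trace from that 10% crossing
  to the end of the recording.

Percent-of-peak levels are taken relative to the baseline-subtracted
amplitude A = peak - 1 (a "10% of peak" level of 1 + 0.1*A), and
threshold crossings are located by linear interpolation between samples,
searching only between the stimulus and the peak; the first crossing
wins.  Features other than the peak are undefined for non-responders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trace_io import (
    AnalysisConfig,
    NormalizedTrace,
    UndefinedFeatureError,
)

__all__ = [
    "KineticFeatures",
    "is_responder",
    "peak_amplitude",
    "rise_time",
    "latency",
    "area_under_curve",
    "extract_features",
    "features_to_frame",
]


@dataclass
class KineticFeatures:
    """Responder flag and kinetic parameters for one cell.

    Fields that are undefined (non-responder, or excluded for
    pre-stimulus activity) are ``None``.
    """

    cell_id: str
    responder: bool
    peak: float
    t_peak_s: float
    rise_time_s: float | None = None
    latency_s: float | None = None
    auc: float | None = None
    t10_s: float | None = None
    excluded: bool = False


def _responder_threshold(ntrace: NormalizedTrace,
                         config: AnalysisConfig) -> float:
    if config.responder_mode == "adaptive_3sd":
        return 1.0 + 3.0 * ntrace.baseline_sd_ratio
    return config.responder_fold


def is_responder(ntrace: NormalizedTrace,
                 config: AnalysisConfig | None = None) -> bool:
    """True when the maximum post-stimulus F/F0 strictly exceeds the
    responder threshold (default the fixed 1.045 fold change)."""
    config = config or AnalysisConfig()
    post = ntrace.ratio[ntrace.post_mask]
    if post.size == 0:
        return False
    return bool(post.max() > _responder_threshold(ntrace, config))


def peak_amplitude(ntrace: NormalizedTrace) -> tuple[float, float]:
    """Largest post-stimulus fold change and the earliest time attaining it."""
    mask = ntrace.post_mask
    post = ntrace.ratio[mask]
    if post.size == 0:
        raise UndefinedFeatureError(
            f"cell {ntrace.cell_id!r}: no samples at or after the stimulus")
    i = int(np.argmax(post))  # argmax returns the first maximum
    return float(post[i]), float(ntrace.times[mask][i])


def _first_crossing(times: np.ndarray, values: np.ndarray,
                    level: float) -> float:
    """Earliest time ``values`` reaches ``level``, linearly interpolated.

    ``values[-1]`` is guaranteed >= level by the callers (the segment
    ends at the peak).  If the first sample already sits at or above the
    level the segment start time is returned.
    """
    above = values >= level
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def _t10_t90(ntrace: NormalizedTrace,
             config: AnalysisConfig) -> tuple[float, float]:
    peak, t_peak = peak_amplitude(ntrace)
    amp = peak - 1.0
    if amp <= 0:
        raise UndefinedFeatureError(
            f"cell {ntrace.cell_id!r}: non-positive response amplitude")
    seg = ntrace.post_mask & (ntrace.times <= t_peak)
    times = ntrace.times[seg]
    values = ntrace.ratio[seg]
    t10 = _first_crossing(times, values,
                          1.0 + config.rise_fraction_low * amp)
    t90 = _first_crossing(times, values,
                          1.0 + config.rise_fraction_high * amp)
    return t10, t90


def _require_responder(ntrace: NormalizedTrace,
                       config: AnalysisConfig) -> None:
    if not is_responder(ntrace, config):
        raise UndefinedFeatureError(
            f"cell {ntrace.cell_id!r} is not a responder")


def rise_time(ntrace: NormalizedTrace,
              config: AnalysisConfig | None = None) -> float:
    """Time to rise from 10% to 90% of the baseline-subtracted peak."""
    config = config or AnalysisConfig()
    _require_responder(ntrace, config)
    t10, t90 = _t10_t90(ntrace, config)
    return t90 - t10


def latency(ntrace: NormalizedTrace,
            config: AnalysisConfig | None = None) -> float:
    """Time from agonist addition to the first 10%-of-peak crossing."""
    config = config or AnalysisConfig()
    _require_responder(ntrace, config)
    t10, _ = _t10_t90(ntrace, config)
    return t10 - ntrace.stim_time


def area_under_curve(ntrace: NormalizedTrace,
                     config: AnalysisConfig | None = None) -> float:
    """Trapezoidal integral of the trace from the 10%-of-peak crossing
    to the end of the recording.

    The integrand is F/F0 itself (``raw_ratio``) or F/F0 - 1
    (``baseline_subtracted``) according to the configuration.
    """
    config = config or AnalysisConfig()
    _require_responder(ntrace, config)
    t10, _ = _t10_t90(ntrace, config)
    after = ntrace.times > t10
    times = np.concatenate(([t10], ntrace.times[after]))
    start = float(np.interp(t10, ntrace.times, ntrace.ratio))
    values = np.concatenate(([start], ntrace.ratio[after]))
    if config.auc_integrand == "baseline_subtracted":
        values = values - 1.0
    return float(np.trapezoid(values, times))


def extract_features(ntrace: NormalizedTrace,
                     config: AnalysisConfig | None = None,
                     excluded: bool = False) -> KineticFeatures:
    """All kinetic parameters for one cell.

    Excluded cells (pre-stimulus activity) and non-responders get the
    peak only; rise time, latency, AUC and t10 stay undefined.
    """
    config = config or AnalysisConfig()
    peak, t_peak = peak_amplitude(ntrace)
    responder = (not excluded) and is_responder(ntrace, config)
    feats = KineticFeatures(
        cell_id=ntrace.cell_id, responder=responder, peak=peak,
        t_peak_s=t_peak, excluded=excluded)
    if responder:
        t10, t90 = _t10_t90(ntrace, config)
        feats.t10_s = t10
        feats.rise_time_s = t90 - t10
        feats.latency_s = t10 - ntrace.stim_time
        feats.auc = area_under_curve(ntrace, config)
    return feats


def features_to_frame(features: Iterable[KineticFeatures]) -> pd.DataFrame:
    """Tabulate features, one row per cell; undefined fields become NaN."""
    rows = [
        {
            "cell_id": f.cell_id,
            "responder": f.responder,
            "excluded": f.excluded,
            "peak": f.peak,
            "rise_time_s": f.rise_time_s,
            "latency_s": f.latency_s,
            "auc": f.auc,
            "t_peak_s": f.t_peak_s,
            "t10_s": f.t10_s,
        }
        for f in features
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "responder", "excluded", "peak",
                       "rise_time_s", "latency_s", "auc", "t_peak_s",
                       "t10_s"])
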