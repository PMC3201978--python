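"""Reading, writing and F/F0 normalization of per-cell fluorescence traces.

A recording is a set of per-cell fluorescence time series (arbitrary
intensity units) with a known agonist-addition time.  Each trace is
normalized to the dimensionless ratio F/F0, where F0 is the mean intensity
over the pre-stimulus baseline window (the 20 s immediately preceding
agonist addition).  Cells whose ratio already exceeds the responder
threshold before the stimulus carry an "excluded" flag: their activity
cannot be attributed to the agonist.

Two tabular text layouts are supported:

* ``wide``: first column ``time_s``, one column per cell, shared time base.
* ``long``: columns ``cell_id,time_s,intensity``, one row per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CalsigError",
    "ValidationError",
    "TraceFormatError",
    "InsufficientBaselineError",
    "InsufficientDataError",
    "DataError",
    "UndefinedFeatureError",
    "AnalysisConfig",
    "Trace",
    "NormalizedTrace",
    "read_traces",
    "write_traces",
    "normalize",
    "excluded_prestim",
    "write_normalized",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CalsigError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CalsigError):
    """A configuration or parameter record violates its invariants."""


class TraceFormatError(CalsigError):
    """An input file is malformed (missing, non-numeric or unordered data)."""


class InsufficientBaselineError(CalsigError):
    """Fewer than two samples fall inside the pre-stimulus baseline window."""


class InsufficientDataError(CalsigError):
    """A trace is too short for the requested operation."""


class DataError(CalsigError):
    """Numerically invalid data (e.g. non-positive baseline fluorescence)."""


class UndefinedFeatureError(CalsigError):
    """A kinetic feature was requested for a cell on which it is undefined."""


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

_AUC_INTEGRANDS = ("raw_ratio", "baseline_subtracted")
_RESPONDER_MODES = ("fixed", "adaptive_3sd")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every threshold of the analysis in one validated record.

    Parameters
    ----------
    baseline_window_s
        Length of the pre-stimulus window used for F0 (seconds).  The
        window is ``[stim_time - baseline_window_s, stim_time)``, half-open
        at the stimulus.
    responder_fold
        A cell is a responder when its post-stimulus F/F0 exceeds this
        fold change (strict ``>``).
    smooth_window_s
        Width of the centred moving average subtracted from the ratio
        trace before spike detection (seconds).
    spike_threshold
        Detrended-ratio level a spike must exceed (dimensionless).
    spike_min_width_s
        Minimum duration a supra-threshold excursion must last to count
        as a spike (seconds).
    class_auc_low, class_auc_high
        AUC cutoffs (fold*s) splitting single-spike vs sustained
        responses (low) and gating the burst class (high).
    class_isi_product
        Cutoff on mean interspike interval x spike count (seconds)
        separating bursts from repetitive spiking.
    auc_integrand
        ``"raw_ratio"`` integrates F/F0 itself; ``"baseline_subtracted"``
        integrates F/F0 - 1.
    responder_mode
        ``"fixed"`` uses ``responder_fold``; ``"adaptive_3sd"`` uses
        1 + 3 x the baseline SD of the ratio, per cell.
    rise_fraction_low, rise_fraction_high
        Fractions of the baseline-subtracted peak bounding the rise-time
        measurement (default 10% to 90%).
    """

    baseline_window_s: float = 20.0
    responder_fold: float = 1.045
    smooth_window_s: float = 6.25
    spike_threshold: float = 0.4
    spike_min_width_s: float = 5.0
    class_auc_low: float = 500.0
    class_auc_high: float = 1000.0
    class_isi_product: float = 300.0
    auc_integrand: str = "raw_ratio"
    responder_mode: str = "fixed"
    rise_fraction_low: float = 0.10
    rise_fraction_high: float = 0.90

    def __post_init__(self) -> None:
        positive = (
            "baseline_window_s", "responder_fold", "smooth_window_s",
            "spike_threshold", "spike_min_width_s", "class_auc_low",
            "class_auc_high", "class_isi_product",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.auc_integrand not in _AUC_INTEGRANDS:
            raise ValidationError(
                f"auc_integrand must be one of {_AUC_INTEGRANDS}")
        if self.responder_mode not in _RESPONDER_MODES:
            raise ValidationError(
                f"responder_mode must be one of {_RESPONDER_MODES}")
        if not (0 < self.rise_fraction_low < self.rise_fraction_high < 1):
            raise ValidationError(
                "require 0 < rise_fraction_low < rise_fraction_high < 1")
        if self.class_auc_low > self.class_auc_high:
            raise ValidationError("class_auc_low must be <= class_auc_high")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        """Build a config from a dict, rejecting unknown keys."""
        unknown = set(mapping) - set(cls.field_names())
        if unknown:
            raise ValidationError(
                f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**mapping)


def long_term_config(**overrides) -> AnalysisConfig:
    """Configuration for the 20-min classification workflow.

    Identical to the defaults except for two settings that the
    classification rules require to be internally consistent:

    * the AUC integrand is the baseline-subtracted ratio - over a
      20-minute recording the resting ratio of ~1 alone would integrate
      to ~1200 fold*s, so the single-spike class (AUC < 500) is only
      reachable once the baseline is subtracted;
    * the detrending window is 25 s (50 samples at the 2 Hz long-term
      frame rate).  A 6.25 s window cannot support the 0.4 / 5 s spike
      rule at all: the moving average re-converges onto the trace within
      half a window, so no bounded transient stays above threshold for
      5 s.  50 samples at 2 Hz resolves this; the 6.25 s default
      corresponds to 50 samples at the 8 Hz short-term frame rate.
    """
    overrides.setdefault("auc_integrand", "baseline_subtracted")
    overrides.setdefault("smooth_window_s", 25.0)
    return AnalysisConfig(**overrides)


# ---------------------------------------------------------------------------
# Trace containers
# ---------------------------------------------------------------------------

def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Trace:
    """A raw per-cell fluorescence time series with its stimulus time."""

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray
    stim_time: float
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if len(self.times) != len(self.intensities):
            raise ValidationError("times and intensities differ in length")
        if len(self.times) < 2:
            raise ValidationError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise TraceFormatError(
                f"times not strictly increasing for cell {self.cell_id!r}")
        if not np.all(np.isfinite(self.intensities)):
            raise DataError(f"non-finite intensity in cell {self.cell_id!r}")
        if not np.all(self.intensities > 0):
            raise DataError(f"non-positive intensity in cell {self.cell_id!r}")
        if not (self.times[0] <= self.stim_time < self.times[-1]):
            raise ValidationError(
                f"stim_time {self.stim_time} outside recording for cell "
                f"{self.cell_id!r}")
        dt = np.diff(self.times)
        if len(dt) > 1 and (dt.max() - dt.min()) > 0.01 * np.median(dt):
            logger.warning(
                "cell %s: sampling interval varies by more than 1%%",
                self.cell_id)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class NormalizedTrace:
    """An F/F0-normalized trace.

    ``ratio`` is intensity divided by ``f0``, the mean intensity over the
    baseline window; ``baseline_sd_ratio`` is the sample SD of the ratio
    over that same window (the pre-stimulus noise level in fold units).
    """

    cell_id: str
    times: np.ndarray
    ratio: np.ndarray
    f0: float
    baseline_sd_ratio: float
    stim_time: float
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.ratio = _as_float_array(self.ratio, "ratio")
        if self.f0 <= 0:
            raise DataError("f0 must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def pre_mask(self) -> np.ndarray:
        """Samples strictly before the stimulus."""
        return self.times < self.stim_time

    @property
    def post_mask(self) -> np.ndarray:
        """Samples at or after the stimulus."""
        return self.times >= self.stim_time

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.times)))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise TraceFormatError(f"{path} contains no data rows")
    return frame


def _numeric_column(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    series = pd.to_numeric(frame[column], errors="coerce")
    bad = series.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise TraceFormatError(
            f"{path}: missing or non-numeric value at row {row + 2}, "
            f"column {column!r}")
    return series.to_numpy(dtype=float)


def read_traces(path, layout: str = "wide", *, stim_time: float,
                well_id: str | None = None) -> list[Trace]:
    """Read per-cell traces from a CSV file.

    ``wide`` files have a ``time_s`` first column and one column per cell;
    ``long`` files have columns ``cell_id,time_s,intensity``.  Cell order
    follows column order (wide) or first appearance (long); long-format
    rows are sorted by time within each cell.
    """
    frame = _read_table(path)
    if layout == "wide":
        time_col = frame.columns[0]
        times = _numeric_column(frame, time_col, path)
        if not np.all(np.diff(times) > 0):
            raise TraceFormatError(
                f"{path}: time column not strictly increasing")
        if frame.shape[1] < 2:
            raise TraceFormatError(f"{path}: no cell columns present")
        return [
            Trace(cell_id=str(col), times=times,
                  intensities=_numeric_column(frame, col, path),
                  stim_time=stim_time, well_id=well_id)
            for col in frame.columns[1:]
        ]
    if layout == "long":
        required = {"cell_id", "time_s", "intensity"}
        missing = required - set(frame.columns)
        if missing:
            raise TraceFormatError(
                f"{path}: long layout missing columns {sorted(missing)}")
        times_all = _numeric_column(frame, "time_s", path)
        intens_all = _numeric_column(frame, "intensity", path)
        frame = frame.assign(time_s=times_all, intensity=intens_all)
        traces = []
        for cell_id in frame["cell_id"].drop_duplicates():
            sub = frame[frame["cell_id"] == cell_id].sort_values("time_s")
            if sub["time_s"].duplicated().any():
                raise TraceFormatError(
                    f"{path}: repeated time value for cell {cell_id!r}")
            traces.append(Trace(
                cell_id=str(cell_id),
                times=sub["time_s"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                stim_time=stim_time, well_id=well_id))
        return traces
    raise ValidationError(f"unknown layout {layout!r}")


def write_traces(traces: Sequence[Trace], path, layout: str = "wide") -> None:
    """Write traces to CSV in the ``wide`` or ``long`` layout."""
    if not traces:
        raise ValidationError("no traces to write")
    path = Path(path)
    if layout == "wide":
        base = traces[0].times
        for tr in traces:
            if len(tr) != len(base) or not np.array_equal(tr.times, base):
                raise ValidationError(
                    "wide layout requires a shared time base")
        frame = pd.DataFrame({"time_s": base})
        for tr in traces:
            frame[tr.cell_id] = tr.intensities
        frame.to_csv(path, index=False)
    elif layout == "long":
        parts = [
            pd.DataFrame({"cell_id": tr.cell_id, "time_s": tr.times,
                          "intensity": tr.intensities})
            for tr in traces
        ]
        pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Normalization and the pre-stimulus exclusion rule
# ---------------------------------------------------------------------------

def normalize(trace: Trace, config: AnalysisConfig | None = None
              ) -> NormalizedTrace:
    """Normalize a trace to F/F0.

    F0 is the arithmetic mean intensity over the baseline window
    ``[stim_time - baseline_window_s, stim_time)``; the ratio series is
    intensity / F0, so its mean over the baseline window is 1 by
    construction.
    """
    config = config or AnalysisConfig()
    lo = trace.stim_time - config.baseline_window_s
    mask = (trace.times >= lo) & (trace.times < trace.stim_time)
    if mask.sum() < 2:
        raise InsufficientBaselineError(
            f"cell {trace.cell_id!r}: {int(mask.sum())} baseline sample(s) "
            f"in [{lo}, {trace.stim_time}) - need at least 2")
    f0 = float(trace.intensities[mask].mean())
    if f0 <= 0:
        raise DataError(f"cell {trace.cell_id!r}: non-positive F0")
    ratio = trace.intensities / f0
    sd = float(np.std(ratio[mask], ddof=1))
    return NormalizedTrace(
        cell_id=trace.cell_id, times=trace.times.copy(), ratio=ratio,
        f0=f0, baseline_sd_ratio=sd, stim_time=trace.stim_time,
        well_id=trace.well_id)


def excluded_prestim(ntrace: NormalizedTrace,
                     config: AnalysisConfig | None = None) -> bool:
    """True when the cell was already active before agonist addition.

    Operationalized as any pre-stimulus ratio sample strictly exceeding
    the responder fold change: such cells cannot be attributed to the
    stimulus and are flagged (but retained in output files).
    """
    config = config or AnalysisConfig()
    pre = ntrace.ratio[ntrace.pre_mask]
    return bool(np.any(pre > config.responder_fold))


def write_normalized(ntraces: Sequence[NormalizedTrace], path) -> None:
    """Write normalized traces as long CSV plus a YAML sidecar of F0 values.

    The sidecar (``<path>.meta.yaml``) records f0, baseline SD and
    stimulus time per cell so the normalization is invertible.
    """
    if not ntraces:
        raise ValidationError("no traces to write")
    path = Path(path)
    parts = [
        pd.DataFrame({"cell_id": nt.cell_id, "time_s": nt.times,
                      "ratio": nt.ratio})
        for nt in ntraces
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    meta = {
        nt.cell_id: {
            "f0": float(nt.f0),
            "baseline_sd_ratio": float(nt.baseline_sd_ratio),
            "stim_time": float(nt.stim_time),
        }
        for nt in ntraces
    }
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
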