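"""Synthetic fluorescence traces and surrogate parameter populations.

No public dataset accompanies the analysis this package implements, so
every stage is exercised on generated data with known ground truth.  The
generator emulates fluo-4 F/F0 traces of cultured astrocytes sampled at
2 Hz over 20 min (long-term protocol) or 8 Hz over ~100 s (short-term
high-throughput protocol), containing the four response archetypes:

* **SS** - a single Ca2+ transient: fast rise, exponential decay;
* **BS** - a burst of several spikes of geometrically diminishing
  amplitude riding on an elevated level that decays over minutes;
* **RS** - repetitive constant-amplitude spikes at long intervals;
* **SU** - a rise to a sustained plateau held to the end of the
  recording, with an initial overshoot.

The transient kernel is phenomenological (linear rise, exponential
decay): only threshold crossings, widths and areas matter downstream,
and those have closed forms for this kernel.  Measurement noise is
multiplicative Gaussian on the intensity (photon-scaling heuristic) and
a small linear drift exercises the detrending stage.  Kinetic-parameter
populations are drawn from right-skewed distributions (lognormal by
default) matching the skew seen in large cell populations.  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_io import Trace, ValidationError

__all__ = [
    "ArchetypeParams",
    "PopulationSpec",
    "default_archetypes",
    "generate_trace",
    "generate_cohort",
    "generate_population",
    "generate_gaussian_surrogate",
]

#: default resting fluorescence, arbitrary units (analysis is scale-invariant)
BASELINE_INTENSITY = 100.0

#: rise time of the transient kernel, seconds
KERNEL_RISE_S = 2.0

#: geometric amplitude decay between successive spikes of a burst
BURST_AMP_RATIO = 0.85

_CLASS_LABELS = ("SS", "BS", "RS", "SU")


@dataclass(frozen=True)
class ArchetypeParams:
    """Shape parameters of one response archetype.

    ``amplitude`` is the baseline-subtracted peak of the (first) spike
    in fold units; ``spike_width_s`` the exponential decay time of each
    spike within a train; ``decay_tau_s`` the decay time of the single
    transient (SS), of the burst envelope (BS), or of the overshoot
    relaxation onto the plateau (SU); ``plateau_level`` the sustained
    baseline-subtracted level (BS envelope peak, SU plateau).
    """

    class_label: str
    amplitude: float
    onset_s: float = 5.0
    spike_width_s: float = 7.0
    decay_tau_s: float = 20.0
    n_spikes: int = 1
    isi_s: float = 0.0
    plateau_level: float = 0.0
    noise_sd: float = 0.02
    drift_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in _CLASS_LABELS:
            raise ValidationError(
                f"class_label must be one of {_CLASS_LABELS}")
        if not self.amplitude > 0:
            raise ValidationError("amplitude must be > 0")
        if self.n_spikes < 1:
            raise ValidationError("n_spikes must be >= 1")
        if self.n_spikes > 1 and not self.isi_s > self.spike_width_s:
            raise ValidationError(
                "isi_s must exceed spike_width_s for multi-spike classes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.onset_s < 0 or self.spike_width_s <= 0 or self.decay_tau_s <= 0:
            raise ValidationError("onset/width/decay must be positive")


def default_archetypes(noise_sd: float = 0.02,
                       drift_per_s: float = 5e-5
                       ) -> dict[str, ArchetypeParams]:
    """The four archetypes with parameters well clear of every
    classification boundary (baseline-subtracted AUC cutoffs 500/1000,
    ISI x count cutoff 300 s, spike threshold 0.4 / 5 s)."""
    common = dict(noise_sd=noise_sd, drift_per_s=drift_per_s)
    return {
        "SS": ArchetypeParams("SS", amplitude=2.0, onset_s=5.0,
                              decay_tau_s=20.0, **common),
        "BS": ArchetypeParams("BS", amplitude=2.5, onset_s=5.0,
                              n_spikes=4, isi_s=30.0, spike_width_s=10.0,
                              plateau_level=3.5, decay_tau_s=450.0,
                              **common),
        "RS": ArchetypeParams("RS", amplitude=2.5, onset_s=5.0,
                              n_spikes=8, isi_s=150.0, spike_width_s=9.0,
                              decay_tau_s=9.0, **common),
        "SU": ArchetypeParams("SU", amplitude=2.8, onset_s=5.0,
                              plateau_level=1.8, decay_tau_s=25.0,
                              **common),
    }


def _transient(t: np.ndarray, amp: float, tau: float,
               rise_s: float = KERNEL_RISE_S) -> np.ndarray:
    """Fast-rise / exponential-decay kernel starting at t = 0."""
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    out[rising] = amp * t[rising] / rise_s
    after = t >= rise_s
    out[after] = amp * np.exp(-(t[after] - rise_s) / tau)
    return out


def _plateau(t: np.ndarray, level: float, tau: float | None,
             rise_s: float = KERNEL_RISE_S) -> np.ndarray:
    """Rise to ``level`` then hold (tau=None) or decay with ``tau``."""
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    out[rising] = level * t[rising] / rise_s
    after = t >= rise_s
    if tau is None:
        out[after] = level
    else:
        out[after] = level * np.exp(-(t[after] - rise_s) / tau)
    return out


def _response(params: ArchetypeParams, t_post: np.ndarray) -> np.ndarray:
    """Noise-free baseline-subtracted response, t_post relative to onset."""
    label = params.class_label
    if label == "SS":
        return _transient(t_post, params.amplitude, params.decay_tau_s)
    if label == "BS":
        resp = _plateau(t_post, params.plateau_level, params.decay_tau_s)
        for k in range(params.n_spikes):
            amp = params.amplitude * BURST_AMP_RATIO ** k
            resp += _transient(t_post - k * params.isi_s, amp,
                               params.spike_width_s)
        return resp
    if label == "RS":
        resp = np.zeros_like(t_post)
        for k in range(params.n_spikes):
            resp += _transient(t_post - k * params.isi_s, params.amplitude,
                               params.spike_width_s)
        return resp
    # SU: overshoot to `amplitude`, relaxing onto the held plateau
    resp = _plateau(t_post, params.plateau_level, None)
    overshoot = params.amplitude - params.plateau_level
    if overshoot > 0:
        resp += _transient(t_post, overshoot, params.decay_tau_s)
    return resp


def generate_trace(params: ArchetypeParams, duration_s: float = 1200.0,
                   rate_hz: float = 2.0, stim_time: float = 30.0,
                   seed: int = 0, cell_id: str | None = None,
                   baseline: float = BASELINE_INTENSITY) -> Trace:
    """Generate one labelled fluorescence trace.

    Long-term defaults: 20 min at 2 Hz with the stimulus at 30 s.  The
    short-term protocol corresponds to ``duration_s~130, rate_hz=8``.
    Intensity = baseline x (1 + response) x (1 + drift x t) x
    (1 + Gaussian noise), deterministic for a fixed seed.
    """
    if duration_s <= stim_time + params.onset_s:
        raise ValidationError("duration must cover stimulus and response")
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    times = np.arange(0.0, duration_s, dt)
    t_post = times - stim_time - params.onset_s
    ratio = 1.0 + _response(params, t_post)
    drift = 1.0 + params.drift_per_s * times
    noise = 1.0 + rng.normal(0.0, params.noise_sd, size=times.size)
    intensities = baseline * ratio * drift * np.maximum(noise, 0.05)
    return Trace(cell_id=cell_id or f"{params.class_label}_{seed}",
                 times=times, intensities=intensities,
                 stim_time=stim_time)


def _jittered(params: ArchetypeParams, rng: np.random.Generator,
              cv: float) -> ArchetypeParams:
    """Multiply the continuous shape parameters by lognormal factors of
    coefficient of variation ``cv`` (spike counts stay fixed)."""
    def factor() -> float:
        return float(rng.lognormal(mean=0.0, sigma=cv))

    fields = dict(
        amplitude=params.amplitude * factor(),
        decay_tau_s=params.decay_tau_s * factor(),
        spike_width_s=params.spike_width_s * factor(),
    )
    if params.n_spikes > 1:
        fields["isi_s"] = params.isi_s * factor()
        # keep spikes resolvable: width must stay below the interval
        fields["spike_width_s"] = min(fields["spike_width_s"],
                                      0.6 * fields["isi_s"])
    if params.plateau_level > 0:
        fields["plateau_level"] = params.plateau_level * factor()
    return replace(params, **fields)


def generate_cohort(n_per_class: int = 50, seed: int = 0,
                    duration_s: float = 1200.0, rate_hz: float = 2.0,
                    stim_time: float = 30.0, noise_sd: float = 0.02,
                    jitter_cv: float = 0.10,
                    archetypes: dict[str, ArchetypeParams] | None = None
                    ) -> tuple[list[Trace], pd.DataFrame]:
    """Generate a labelled population of traces, ``n_per_class`` per
    archetype, with mild lognormal jitter on the shape parameters.

    Returns the traces and a ground-truth table (one row per cell:
    ``cell_id, class_label, amplitude, n_spikes, isi_s, plateau_level,
    decay_tau_s``).
    """
    archetypes = archetypes or default_archetypes(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    traces: list[Trace] = []
    rows = []
    for label, proto in archetypes.items():
        proto = replace(proto, noise_sd=noise_sd)
        for i in range(n_per_class):
            params = _jittered(proto, rng, jitter_cv)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell_id = f"{label}_{i:03d}"
            traces.append(generate_trace(
                params, duration_s=duration_s, rate_hz=rate_hz,
                stim_time=stim_time, seed=cell_seed, cell_id=cell_id))
            rows.append({
                "cell_id": cell_id,
                "class_label": label,
                "amplitude": params.amplitude,
                "n_spikes": params.n_spikes,
                "isi_s": params.isi_s,
                "plateau_level": params.plateau_level,
                "decay_tau_s": params.decay_tau_s,
            })
    return traces, pd.DataFrame(rows)


@dataclass(frozen=True)
class PopulationSpec:
    """A seeded draw of one kinetic parameter across a cell population.

    ``lognormal``: location/scale are the mean and SD of the underlying
    normal; ``gamma``: shape and scale; ``gaussian``: mean and SD.
    """

    distribution: str = "lognormal"
    location: float = 0.0
    scale: float = 0.5
    n_cells: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "gamma", "gaussian"):
            raise ValidationError(
                "distribution must be lognormal, gamma or gaussian")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")


def generate_population(spec: PopulationSpec) -> np.ndarray:
    """Draw ``n_cells`` parameter values from the named distribution."""
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "lognormal":
        return rng.lognormal(spec.location, spec.scale, spec.n_cells)
    if spec.distribution == "gamma":
        if spec.location <= 0:
            raise ValidationError("gamma shape (location) must be > 0")
        return rng.gamma(spec.location, spec.scale, spec.n_cells)
    return rng.normal(spec.location, spec.scale, spec.n_cells)


def generate_gaussian_surrogate(n: int, mean: float, sd: float,
                                seed: int = 0) -> np.ndarray:
    """A seeded Gaussian sample (the idealized surrogate populations used
    to calibrate the histogram difference metric)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    return np.random.default_rng(seed).normal(mean, sd, n)
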