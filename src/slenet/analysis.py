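"""Derived analyses: burst detection, activity classification, IBI scaling
fits, bifurcation sweeps, fast-slow replay assessment and the postictal
excitability measurement.

Burst definition (parameterised): spikes are grouped whenever consecutive
inter-spike intervals are below ``max_isi`` (200 ms); a group qualifies as
an ictal burst when it contains at least ``min_spikes`` (2) spikes and
lasts no longer than ``max_duration`` (2 s) — the duration cap separates
discrete ictal bursts from sustained tonic firing.  Inter-burst intervals
are measured onset to onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import constants as cn
from .engine import TraceSet, integrate
from .network import (PY_DENDRITES, PY_SOMATA, SOMATA, NetworkModel,
                      NetworkState, RunSpec)
from .protocols import (clamped_run_spec, clamped_state, linear_ramp_run,
                        run_probe_protocol, settled_state)

__all__ = [
    "BurstTrain", "IBIFit", "ActivityLabel",
    "detect_spikes", "detect_bursts", "fit_ibi", "classify_activity",
    "sle_phase_markers", "bifurcation_sweep", "linear_ramp_ibi",
    "excitability_probe",
]


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

@dataclass
class BurstTrain:
    """Ordered ictal bursts: onset/offset times (ms) and spike counts."""

    onsets: np.ndarray
    offsets: np.ndarray
    sizes: np.ndarray

    @property
    def ibi(self) -> np.ndarray:
        """Onset-to-onset inter-burst intervals, seconds."""
        return np.diff(self.onsets) / 1e3

    def __len__(self):
        return len(self.onsets)


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = -10.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings of a sampled voltage trace (ms).

    Amplitude-scale and DC-offset invariance is the caller's concern; the
    default threshold matches the simulator's spike detector.
    """
    v = np.asarray(v, float)
    up = np.where((v[1:] > threshold) & (v[:-1] <= threshold))[0] + 1
    if len(up) == 0:
        return np.empty(0)
    times = np.asarray(t, float)[up]
    keep = [times[0]]
    for x in times[1:]:
        if x - keep[-1] >= refractory:
            keep.append(x)
    return np.array(keep)


def detect_bursts(spike_times: np.ndarray, max_isi: float = 200.0,
                  min_spikes: int = 2, max_duration: float = 2000.0) -> BurstTrain:
    """Group spike times (ms) into ictal bursts; see module docstring."""
    sp = np.sort(np.asarray(spike_times, float))
    if sp.size == 0:
        return BurstTrain(np.empty(0), np.empty(0), np.empty(0, int))
    cuts = np.where(np.diff(sp) > max_isi)[0]
    groups = np.split(sp, cuts + 1)
    on, off, size = [], [], []
    for g in groups:
        if len(g) >= min_spikes and (g[-1] - g[0]) <= max_duration:
            on.append(g[0])
            off.append(g[-1])
            size.append(len(g))
    return BurstTrain(np.array(on), np.array(off), np.array(size, int))


# ---------------------------------------------------------------------------
# IBI scaling-law fits
# ---------------------------------------------------------------------------

@dataclass
class IBIFit:
    """One fitted IBI scaling law with parameters and goodness of fit."""

    model: str            # linear | exponential | logarithmic | inverse_sqrt
    params: dict
    rmse: float
    predictor: str        # "t" or "lambda"
    bic: float = np.nan   # Bayesian information criterion (Gaussian residuals)

    def predict(self, t: np.ndarray, t_end: float | None = None) -> np.ndarray:
        p = self.params
        if self.model == "linear":
            return p["A"] + p["B"] * t
        if self.model == "exponential":
            return p["A"] + p["B"] * np.exp(p["C"] * t)
        lam = (t_end if t_end is not None else p["t_end"]) - t + 1.0
        if self.model == "logarithmic":
            return p["A"] + p["B"] * np.log(lam)
        return p["A"] + p["B"] / np.sqrt(lam)


def _lsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a, b = np.polyfit(x, y, 1)[::-1]
    rmse = float(np.sqrt(np.mean((a + b * x - y) ** 2)))
    return a, b, rmse


def fit_ibi(train: BurstTrain, t_end: float | None = None) -> dict[str, IBIFit]:
    """Fit all four IBI scaling laws; keys are model names plus 'best'.

    IBIs are regressed on the time of the interval start (seconds, relative
    to the first burst).  The logarithmic and inverse-square-root laws use
    the distance to the end of the event, lambda = t_end - t + 1 (s), with
    t_end defaulting to the last burst onset plus its extrapolated IBI.
    The exponential law is fitted by Nelder-Mead on C (A, B profiled by
    linear least squares) from several deterministic starts.
    """
    if len(train) < 5:
        raise ValueError("need at least 4 inter-burst intervals to fit")
    t0 = train.onsets[0]
    t = (train.onsets[:-1] - t0) / 1e3
    y = train.ibi
    if t_end is None:
        t_end = (train.onsets[-1] - t0) / 1e3 + y[-1]
    fits: dict[str, IBIFit] = {}

    a, b, rmse = _lsq(t, y)
    fits["linear"] = IBIFit("linear", {"A": a, "B": b}, rmse, "t")

    lam = t_end - t + 1.0
    if np.any(lam <= 0):
        raise ValueError("t_end leaves non-positive distance-to-end values")
    a, b, rmse = _lsq(np.log(lam), y)
    fits["logarithmic"] = IBIFit(
        "logarithmic", {"A": a, "B": b, "t_end": t_end}, rmse, "lambda")
    a, b, rmse = _lsq(1.0 / np.sqrt(lam), y)
    fits["inverse_sqrt"] = IBIFit(
        "inverse_sqrt", {"A": a, "B": b, "t_end": t_end}, rmse, "lambda")

    def exp_rmse(c):
        x = np.exp(np.clip(c * t, -500, 500))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ill-conditioned far from optimum
                a_, b_ = np.polyfit(x, y, 1)[::-1]
        except np.linalg.LinAlgError:
            return np.inf, 0.0, 0.0
        r = float(np.sqrt(np.mean((a_ + b_ * x - y) ** 2)))
        return r, a_, b_

    best = None
    for c0 in (0.01, 0.05, 0.1, 0.5):
        res = minimize(lambda c: exp_rmse(c[0])[0], [c0],
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12})
        r, a_, b_ = exp_rmse(res.x[0])
        if best is None or r < best[0]:
            best = (r, a_, b_, res.x[0])
    fits["exponential"] = IBIFit(
        "exponential", {"A": best[1], "B": best[2], "C": best[3]},
        best[0], "t")

    n = y.size
    for name, k in (("linear", 2), ("exponential", 3),
                    ("logarithmic", 2), ("inverse_sqrt", 2)):
        f = fits[name]
        rss = max(n * f.rmse ** 2, 1e-300)
        f.bic = n * np.log(rss / n) + k * np.log(n)

    models = ("linear", "exponential", "logarithmic", "inverse_sqrt")
    # raw-RMSE winner: the published goodness-of-fit contest
    fits["best"] = min((fits[k] for k in models), key=lambda f: f.rmse)
    # parsimony-corrected winner: the three-parameter exponential nests the
    # linear law and shadows the two-parameter laws on any smoothly
    # accelerating sequence, so law *recovery* is judged by BIC
    fits["best_bic"] = min((fits[k] for k in models), key=lambda f: f.bic)
    return fits


# ---------------------------------------------------------------------------
# activity classification
# ---------------------------------------------------------------------------

@dataclass
class ActivityLabel:
    """One of rest / tonic / bursting, with the diagnostics that decided it."""

    label: str
    n_spikes: int
    n_bursts: int
    max_gap: float   # ms, largest inter-spike gap in the window


def classify_activity(spike_times: np.ndarray, window: tuple[float, float],
                      min_quiescence: float = 300.0,
                      burst_kwargs: dict | None = None) -> ActivityLabel:
    """Deterministic activity label from spikes inside ``window`` (ms).

    rest: no spikes.  bursting: at least two detected bursts separated by
    quiescent gaps longer than ``min_quiescence``.  tonic: anything else.
    """
    sp = np.sort(np.asarray(spike_times, float))
    sp = sp[(sp >= window[0]) & (sp < window[1])]
    if sp.size == 0:
        return ActivityLabel("rest", 0, 0, 0.0)
    train = detect_bursts(sp, **(burst_kwargs or {}))
    max_gap = float(np.max(np.diff(sp))) if sp.size > 1 else 0.0
    if len(train) >= 2 and np.any(train.onsets[1:] - train.offsets[:-1]
                                  > min_quiescence):
        return ActivityLabel("bursting", sp.size, len(train), max_gap)
    return ActivityLabel("tonic", sp.size, len(train), max_gap)


# ---------------------------------------------------------------------------
# reference-SLE phase markers
# ---------------------------------------------------------------------------

@dataclass
class PhaseMarkers:
    """Detected phase boundaries of a seizure-like event (ms)."""

    sle_onset: float          # stimulation / LVF onset
    tonic_onset: float | None
    bursting_onset: float | None
    termination: float | None


def sle_phase_markers(traces: TraceSet, sle_onset: float = 60e3,
                      rate_threshold: float = 2.0,
                      sustain: float = 3e3) -> PhaseMarkers:
    """Automated phase markers from the pooled pyramidal spike trains.

    Tonic onset: first time the pooled PY somatic rate (1 s bins) stays at
    or above ``rate_threshold`` Hz per cell for ``sustain`` ms.  Bursting
    onset: first detected ictal burst after tonic onset.  Termination:
    offset of the last ictal burst.
    """
    sp = traces.spikes(PY_SOMATA)
    sp = sp[sp >= sle_onset]
    tonic = None
    if sp.size:
        bins = np.arange(sle_onset, traces.duration + 1e3, 1e3)
        rate = np.histogram(sp, bins)[0] / len(PY_SOMATA)
        need = max(int(sustain / 1e3), 1)
        run = 0
        for i, r in enumerate(rate):
            run = run + 1 if r >= rate_threshold else 0
            if run >= need:
                tonic = bins[i - need + 1]
                break
    burst_on = termination = None
    train = detect_bursts(traces.spike_times[PY_SOMATA[1]])
    sel = train.onsets >= (tonic if tonic is not None else sle_onset)
    if np.any(sel):
        burst_on = float(train.onsets[sel][0])
        termination = float(train.offsets[sel][-1])
    return PhaseMarkers(sle_onset, tonic, burst_on, termination)


# ---------------------------------------------------------------------------
# clamped-ion bifurcation sweep
# ---------------------------------------------------------------------------

def bifurcation_sweep(model: NetworkModel,
                      k_dend_values=(3.5, 4.75, 6.0),
                      k_soma_range=(3.0, 12.0), k_soma_step: float = 0.5,
                      na_levels=((10.0, 10.0), (11.0, 10.5), (12.0, 11.0)),
                      step_duration: float = 5e3,
                      directions=("forward", "backward"),
                      carry_state: bool = True,
                      state: NetworkState | None = None,
                      monitor: int = PY_SOMATA[1]):
    """Activity map over the clamped (K+_o,dend, K+_o,soma) grid.

    With ``carry_state`` (the hysteresis protocol) the somatic K+ is
    stepped across ``k_soma_range`` in both directions with the state
    carried between steps.  With ``carry_state=False`` every grid point is
    simulated independently from the settled rest state, which resolves
    the quasi-stationary regime of each point without the accommodation
    transients that dominate short carried steps (see docs/methods.md).
    The final 3 s of each step are classified.  Returns a list of records.
    """
    base = state if state is not None else settled_state(model)
    k_vals = np.arange(k_soma_range[0], k_soma_range[1] + 1e-9, k_soma_step)
    records = []
    for na_s, na_d in na_levels:
        for kd in k_dend_values:
            for direction in directions:
                seq = k_vals if direction == "forward" else k_vals[::-1]
                st = clamped_state(model, base, k_soma=seq[0], k_dend=kd,
                                   cl_py=7.0, na_soma=na_s, na_dend=na_d)
                for ks in seq:
                    if not carry_state:
                        st = clamped_state(model, base, k_soma=ks, k_dend=kd,
                                           cl_py=7.0, na_soma=na_s,
                                           na_dend=na_d)
                    else:
                        st.co[SOMATA, cn.K] = ks
                    spec = clamped_run_spec(step_duration)
                    tr, st = integrate(model, spec, state=st)
                    lab = classify_activity(
                        tr.spike_times[monitor],
                        (step_duration - 3e3, step_duration))
                    records.append({
                        "na_soma": na_s, "na_dend": na_d, "k_dend": kd,
                        "k_soma": float(ks), "direction": direction,
                        "label": lab.label, "n_spikes": lab.n_spikes,
                        "n_bursts": lab.n_bursts})
                if not carry_state:
                    break  # directions are identical without carried state
    return records


def sweep_to_frame(records):
    import pandas as pd
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# linear-ramp IBI experiments and the excitability probe
# ---------------------------------------------------------------------------

def linear_ramp_ibi(model: NetworkModel, species: str,
                    state: NetworkState | None = None,
                    monitor: int = PY_SOMATA[1],
                    **kwargs) -> tuple[BurstTrain, dict[str, IBIFit]]:
    """Ramp one clamped species linearly and fit the IBI scaling laws."""
    traces = linear_ramp_run(model, species, state=state, **kwargs)
    train = detect_bursts(traces.spike_times[monitor])
    if len(train) < 5:
        raise RuntimeError(
            f"linear ramp {species!r}: only {len(train)} bursts detected")
    return train, fit_ibi(train)


@dataclass
class ProbeResult:
    """Per-probe responses and the derived postictal unresponsive span."""

    probe_times: np.ndarray      # ms
    responded: np.ndarray        # bool per probe
    latencies: np.ndarray        # ms (nan where no response)
    probe_weight: float          # uS
    sle_offset: float | None     # ms
    unresponsive_span: float     # s

    traces: TraceSet | None = field(default=None, repr=False)


def excitability_probe(model: NetworkModel, duration: float = 300e3,
                       probe_weight: float | None = None,
                       response_window: float = 50.0,
                       state: NetworkState | None = None) -> ProbeResult:
    """Postictal excitability via the calibrated 5 s periodic probe.

    The unresponsive span is the longest contiguous run of failed probes
    after the SLE offset, reported in seconds (run length times the probe
    period).
    """
    traces, w = run_probe_protocol(model, duration=duration,
                                   probe_weight=probe_weight, state=state)
    period = traces.meta["probe_period_ms"]
    start = traces.meta["probe_start_ms"]
    probe_times = np.arange(start, traces.duration, period)
    sp = traces.spikes(PY_SOMATA)
    responded = np.zeros(probe_times.size, bool)
    lat = np.full(probe_times.size, np.nan)
    for i, pt in enumerate(probe_times):
        hit = sp[(sp >= pt) & (sp < pt + response_window)]
        if hit.size:
            responded[i] = True
            lat[i] = hit[0] - pt
    train = detect_bursts(traces.spike_times[PY_SOMATA[1]])
    ramp_on = traces.meta["ramp_onset_ms"]
    sel = train.onsets > ramp_on
    offset = float(train.offsets[sel][-1]) if np.any(sel) else None
    span = 0.0
    if offset is not None:
        post = responded[probe_times > offset]
        run = best = 0
        for r in post:
            run = run + 1 if not r else 0
            best = max(best, run)
        span = best * period / 1e3
    return ProbeResult(probe_times, responded, lat, w, offset, span, traces)
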