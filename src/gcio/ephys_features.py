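"""Intrinsic biophysical parameters and spike detection.

Spike criterion: an action potential is a deflection of the first derivative
of the voltage trace exceeding 20 mV/ms after zero-phase 4 kHz low-pass
filtering; threshold is the voltage at the 20 mV/ms crossing, while the peak
rate of rise is taken from the unfiltered derivative.

Passive parameters come from -10 pA step responses (input resistance from the
mean steady-state deflection, membrane time constant from single-exponential
fits 2-100 ms after step onset and offset), whole-cell capacitance from the
charge of a -5 mV voltage-clamp step, and excitability measures from an
incrementing square-pulse family run until depolarization block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from gcio.trace_io import CellRecord, Sweep

#: spike criterion on the filtered derivative (mV/ms)
SPIKE_DVDT_THRESHOLD = 20.0
#: post hoc low-pass corner for spike detection (kHz)
SPIKE_FILTER_KHZ = 4.0
#: minimum separation between detected events (ms); the source protocol
#: leaves this unspecified
REFRACTORY_GUARD_MS = 1.0
#: session-level exclusion: RMP drift beyond this is a failed recording (mV)
RMP_DRIFT_LIMIT_MV = 4.0
#: semilunar granule cells have input resistance below this (MOhm)
SEMILUNAR_RIN_MOHM = 90.0
#: sweeps whose baseline/response deviates > this many robust SDs of the
#: pooled baseline carry "large spontaneous events" and are excluded
SPONTANEOUS_EVENT_SIGMA = 5.0
#: fraction of the step used as the steady-state window
STEADY_STATE_FRACTION = 0.2


class FeatureError(RuntimeError):
    """Raised when a feature cannot be computed from the provided sweeps."""


@dataclass
class SpikeEvent:
    time_ms: float
    threshold_v: float  # mV, voltage at the 20 mV/ms crossing
    peak_dvdt: float  # mV/ms, unfiltered derivative maximum


@dataclass
class PassiveFeatures:
    r_in: float  # MOhm
    tau_m: float  # ms
    c_m: float  # pF
    rmp: float  # mV

    def __post_init__(self) -> None:
        if not (self.r_in > 0 and self.tau_m > 0 and self.c_m >= 0):
            raise ValueError("passive features must be positive")


@dataclass
class ExcitabilityFeatures:
    ap_threshold: float  # mV
    peak_dvdt: float  # mV/ms
    max_rate: float  # Hz (spikes per 1 s sweep before depolarization block)
    counts: list[int] = field(default_factory=list)
    block_index: Optional[int] = None


@dataclass
class QCResult:
    rmp_drift: float  # mV
    passed: bool
    excluded_as_semilunar: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# spike detection


def _lowpass(v: np.ndarray, sample_rate_khz: float, corner_khz: float) -> np.ndarray:
    sos = signal.butter(4, corner_khz / (sample_rate_khz / 2.0), output="sos")
    return signal.sosfiltfilt(sos, v)


def detect_spikes(
    sweep: Sweep,
    threshold_dvdt: float = SPIKE_DVDT_THRESHOLD,
    refractory_ms: float = REFRACTORY_GUARD_MS,
) -> list[SpikeEvent]:
    """Detect action potentials on a current-clamp sweep.

    Events are upward crossings of ``threshold_dvdt`` in the derivative of the
    4 kHz low-pass-filtered trace, deduplicated so that two events are at
    least ``refractory_ms`` apart.
    """
    if sweep.clamp_mode != "current_clamp":
        raise FeatureError("spike detection needs a current-clamp sweep")
    sr = sweep.sample_rate
    if sr < 10.0:
        raise FeatureError(
            f"sample rate {sr} kHz too low to resolve the 4 kHz filter (need >= 10)"
        )
    vf = _lowpass(sweep.voltage, sr, SPIKE_FILTER_KHZ)
    dvdt_f = np.gradient(vf) * sr  # mV/ms
    dvdt_raw = np.gradient(sweep.voltage) * sr

    above = dvdt_f >= threshold_dvdt
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    guard = int(round(refractory_ms * sr))
    events: list[SpikeEvent] = []
    last = -guard - 1
    kept: list[int] = []
    for idx in crossings:
        if idx - last <= guard:
            continue
        kept.append(int(idx))
        last = idx
    for j, idx in enumerate(kept):
        end = kept[j + 1] if j + 1 < len(kept) else sweep.n_samples
        window_end = min(idx + int(round(3.0 * sr)), end)
        peak = float(np.max(dvdt_raw[idx:window_end])) if window_end > idx else float(
            dvdt_raw[idx]
        )
        events.append(
            SpikeEvent(
                time_ms=idx / sr,
                threshold_v=float(vf[idx]),
                peak_dvdt=peak,
            )
        )
    return events


# ---------------------------------------------------------------------------
# step-window helpers


def _step_window(sweep: Sweep) -> tuple[int, int, float]:
    """Locate the command step on the stimulus channel.

    Returns (onset index, offset index, step amplitude) where amplitude is in
    the stimulus channel's units relative to the pre-step holding level.
    """
    stim = sweep.current if sweep.clamp_mode == "current_clamp" else sweep.voltage
    base = float(np.mean(stim[sweep.baseline_slice()]))
    dev = stim - base
    amp = dev[np.argmax(np.abs(dev))]
    if abs(amp) < 1e-9:
        raise FeatureError(f"sweep {sweep.sweep_id!r}: no step on stimulus channel")
    inside = np.abs(dev) > abs(amp) / 2.0
    idx = np.nonzero(inside)[0]
    onset, offset = int(idx[0]), int(idx[-1]) + 1
    amp = float(np.mean(dev[onset:offset]))
    return onset, offset, amp


def _steady_state_slice(onset: int, offset: int) -> slice:
    n = offset - onset
    return slice(offset - max(1, int(round(n * STEADY_STATE_FRACTION))), offset)


def _accept_step_sweeps(
    sweeps: Sequence[Sweep], sigma: float = SPONTANEOUS_EVENT_SIGMA
) -> list[bool]:
    """Flag sweeps with large spontaneous events.

    A sweep is rejected when its baseline or steady-state response window
    strays more than ``sigma`` robust SDs (of the pooled baseline residuals)
    from that window's own mean.
    """
    residuals = []
    for s in sweeps:
        b = s.voltage[s.baseline_slice()]
        residuals.append(b - np.mean(b))
    pooled = np.concatenate(residuals)
    mad = np.median(np.abs(pooled - np.median(pooled)))
    # floor at a 0.02 mV instrumentation noise so noise-free fixtures are
    # not excluded for numerically tiny wiggles
    robust_sd = max(1.4826 * mad, 0.02)
    accepted = []
    for s in sweeps:
        onset, offset, _ = _step_window(s)
        ok = True
        for window in (s.voltage[s.baseline_slice()], s.voltage[_steady_state_slice(onset, offset)]):
            if np.max(np.abs(window - np.mean(window))) > sigma * robust_sd:
                ok = False
                break
        accepted.append(ok)
    return accepted


# ---------------------------------------------------------------------------
# passive parameters


def measure_input_resistance(
    sweeps: Sequence[Sweep], sigma: float = SPONTANEOUS_EVENT_SIGMA
) -> float:
    """Input resistance (MOhm) from the mean steady-state response to
    -10 pA steps, excluding sweeps with large spontaneous events."""
    if not sweeps:
        raise FeatureError("no hyperpolarizing step sweeps")
    accepted = _accept_step_sweeps(sweeps, sigma)
    used = [s for s, ok in zip(sweeps, accepted) if ok]
    if not used:
        raise FeatureError("all step sweeps excluded for spontaneous events")
    deltas, amps = [], []
    for s in used:
        onset, offset, amp = _step_window(s)
        base = float(np.mean(s.voltage[s.baseline_slice()]))
        ss = float(np.mean(s.voltage[_steady_state_slice(onset, offset)]))
        deltas.append(ss - base)
        amps.append(amp)
    # mV / pA = GOhm -> x1000 for MOhm
    r = float(np.mean(deltas)) / float(np.mean(amps)) * 1000.0
    if r <= 0:
        raise FeatureError(f"non-physical input resistance {r:.1f} MOhm")
    return r


def _fit_exponential(t_ms: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Least-squares single-exponential fit; returns (tau_ms, relative RMS)."""
    v0, v1 = float(v[0]), float(np.mean(v[-max(3, v.size // 10):]))
    amp0 = v0 - v1
    if abs(amp0) < 1e-12:
        raise FeatureError("flat segment, cannot fit exponential")

    def model(t, amp, tau, c):
        return amp * np.exp(-(t - t_ms[0]) / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            t_ms,
            v,
            p0=[amp0, (t_ms[-1] - t_ms[0]) / 3.0, v1],
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FeatureError(f"exponential fit failed: {exc}") from exc
    resid = v - model(t_ms, *popt)
    rel_rms = float(np.sqrt(np.mean(resid**2)) / abs(amp0))
    return float(popt[1]), rel_rms


#: relative fit residual above which the single-exponential compromise is
#: flagged (multi-exponential decay)
TAU_FIT_WARN_REL_RMS = 0.02


def measure_time_constant(sweeps: Sequence[Sweep]) -> float:
    """Membrane time constant (ms): single-exponential fits on the averaged
    -10 pA step response, 2-100 ms after onset and after offset, averaged."""
    if not sweeps:
        raise FeatureError("no step sweeps")
    sr = sweeps[0].sample_rate
    v_mean = np.mean([s.voltage for s in sweeps], axis=0)
    onset, offset, _ = _step_window(sweeps[0])

    taus = []
    worst_rel = 0.0
    for edge in (onset, offset):
        lo = edge + int(round(2.0 * sr))
        hi = edge + int(round(100.0 * sr))
        hi = min(hi, v_mean.size)
        if hi - lo < 10:
            raise FeatureError("segment too short for the 2-100 ms fit window")
        t = np.arange(lo, hi) / sr
        tau, rel = _fit_exponential(t, v_mean[lo:hi])
        taus.append(tau)
        worst_rel = max(worst_rel, rel)
    if worst_rel > TAU_FIT_WARN_REL_RMS:
        warnings.warn(
            f"single-exponential compromise: relative fit residual "
            f"{worst_rel:.3f} suggests a multi-exponential decay",
            stacklevel=2,
        )
    return float(np.mean(taus))


def measure_rmp(sweeps: Sequence[Sweep]) -> float:
    """Resting membrane potential (mV): mean pre-stimulus baseline across sweeps."""
    if not sweeps:
        raise FeatureError("no sweeps for RMP")
    return float(np.mean([np.mean(s.voltage[s.baseline_slice()]) for s in sweeps]))


def measure_capacitance(sweep: Sweep) -> float:
    """Whole-cell capacitance (pF) from a -5 mV voltage-clamp step.

    The capacitive charge is the integral of the current transient measured
    from the steady-state level, divided by the step amplitude; integration
    runs from step onset until the current settles to within twice the
    baseline noise SD of steady state.
    """
    if sweep.clamp_mode != "voltage_clamp":
        raise FeatureError("capacitance needs a voltage-clamp step sweep")
    onset, offset, dv = _step_window(sweep)  # dv in mV
    i = sweep.current
    i_ss = float(np.mean(i[_steady_state_slice(onset, offset)]))
    base = i[sweep.baseline_slice()]
    noise_sd = float(np.std(base - np.mean(base)))
    resid = np.abs(i[onset:offset] - i_ss)
    settle_level = max(2.0 * noise_sd, 1e-12)
    if resid.max() <= settle_level:
        warnings.warn("no capacitive transient detected; returning 0 pF", stacklevel=2)
        return 0.0
    below = resid < settle_level
    # first index after which the current stays settled
    settled = offset - onset
    for k in range(below.size):
        if below[k:].all():
            settled = k
            break
    dt_ms = 1.0 / sweep.sample_rate
    q_fc = float(np.sum(i[onset : onset + settled] - i_ss) * dt_ms)  # pA*ms = fC
    return abs(q_fc) / abs(dv)  # fC/mV = pF


# ---------------------------------------------------------------------------
# excitability

#: a sweep whose count drops below this fraction of the running maximum
#: (while drive increased) marks depolarization block
BLOCK_FRACTION = 0.5


def measure_excitability(square_sweeps: Sequence[Sweep]) -> ExcitabilityFeatures:
    """Spike threshold, peak dV/dt and maximal firing rate from the
    incrementing square-pulse family.

    Threshold and peak dV/dt come from the first spike at the lowest spiking
    amplitude; the maximal rate is the largest spike count of any 1 s sweep
    before depolarization block.
    """
    if not square_sweeps:
        raise FeatureError("no square-family sweeps")
    ordered = sorted(square_sweeps, key=lambda s: s.protocol.amplitude)
    counts: list[int] = []
    first_events: Optional[list[SpikeEvent]] = None
    for s in ordered:
        ev = detect_spikes(s)
        counts.append(len(ev))
        if first_events is None and ev:
            first_events = ev
    if first_events is None:
        raise FeatureError("no spiking sweep in the square family")
    block_index: Optional[int] = None
    running_max = 0
    max_rate = 0
    for k, n in enumerate(counts):
        if running_max > 0 and n < BLOCK_FRACTION * running_max:
            block_index = k
            break
        running_max = max(running_max, n)
        max_rate = running_max
    first = first_events[0]
    return ExcitabilityFeatures(
        ap_threshold=first.threshold_v,
        peak_dvdt=first.peak_dvdt,
        max_rate=float(max_rate),
        counts=counts,
        block_index=block_index,
    )


# ---------------------------------------------------------------------------
# quality control


def qc_cell(record: CellRecord, passive: PassiveFeatures) -> QCResult:
    """Session-level exclusions: RMP drift > 4 mV, or semilunar identity
    (input resistance < 90 MOhm)."""
    baselines = [
        float(np.mean(s.voltage[s.baseline_slice()]))
        for s in record.sweeps
        if s.clamp_mode == "current_clamp"
    ]
    if not baselines:
        raise FeatureError(f"cell {record.cell_id!r}: no current-clamp sweeps for QC")
    drift = float(np.max(np.abs(np.asarray(baselines) - baselines[0])))
    reasons = []
    if drift > RMP_DRIFT_LIMIT_MV:
        reasons.append(
            f"RMP drifted {drift:.2f} mV from the initial value "
            f"(limit {RMP_DRIFT_LIMIT_MV} mV)"
        )
    semilunar = passive.r_in < SEMILUNAR_RIN_MOHM
    if semilunar:
        reasons.append(
            f"input resistance {passive.r_in:.0f} MOhm < {SEMILUNAR_RIN_MOHM:.0f} "
            f"MOhm: semilunar granule cell"
        )
    passed = drift <= RMP_DRIFT_LIMIT_MV and not semilunar
    return QCResult(
        rmp_drift=drift,
        passed=passed,
        excluded_as_semilunar=semilunar,
        reasons=reasons,
    )


def extract_passive(record: CellRecord) -> PassiveFeatures:
    """Convenience: all four passive parameters from one record."""
    steps = record.sweeps_of_kind("hyperpol_step")
    vc = record.sweeps_of_kind("vc_step")
    r_in = measure_input_resistance(steps)
    tau = measure_time_constant(steps)
    rmp = measure_rmp(steps)
    c_m = measure_capacitance(vc[0]) if vc else tau / r_in * 1000.0
    return PassiveFeatures(r_in=r_in, tau_m=tau, c_m=c_m, rmp=rmp)
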