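"""Ground-truthed synthetic neuron cohorts.

Two tiers:

* tier "curves" -- input-output spike counts generated directly per cell and
  frequency, fast enough for repeated statistical testing.  Sensitive (S)
  cells concentrate most of their dynamic range in one dominant increment
  (high increment variance); Linear (L) cells grow by a near-constant
  increment per 50 pA step.
* tier "traces" -- exponential integrate-and-fire (EIF) sweeps under the
  recording protocols (-10 pA steps, incrementing square family, sinusoid
  families, -5 mV voltage-clamp step), integrated with Euler-Maruyama at
  0.02 ms.

Cohorts carry a latent S/L group whose probability shifts with postmitotic
age (all S at 21 days, all L by 70 days) while the seven intrinsic
parameters drift with age *independently of group*, so intrinsic parameters
cannot predict group identity.  The offset of the input-output curve is tied
to input resistance in both groups; the slope depends on input resistance in
the L group only.

Default pooled generating centers: slope 2.409 (S) / 1.627 (L), increment
variance 1.536 (S) / 0.659 (L).  Passive drift magnitudes are plausible
granule-cell values chosen for fixtures, not measured facts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from gcio.io_features import IOCurve
from gcio.trace_io import (
    SINE_FREQUENCIES_HZ,
    SINE_GRID_PA,
    CellRecord,
    ProtocolDescriptor,
    Sweep,
    sine_amplitude_grid,
)

#: pooled generating centers (slope, increment variance) per group
DEFAULT_CENTERS = {
    "S": {"asl": 2.409, "var": 1.536},
    "L": {"asl": 1.627, "var": 0.659},
}
DEFAULT_ASL_SD = 0.15
DEFAULT_VAR_SD = 0.15

EULER_DT_MS = 0.02


class CohortSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# EIF simulator (tier "traces")


@dataclass
class EIFParams:
    """Exponential integrate-and-fire parameters; delta_t = 0 is the LIF limit."""

    c_m: float  # pF
    g_l: float  # nS
    e_l: float  # mV
    v_t: float  # mV
    delta_t: float  # mV
    v_reset: float  # mV
    v_peak: float = 0.0  # mV
    refractory_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.c_m > 0 and self.g_l > 0):
            raise ValueError("c_m and g_l must be positive")
        if not self.v_reset < self.v_t < self.v_peak:
            raise ValueError("require v_reset < v_t < v_peak")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    @property
    def tau_ms(self) -> float:
        return self.c_m / self.g_l  # pF/nS = ms

    @property
    def r_mohm(self) -> float:
        return 1000.0 / self.g_l  # 1/nS = GOhm -> MOhm


def _protocol_current(
    protocol: ProtocolDescriptor, dt_ms: float, pre_ms: float, post_ms: float
) -> tuple[np.ndarray, float]:
    """Command current array (pA) and stimulus onset time (ms)."""
    n_pre = int(round(pre_ms / dt_ms))
    n_stim = int(round(protocol.duration_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    i = np.full(n_pre + n_stim + n_post, protocol.holding, dtype=np.float64)
    stim = slice(n_pre, n_pre + n_stim)
    if protocol.kind in ("hyperpol_step", "square_family", "monitor_step"):
        i[stim] += protocol.amplitude
    elif protocol.kind == "sine_family":
        t = np.arange(n_stim) * dt_ms / 1000.0  # s
        i[stim] += protocol.amplitude * np.sin(2.0 * math.pi * protocol.frequency * t)
    else:
        raise ValueError(f"cannot build a current command for {protocol.kind!r}")
    return i, pre_ms


#: stylized spike shape rendered into the voltage trace so that downstream
#: derivative-based detection sees a realistic upstroke; raised-cosine
#: segments start and end with zero slope, and the fall lands exactly on the
#: membrane state's recovery value, so the trace has no corners that would
#: ring through the 4 kHz detection filter
_SPIKE_RISE_MS = 0.3
_SPIKE_FALL_MS = 1.2


def _render_spike(v_start: float, v_peak: float, v_end: float, m: int) -> np.ndarray:
    """Raised-cosine AP waveform over ``m`` samples: up then down to v_end."""
    frac = _SPIKE_RISE_MS / (_SPIKE_RISE_MS + _SPIKE_FALL_MS)
    n_up = max(1, int(round(m * frac)))
    n_down = m - n_up
    up = v_start + (v_peak - v_start) * 0.5 * (
        1.0 - np.cos(np.pi * (np.arange(n_up) + 1) / n_up)
    )
    if n_down <= 0:
        return up
    down = v_end + (v_peak - v_end) * 0.5 * (
        1.0 + np.cos(np.pi * (np.arange(n_down) + 1) / n_down)
    )
    return np.concatenate([up, down])


def simulate_eif_sweep(
    params: EIFParams,
    protocol: ProtocolDescriptor,
    seed: Optional[int] = None,
    dt_ms: float = EULER_DT_MS,
    noise_sd_pa: float = 0.0,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    sweep_id: str = "sweep",
) -> Sweep:
    """Forward-integrate C dV/dt = -g_l (V - e_l) + g_l dT exp((V-v_t)/dT) + I.

    A spike is emitted when V reaches ``v_peak`` (``v_t`` in the LIF limit
    delta_t = 0); the trace then follows a stylized 1 ms action-potential
    waveform down to ``v_reset``, followed by the refractory hold.  Ground-
    truth spike times (ms) are attached under ``extra["true_spike_times_ms"]``.
    """
    if protocol.kind == "vc_step":
        return _simulate_vc_step(params, protocol, seed, dt_ms, pre_ms, post_ms, sweep_id)
    if dt_ms > 0.02 + 1e-12:
        raise ValueError("integration step must be <= 0.02 ms")
    current, _ = _protocol_current(protocol, dt_ms, pre_ms, post_ms)
    n = current.size
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd_pa, size=n) if noise_sd_pa > 0 else np.zeros(n)
    )
    c, gl, el, vt, dT = params.c_m, params.g_l, params.e_l, params.v_t, params.delta_t
    fire_at = vt if dT == 0.0 else params.v_peak
    n_refr = int(round(params.refractory_ms / dt_ms))
    # pass 1: hidden membrane state with instant reset, so firing rates match
    # the closed forms exactly
    s = np.empty(n, dtype=np.float64)
    s[0] = params.e_l
    spike_idx: list[int] = []
    refr_until = -1
    for k in range(n - 1):
        if k < refr_until:
            s[k + 1] = params.v_reset
            continue
        dvdt = -gl * (s[k] - el) + (current[k] + noise[k])
        if dT > 0.0:
            # clamped exponential; divergence past v_peak is a spike
            dvdt += gl * dT * math.exp(min((s[k] - vt) / dT, 30.0))
        v_next = s[k] + dt_ms * dvdt / c  # pA/pF = mV/ms
        if not math.isfinite(v_next):
            raise FloatingPointError(
                "numerical blow-up without spike detection (step too large)"
            )
        if v_next >= fire_at:
            spike_idx.append(k + 1)
            refr_until = k + 1 + n_refr
            v_next = params.v_reset
        s[k + 1] = v_next
    # pass 2: render the stylized AP over the state trace
    v = s.copy()
    n_wf = int(round((_SPIKE_RISE_MS + _SPIKE_FALL_MS) / dt_ms))
    for j_pos, j in enumerate(spike_idx):
        end = min(j + n_wf, n)
        if j_pos + 1 < len(spike_idx):
            end = min(end, spike_idx[j_pos + 1])
        m = end - j
        if m <= 0:
            continue
        v_start = min(s[j - 1], params.v_peak - 1.0) if j > 0 else fire_at
        v_end = s[end] if end < n else params.v_reset
        v[j:end] = _render_spike(v_start, params.v_peak, v_end, m)
    spike_times = [j * dt_ms for j in spike_idx]
    return Sweep(
        sweep_id=sweep_id,
        clamp_mode="current_clamp",
        sample_rate=1.0 / dt_ms,  # kHz
        voltage=v,
        current=current,
        protocol=protocol,
        t0_baseline_window=(0.0, pre_ms * 0.9),
        extra={"true_spike_times_ms": [round(t, 6) for t in spike_times]},
    )


#: effective clamp time constant of the synthetic voltage-clamp transient (ms)
_VC_TAU_MS = 0.2


def _simulate_vc_step(
    params: EIFParams,
    protocol: ProtocolDescriptor,
    seed: Optional[int],
    dt_ms: float,
    pre_ms: float,
    post_ms: float,
    sweep_id: str,
) -> Sweep:
    """Ideal-clamp current response to a voltage step: an exponential
    capacitive transient carrying charge C * dV plus the resistive step."""
    dv = protocol.amplitude  # mV
    n_pre = int(round(pre_ms / dt_ms))
    n_stim = int(round(protocol.duration_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    n = n_pre + n_stim + n_post
    holding_v = protocol.holding
    command = np.full(n, holding_v, dtype=np.float64)
    command[n_pre : n_pre + n_stim] += dv
    i = np.zeros(n, dtype=np.float64)
    i_hold = params.g_l * (holding_v - params.e_l)
    i[:] = i_hold
    i_ss = params.g_l * dv  # pA

    def transient(n_samples: int) -> np.ndarray:
        # per-sample averages of (C dV / tau) exp(-t/tau): rectangle-rule
        # integration of the emitted trace recovers the charge C dV exactly
        edges = np.arange(n_samples + 1) * dt_ms
        cum = 1.0 - np.exp(-edges / _VC_TAU_MS)  # fraction of charge delivered
        return params.c_m * dv * np.diff(cum) / dt_ms

    i[n_pre : n_pre + n_stim] += i_ss + transient(n_stim)
    # symmetric off-transient after the step
    i[n_pre + n_stim :] -= transient(n_post)
    if seed is not None:
        rng = np.random.default_rng(seed)
        i += rng.normal(0.0, 0.5, size=n)
    return Sweep(
        sweep_id=sweep_id,
        clamp_mode="voltage_clamp",
        sample_rate=1.0 / dt_ms,
        voltage=command,
        current=i,
        protocol=protocol,
        t0_baseline_window=(0.0, pre_ms * 0.9),
    )


def lif_rate_hz(i_pa: float, params: EIFParams) -> float:
    """Closed-form LIF firing rate under constant drive (refractory included)."""
    r_gohm = 1.0 / params.g_l
    v_inf = params.e_l + i_pa * r_gohm  # pA * GOhm = mV
    if v_inf <= params.v_t:
        return 0.0
    tau_s = params.tau_ms / 1000.0
    t = tau_s * math.log((v_inf - params.v_reset) / (v_inf - params.v_t))
    return 1.0 / (t + params.refractory_ms / 1000.0)


# ---------------------------------------------------------------------------
# curve-level generator (tier "curves")


def _increment_direction(group: str, n_inc: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance, zero-mean increment shape: one dominant jump for S,
    spread variation for L."""
    if group == "S":
        shape = rng.normal(0.0, 0.08, size=n_inc)
        shape[rng.integers(0, n_inc)] += 1.0
    else:
        shape = rng.normal(0.0, 1.0, size=n_inc)
    shape = shape - shape.mean()
    sd = shape.std(ddof=1)
    if sd == 0:
        shape[0] += 1e-6
        sd = shape.std(ddof=1)
    return shape / sd


def generate_io_counts(
    group: str,
    frequency: float,
    asl_target: float,
    var_target: float,
    onset_steps: int = 0,
    n_increments: int = 5,
    noise: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> IOCurve:
    """Input-output counts at one frequency with known generating statistics.

    Pre-rounding, the included increments have mean ``asl_target * sqrt(f)``
    and sample variance ``var_target * f`` exactly; ``noise`` adds Poisson-
    like count jitter.  ``onset_steps`` leading amplitudes spike zero times
    (the curve's lack region), shifting the measured offset.  The first
    non-zero count anchors the included run so the masked increments are the
    generated vector itself, not a truncation of it.
    """
    if group not in ("S", "L"):
        raise CohortSpecError(f"unknown group {group!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = asl_target * math.sqrt(frequency)
    sd = math.sqrt(max(var_target, 0.0) * frequency)
    d = m + sd * _increment_direction(group, n_increments, rng)
    if noise > 0:
        d = d + rng.normal(0.0, noise * math.sqrt(max(m, 1.0)), size=d.size)
    d = np.maximum(np.round(d), 1.0)  # counts must keep rising inside the run
    c0 = max(1.0, np.round(m / 2.0))
    counts = np.concatenate(
        [np.zeros(onset_steps), c0 + np.concatenate([[0.0], np.cumsum(d)])]
    ).astype(np.int64)
    n_points = counts.size
    return IOCurve(
        frequency=frequency,
        amplitudes=sine_amplitude_grid(n_points),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# cohort specification


def default_p_l_of_age(age_days: float) -> float:
    """Probability of the Linear group: 0 up to 28 d, 1 from 63 d, smooth in
    between (pinned to 0 at 21 d and 1 at 70 d)."""
    x = (age_days - 28.0) / (63.0 - 28.0)
    x = min(max(x, 0.0), 1.0)
    return x * x * (3.0 - 2.0 * x)  # smoothstep


def default_passive_drift(age_days: float) -> dict:
    """Age-dependent means and SDs for the seven intrinsic parameters.

    Input resistance decays from ~4 GOhm (3 wk) toward ~300 MOhm (10 wk);
    the other parameters mature monotonically along the same early-saturating
    trajectory (most of the drift is over by week 5, while the functional
    S-to-L switch happens later), with generous cell-to-cell scatter -- which
    is what makes the intrinsic parameters poor predictors of the functional
    group.  Fixture values, not facts.
    """
    u = min(max((age_days - 21.0) / (70.0 - 21.0), 0.0), 1.0)
    # saturating maturation, rescaled to pin both endpoints
    v = (1.0 - math.exp(-8.0 * u)) / (1.0 - math.exp(-8.0))
    r_in = 4000.0 - (4000.0 - 300.0) * v
    return {
        "r_in": (r_in, 0.36 * r_in),
        "tau_m": (55.0 - 25.0 * v, 12.0),
        "c_m": (15.0 + 45.0 * v, 12.0),
        "rmp": (-68.0 - 12.0 * v, 6.0),
        "ap_threshold": (-38.0 - 7.0 * v, 4.5),
        "peak_dvdt": (150.0 + 250.0 * v, 75.0),
        "max_rate": (25.0 + 75.0 * v, 24.0),
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort draw."""

    n_cells: int = 120
    seed: int = 20140724
    age_low: int = 21
    age_high: int = 70
    p_l_of_age: Callable[[float], float] = default_p_l_of_age
    passive_drift: Callable[[float], dict] = default_passive_drift
    centers: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CENTERS.items()})
    asl_sd: float = DEFAULT_ASL_SD
    var_sd: float = DEFAULT_VAR_SD
    #: within-L dependence of the slope on (standardized log) input resistance
    l_asl_rin_slope: float = 0.12
    #: offset scaling: leading zero steps ~ offset_scale / r_in (pA*MOhm)
    offset_scale: float = 60000.0
    count_noise: float = 0.0
    n_increments: int = 5
    frequencies: tuple = SINE_FREQUENCIES_HZ
    tier: str = "curves"  # "curves" | "traces"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise CohortSpecError("n_cells must be >= 1")
        if self.tier not in ("curves", "traces"):
            raise CohortSpecError(f"unknown tier {self.tier!r}")
        for age in (self.age_low, self.age_high, 21, 45, 70):
            p = self.p_l_of_age(age)
            if not 0.0 <= p <= 1.0:
                raise CohortSpecError(f"p_L({age}) = {p} outside [0, 1]")


@dataclass
class SyntheticCell:
    cell_id: str
    age_days: int
    group: str  # "S" | "L"
    intrinsic: dict  # seven intrinsic parameters
    curves: list[IOCurve] = field(default_factory=list)
    record: Optional[CellRecord] = None
    truth: dict = field(default_factory=dict)


# log-Rin standardization (centered on the typical Linear-group resistance
# under the default drift) used for the L-group slope dependence
_LOG_RIN_MU = math.log(307.0)
_LOG_RIN_SD = 0.42


def _draw_cell(
    spec: CohortSpec, idx: int, rng: np.random.Generator, age: Optional[int] = None
) -> SyntheticCell:
    if age is None:
        age = int(rng.integers(spec.age_low, spec.age_high + 1))
    p_l = spec.p_l_of_age(age)
    group = "L" if rng.random() < p_l else "S"
    drift = spec.passive_drift(age)
    intrinsic = {}
    for key, (mu, sd) in drift.items():
        intrinsic[key] = float(rng.normal(mu, sd))
    intrinsic["r_in"] = max(intrinsic["r_in"], 95.0)

    centers = spec.centers[group]
    z_rin = (math.log(intrinsic["r_in"]) - _LOG_RIN_MU) / _LOG_RIN_SD
    asl_t = rng.normal(centers["asl"], spec.asl_sd)
    if group == "L":
        # L cells: slope rises with input resistance; S cells: independent
        asl_t = centers["asl"] + spec.l_asl_rin_slope * z_rin + rng.normal(
            0.0, spec.asl_sd * 0.7
        )
    var_t = max(float(rng.normal(centers["var"], spec.var_sd)), 0.05)
    onset = int(
        max(0, round(spec.offset_scale / intrinsic["r_in"] / SINE_GRID_PA + rng.normal(0, 0.3)))
    )
    curves = [
        generate_io_counts(
            group,
            f,
            asl_target=float(asl_t),
            var_target=var_t,
            onset_steps=onset,
            n_increments=spec.n_increments,
            noise=spec.count_noise,
            rng=rng,
        )
        for f in spec.frequencies
    ]
    truth = {
        "asl_target": float(asl_t),
        "var_target": float(var_t),
        "onset_steps": onset,
        "p_L": p_l,
    }
    return SyntheticCell(
        cell_id=f"cell{idx:04d}",
        age_days=age,
        group=group,
        intrinsic=intrinsic,
        curves=curves,
        truth=truth,
    )


def _eif_from_intrinsic(intrinsic: dict, group: str) -> EIFParams:
    g_l = 1000.0 / intrinsic["r_in"]  # nS
    c_m = g_l * intrinsic["tau_m"]  # pF, consistent with tau = C/g
    return EIFParams(
        c_m=c_m,
        g_l=g_l,
        e_l=intrinsic["rmp"],
        v_t=intrinsic["ap_threshold"],
        delta_t=0.5 if group == "S" else 2.0,
        v_reset=intrinsic["rmp"] + 5.0,
        v_peak=20.0,
        refractory_ms=2.0,
    )


def _trace_record(
    cell: SyntheticCell,
    spec: CohortSpec,
    rng: np.random.Generator,
    n_rin_steps: int = 30,
    sine_amplitudes: Optional[Sequence[float]] = None,
) -> CellRecord:
    params = _eif_from_intrinsic(cell.intrinsic, cell.group)
    sweeps: list[Sweep] = []
    for k in range(n_rin_steps):
        sweeps.append(
            simulate_eif_sweep(
                params,
                ProtocolDescriptor(kind="hyperpol_step", amplitude=-10.0, duration_ms=300.0),
                seed=int(rng.integers(0, 2**31)),
                pre_ms=120.0,
                post_ms=150.0,
                sweep_id=f"rin{k:03d}",
            )
        )
    for k, amp in enumerate(np.arange(20.0, 201.0, 20.0)):
        sweeps.append(
            simulate_eif_sweep(
                params,
                ProtocolDescriptor(kind="square_family", amplitude=float(amp), duration_ms=1000.0),
                seed=int(rng.integers(0, 2**31)),
                sweep_id=f"sq{k:03d}",
            )
        )
    if sine_amplitudes is None:
        sine_amplitudes = sine_amplitude_grid(6)
    for f in spec.frequencies:
        for a in sine_amplitudes:
            sweeps.append(
                simulate_eif_sweep(
                    params,
                    ProtocolDescriptor(
                        kind="sine_family", amplitude=float(a), frequency=f, duration_ms=1000.0
                    ),
                    seed=int(rng.integers(0, 2**31)),
                    noise_sd_pa=5.0 if cell.group == "S" else 1.0,
                    sweep_id=f"sine{int(f):02d}_{int(a):04d}",
                )
            )
    sweeps.append(
        simulate_eif_sweep(
            params,
            ProtocolDescriptor(kind="vc_step", amplitude=-5.0, duration_ms=100.0, holding=-70.0),
            seed=None,
            sweep_id="vc000",
        )
    )
    return CellRecord(
        cell_id=cell.cell_id,
        sweeps=sweeps,
        animal_id="synthetic",
        age_days=cell.age_days,
        labeled=True,
    )


def generate_cohort(
    spec: CohortSpec, ages: Optional[Sequence[int]] = None
) -> tuple[list[SyntheticCell], pd.DataFrame]:
    """Draw a cohort; returns the cells and their ground-truth table.

    ``ages`` pins each cell's age (length must equal ``n_cells``); otherwise
    ages are uniform over the spec's range.
    """
    rng = np.random.default_rng(spec.seed)
    if ages is not None and len(ages) != spec.n_cells:
        raise CohortSpecError("ages must have n_cells entries")
    cells = []
    for i in range(spec.n_cells):
        cell = _draw_cell(spec, i, rng, age=None if ages is None else int(ages[i]))
        if spec.tier == "traces":
            cell.record = _trace_record(cell, spec, rng)
        cells.append(cell)
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "age_days": c.age_days,
            "group": c.group,
            **c.intrinsic,
            **c.truth,
        }
        rows.append(row)
    return cells, pd.DataFrame(rows)
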