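import math

import numpy as np
import pytest

from gcio.trace_io import CellRecord, ProtocolDescriptor, Sweep

SR_KHZ = 50.0  # default fixture sampling rate


def make_rc_step_sweep(
    r_mohm=300.0,
    tau_ms=30.0,
    rmp_mv=-80.0,
    amp_pa=-10.0,
    sr_khz=SR_KHZ,
    pre_ms=100.0,
    step_ms=300.0,
    post_ms=150.0,
    noise_mv=0.0,
    seed=None,
    sweep_id="step",
    kind="hyperpol_step",
):
    """Analytic RC step response (independent of the package's simulator)."""
    n_pre = int(pre_ms * sr_khz)
    n_step = int(step_ms * sr_khz)
    n_post = int(post_ms * sr_khz)
    dv = amp_pa * r_mohm / 1000.0  # pA * MOhm = uV; /1000 -> mV
    t_step = np.arange(n_step) / sr_khz
    t_post = np.arange(n_post) / sr_khz
    v = np.concatenate(
        [
            np.full(n_pre, rmp_mv),
            rmp_mv + dv * (1.0 - np.exp(-t_step / tau_ms)),
            rmp_mv + dv * (1.0 - math.exp(-step_ms / tau_ms)) * np.exp(-t_post / tau_ms),
        ]
    )
    i = np.concatenate(
        [np.zeros(n_pre), np.full(n_step, amp_pa), np.zeros(n_post)]
    )
    if noise_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_mv, size=v.size)
    return Sweep(
        sweep_id=sweep_id,
        clamp_mode="current_clamp",
        sample_rate=sr_khz,
        voltage=v,
        current=i,
        protocol=ProtocolDescriptor(kind=kind, amplitude=amp_pa, duration_ms=step_ms),
        t0_baseline_window=(0.0, pre_ms * 0.9),
    )


def make_spike_sweep(
    spike_times_ms,
    peak_dvdt=150.0,
    baseline_mv=-75.0,
    duration_ms=1000.0,
    sr_khz=SR_KHZ,
    amp_pa=100.0,
    kind="square_family",
    frequency=None,
    sweep_id="spikes",
):
    """Flat trace with triangular spike waveforms of known upstroke slope.

    Each spike rises at ``peak_dvdt`` mV/ms for 0.5 ms and decays back over
    2 ms -- construction ground truth for derivative-based detection.
    """
    n = int(duration_ms * sr_khz)
    v = np.full(n, baseline_mv)
    rise_ms, fall_ms = 0.5, 2.0
    n_rise = int(rise_ms * sr_khz)
    n_fall = int(fall_ms * sr_khz)
    height = peak_dvdt * rise_ms
    for t in spike_times_ms:
        k = int(t * sr_khz)
        up = np.arange(1, n_rise + 1) * (height / n_rise)
        down = height * (1.0 - np.arange(1, n_fall + 1) / n_fall)
        stop_u = min(k + n_rise, n)
        v[k:stop_u] += up[: stop_u - k]
        stop_d = min(k + n_rise + n_fall, n)
        v[stop_u:stop_d] += down[: stop_d - stop_u]
    i = np.zeros(n)
    proto_kwargs = {"kind": kind, "amplitude": amp_pa, "duration_ms": duration_ms}
    if kind == "sine_family":
        proto_kwargs["frequency"] = frequency
    return Sweep(
        sweep_id=sweep_id,
        clamp_mode="current_clamp",
        sample_rate=sr_khz,
        voltage=v,
        current=i,
        protocol=ProtocolDescriptor(**proto_kwargs),
        t0_baseline_window=(0.0, 5.0),
    )


def make_vc_step_sweep(
    charge_fc=150.0,
    dv_mv=-5.0,
    r_mohm=500.0,
    holding_mv=-70.0,
    sr_khz=SR_KHZ,
    pre_ms=50.0,
    step_ms=100.0,
    post_ms=50.0,
    tau_c_ms=0.2,
    sweep_id="vc",
):
    """Voltage-clamp step with an exponential transient of known charge."""
    n_pre = int(pre_ms * sr_khz)
    n_step = int(step_ms * sr_khz)
    n_post = int(post_ms * sr_khz)
    n = n_pre + n_step + n_post
    command = np.full(n, holding_mv)
    command[n_pre : n_pre + n_step] += dv_mv
    i_ss = dv_mv / r_mohm * 1000.0  # pA
    dt = 1.0 / sr_khz
    edges = np.arange(n_step + 1) * dt
    cum = 1.0 - np.exp(-edges / tau_c_ms)
    per_sample = charge_fc * np.sign(dv_mv) * np.diff(cum) / dt
    i = np.zeros(n)
    i[n_pre : n_pre + n_step] = i_ss + per_sample
    return Sweep(
        sweep_id=sweep_id,
        clamp_mode="voltage_clamp",
        sample_rate=sr_khz,
        voltage=command,
        current=i,
        protocol=ProtocolDescriptor(
            kind="vc_step", amplitude=dv_mv, duration_ms=step_ms, holding=holding_mv
        ),
        t0_baseline_window=(0.0, pre_ms * 0.9),
    )


def make_cell_record(sweeps, cell_id="cell0", age_days=40, labeled=True, **kw):
    return CellRecord(
        cell_id=cell_id, sweeps=list(sweeps), age_days=age_days, labeled=labeled, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140724)


@pytest.fixture
def full_record():
    """A cell bundle with every protocol kind (small, fast to build)."""
    sweeps = [
        make_rc_step_sweep(sweep_id=f"rin{k}", seed=k, noise_mv=0.05)
        for k in range(5)
    ]
    sweeps.append(make_vc_step_sweep(sweep_id="vc0"))
    sweeps.append(
        make_rc_step_sweep(
            amp_pa=-50.0, step_ms=50.0, sweep_id="mon0", kind="monitor_step"
        )
    )
    for k, amp in enumerate((20.0, 40.0, 60.0)):
        n_spk = (0, 3, 8)[k]
        times = np.linspace(120, 900, n_spk) if n_spk else []
        sweeps.append(
            make_spike_sweep(times, amp_pa=amp, sweep_id=f"sq{k}")
        )
    for f in (5.0, 10.0, 20.0, 40.0, 60.0, 80.0):
        for j, amp in enumerate((50.0, 100.0, 150.0, 200.0)):
            n_spk = j * 2
            times = np.linspace(150, 850, n_spk) if n_spk else []
            sweeps.append(
                make_spike_sweep(
                    times,
                    amp_pa=amp,
                    kind="sine_family",
                    frequency=f,
                    sweep_id=f"sine{int(f)}_{int(amp)}",
                )
            )
    return make_cell_record(sweeps)
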