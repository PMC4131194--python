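"""Sweep bundle containers and on-disk formats.

A *bundle* is all data recorded from one cell: a set of sweeps (one stimulus
episode each) plus identity metadata.  Two canonical containers are supported:

* ``hdf5`` -- one file per cell, ``/sweeps/<id>/{voltage,current}`` datasets
  with attribute metadata.  Compact, for bulk data.
* ``csv_json`` -- one directory per cell with ``manifest.json`` plus one CSV
  per sweep.  Diffable, for human-readable fixtures; the writer is
  deterministic so that write -> read -> write is byte-identical.

An optional read-only NWB import is provided when :mod:`pynwb` is installed.

Units are normalized on read to mV (voltage), pA (current) and kHz
(sampling rate); files missing unit declarations are rejected.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SINE_FREQUENCIES_HZ = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0)
SINE_DURATION_MS = 1000.0
SINE_GRID_PA = 50.0
SQUARE_GRID_PA = 20.0
#: labeled-cell postmitotic age range covered by the recordings (days)
AGE_RANGE_DAYS = (20, 72)

PROTOCOL_KINDS = (
    "hyperpol_step",
    "square_family",
    "sine_family",
    "vc_step",
    "monitor_step",
)

_VOLTAGE_FACTORS = {"mV": 1.0, "V": 1000.0, "uV": 1e-3}
_CURRENT_FACTORS = {"pA": 1.0, "nA": 1000.0, "A": 1e12}
_RATE_FACTORS = {"kHz": 1.0, "Hz": 1e-3}


class BundleFormatError(ValueError):
    """Raised when an on-disk bundle violates the container contract."""


def _isclose_grid(value: float, grid: float) -> bool:
    return abs(value / grid - round(value / grid)) < 1e-9


@dataclass
class ProtocolDescriptor:
    """Stimulus protocol metadata for one sweep.

    ``amplitude`` is in pA except for ``vc_step`` where it is the command
    voltage step in mV.  ``frequency`` applies to ``sine_family`` only and
    must lie on the tested grid (5/10/20/40/60/80 Hz).
    """

    kind: str
    amplitude: float
    frequency: Optional[float] = None
    duration_ms: float = 1000.0
    holding: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "sine_family":
            if self.frequency is None or not any(
                math.isclose(self.frequency, f) for f in SINE_FREQUENCIES_HZ
            ):
                raise ValueError(
                    f"frequency not in protocol grid: {self.frequency!r} "
                    f"(allowed: {SINE_FREQUENCIES_HZ})"
                )
            if not math.isclose(self.duration_ms, SINE_DURATION_MS):
                raise ValueError(
                    f"sine sweeps last {SINE_DURATION_MS} ms, got {self.duration_ms}"
                )
            if not _isclose_grid(self.amplitude, SINE_GRID_PA):
                raise ValueError(
                    f"sine amplitude {self.amplitude} pA off the "
                    f"{SINE_GRID_PA} pA grid"
                )
        elif self.frequency is not None:
            raise ValueError(f"frequency given for non-sine protocol {self.kind!r}")
        if self.kind == "square_family" and not _isclose_grid(
            self.amplitude, SQUARE_GRID_PA
        ):
            raise ValueError(
                f"square amplitude {self.amplitude} pA off the "
                f"{SQUARE_GRID_PA} pA grid"
            )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "frequency": self.frequency,
            "duration_ms": self.duration_ms,
            "holding": self.holding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolDescriptor":
        return cls(
            kind=d["kind"],
            amplitude=float(d["amplitude"]),
            frequency=None if d.get("frequency") is None else float(d["frequency"]),
            duration_ms=float(d.get("duration_ms", 1000.0)),
            holding=float(d.get("holding", 0.0)),
        )


@dataclass
class Sweep:
    """One stimulus episode.

    ``voltage`` holds the recorded membrane potential in current clamp and
    the command potential in voltage clamp (mV); ``current`` holds the
    command current in current clamp and the recorded current in voltage
    clamp (pA).  Time is implicit: sample ``i`` is at ``i / sample_rate`` ms.
    """

    sweep_id: str
    clamp_mode: str  # "current_clamp" | "voltage_clamp"
    sample_rate: float  # kHz
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA
    protocol: ProtocolDescriptor
    t0_baseline_window: tuple[float, float] = (0.0, 50.0)  # ms
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.clamp_mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"bad clamp_mode {self.clamp_mode!r}")
        if self.voltage.shape != self.current.shape or self.voltage.ndim != 1:
            raise ValueError(
                f"sweep {self.sweep_id!r}: voltage and current series must be "
                f"1-D and of equal length "
                f"({self.voltage.shape} vs {self.current.shape})"
            )
        if not self.sample_rate > 0:
            raise ValueError(f"sweep {self.sweep_id!r}: sample_rate must be > 0")
        lo, hi = self.t0_baseline_window
        if not (0.0 <= lo < hi <= self.duration_ms + 1e-9):
            raise ValueError(
                f"sweep {self.sweep_id!r}: baseline window ({lo}, {hi}) ms "
                f"outside sweep of {self.duration_ms} ms"
            )

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration_ms(self) -> float:
        return self.voltage.size / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.voltage.size) / self.sample_rate

    def baseline_slice(self) -> slice:
        lo, hi = self.t0_baseline_window
        return slice(int(round(lo * self.sample_rate)), int(round(hi * self.sample_rate)))

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            self.sweep_id == other.sweep_id
            and self.clamp_mode == other.clamp_mode
            and self.sample_rate == other.sample_rate
            and self.protocol == other.protocol
            and self.t0_baseline_window == other.t0_baseline_window
            and np.array_equal(self.voltage, other.voltage)
            and np.array_equal(self.current, other.current)
            and self.extra == other.extra
        )


@dataclass
class CellRecord:
    """All sweeps of one cell plus identity metadata."""

    cell_id: str
    sweeps: list[Sweep]
    animal_id: str = ""
    age_days: Optional[int] = None  # days post virus injection; None if unknown
    labeled: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.labeled:
            if self.age_days is None:
                raise ValueError(f"cell {self.cell_id!r}: labeled cell needs age_days")
            lo, hi = AGE_RANGE_DAYS
            if not lo <= self.age_days <= hi:
                raise ValueError(
                    f"cell {self.cell_id!r}: age_days={self.age_days} outside "
                    f"the labeled range [{lo}, {hi}]"
                )
        ids = [s.sweep_id for s in self.sweeps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cell {self.cell_id!r}: duplicate sweep ids")

    def sweeps_of_kind(self, kind: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.protocol.kind == kind]

    def sine_sweeps(self, frequency: float) -> list[Sweep]:
        return [
            s
            for s in self.sweeps
            if s.protocol.kind == "sine_family"
            and math.isclose(s.protocol.frequency, frequency)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellRecord):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.animal_id == other.animal_id
            and self.age_days == other.age_days
            and self.labeled == other.labeled
            and self.notes == other.notes
            # readers return sweeps sorted by id; compare order-insensitively
            and sorted(self.sweeps, key=lambda s: s.sweep_id)
            == sorted(other.sweeps, key=lambda s: s.sweep_id)
        )


# ---------------------------------------------------------------------------
# unit normalization


def normalize_units(
    voltage: np.ndarray,
    current: np.ndarray,
    sample_rate: float,
    voltage_unit: str,
    current_unit: str,
    rate_unit: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Convert series to the canonical mV / pA / kHz triple.

    Idempotent: normalizing already-canonical data is a no-op.
    """
    try:
        vf = _VOLTAGE_FACTORS[voltage_unit]
        cf = _CURRENT_FACTORS[current_unit]
        rf = _RATE_FACTORS[rate_unit]
    except KeyError as exc:
        raise BundleFormatError(f"unknown unit {exc.args[0]!r}") from exc
    return (
        np.asarray(voltage, dtype=np.float64) * vf,
        np.asarray(current, dtype=np.float64) * cf,
        float(sample_rate) * rf,
    )


# ---------------------------------------------------------------------------
# HDF5 container


def _write_hdf5(record: CellRecord, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = record.cell_id
        f.attrs["animal_id"] = record.animal_id
        f.attrs["labeled"] = bool(record.labeled)
        f.attrs["age_days"] = -1 if record.age_days is None else int(record.age_days)
        f.attrs["notes"] = record.notes
        f.attrs["voltage_unit"] = "mV"
        f.attrs["current_unit"] = "pA"
        f.attrs["rate_unit"] = "kHz"
        grp = f.create_group("sweeps")
        for sweep in record.sweeps:
            g = grp.create_group(sweep.sweep_id)
            g.create_dataset("voltage", data=sweep.voltage, dtype="f8")
            g.create_dataset("current", data=sweep.current, dtype="f8")
            g.attrs["clamp_mode"] = sweep.clamp_mode
            g.attrs["sample_rate"] = sweep.sample_rate
            g.attrs["baseline_ms"] = list(sweep.t0_baseline_window)
            g.attrs["protocol"] = json.dumps(sweep.protocol.to_dict(), sort_keys=True)
            if sweep.extra:
                g.attrs["extra"] = json.dumps(sweep.extra, sort_keys=True)


def _read_hdf5(path: str) -> CellRecord:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("voltage_unit", "current_unit", "rate_unit"):
            if key not in f.attrs:
                raise BundleFormatError(f"{path}: missing required attribute {key!r}")
        vu, cu, ru = (
            str(f.attrs["voltage_unit"]),
            str(f.attrs["current_unit"]),
            str(f.attrs["rate_unit"]),
        )
        sweeps = []
        for sid in sorted(f["sweeps"]):
            g = f["sweeps"][sid]
            v = g["voltage"][...]
            c = g["current"][...]
            if v.shape != c.shape:
                raise BundleFormatError(
                    f"{path}: sweep {sid!r} has truncated series "
                    f"({v.shape} vs {c.shape})"
                )
            v, c, sr = normalize_units(v, c, float(g.attrs["sample_rate"]), vu, cu, ru)
            try:
                proto = ProtocolDescriptor.from_dict(json.loads(g.attrs["protocol"]))
            except ValueError as exc:
                raise BundleFormatError(f"{path}: sweep {sid!r}: {exc}") from exc
            extra = json.loads(g.attrs["extra"]) if "extra" in g.attrs else {}
            sweeps.append(
                Sweep(
                    sweep_id=sid,
                    clamp_mode=str(g.attrs["clamp_mode"]),
                    sample_rate=sr,
                    voltage=v,
                    current=c,
                    protocol=proto,
                    t0_baseline_window=tuple(float(x) for x in g.attrs["baseline_ms"]),
                    extra=extra,
                )
            )
        age = int(f.attrs["age_days"])
        return CellRecord(
            cell_id=str(f.attrs["cell_id"]),
            animal_id=str(f.attrs["animal_id"]),
            age_days=None if age < 0 else age,
            labeled=bool(f.attrs["labeled"]),
            notes=str(f.attrs["notes"]),
            sweeps=sweeps,
        )


# ---------------------------------------------------------------------------
# CSV + JSON fixture dialect (diffable; deterministic bytes)

_FLOAT_FMT = "%.17g"  # shortest repr that survives float64 round-trips


def _write_csv_json(record: CellRecord, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    manifest = {
        "container": "gcio-cell-bundle",
        "version": 1,
        "units": {"voltage": "mV", "current": "pA", "rate": "kHz"},
        "cell_id": record.cell_id,
        "animal_id": record.animal_id,
        "age_days": record.age_days,
        "labeled": record.labeled,
        "notes": record.notes,
        "sweeps": [
            {
                "sweep_id": s.sweep_id,
                "clamp_mode": s.clamp_mode,
                "sample_rate": s.sample_rate,
                "baseline_ms": list(s.t0_baseline_window),
                "protocol": s.protocol.to_dict(),
                "extra": s.extra,
                "file": f"{s.sweep_id}.csv",
            }
            for s in sorted(record.sweeps, key=lambda s: s.sweep_id)
        ],
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for s in record.sweeps:
        data = np.column_stack([s.voltage, s.current])
        with open(os.path.join(path, f"{s.sweep_id}.csv"), "w") as fh:
            fh.write("voltage_mV,current_pA\n")
            np.savetxt(fh, data, fmt=_FLOAT_FMT, delimiter=",")


def _read_csv_json(path: str) -> CellRecord:
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise BundleFormatError(f"{path}: no manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "units" not in manifest:
        raise BundleFormatError(f"{path}: manifest missing 'units'")
    units = manifest["units"]
    sweeps = []
    for meta in manifest["sweeps"]:
        csv_path = os.path.join(path, meta["file"])
        data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
        if data.shape[1] != 2:
            raise BundleFormatError(
                f"{csv_path}: expected 2 columns, got {data.shape[1]}"
            )
        v, c, sr = normalize_units(
            data[:, 0],
            data[:, 1],
            float(meta["sample_rate"]),
            units["voltage"],
            units["current"],
            units["rate"],
        )
        try:
            proto = ProtocolDescriptor.from_dict(meta["protocol"])
        except ValueError as exc:
            raise BundleFormatError(
                f"{path}: sweep {meta['sweep_id']!r}: {exc}"
            ) from exc
        sweeps.append(
            Sweep(
                sweep_id=meta["sweep_id"],
                clamp_mode=meta["clamp_mode"],
                sample_rate=sr,
                voltage=v,
                current=c,
                protocol=proto,
                t0_baseline_window=tuple(float(x) for x in meta["baseline_ms"]),
                extra=meta.get("extra", {}),
            )
        )
    return CellRecord(
        cell_id=manifest["cell_id"],
        animal_id=manifest["animal_id"],
        age_days=manifest["age_days"],
        labeled=manifest["labeled"],
        notes=manifest["notes"],
        sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# optional NWB import (read-only)


def _read_nwb(path: str) -> CellRecord:
    try:
        from pynwb import NWBHDF5IO  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "NWB import requires the optional 'pynwb' package"
        ) from exc
    # Map CurrentClampSeries / stimulus pairs onto Sweep; anything else is
    # skipped with a logged warning.
    from pynwb import NWBHDF5IO

    with NWBHDF5IO(path, "r", load_namespaces=True) as io:  # pragma: no cover
        nwb = io.read()
        sweeps: list[Sweep] = []
        acq = dict(nwb.acquisition)
        stim = dict(nwb.stimulus)
        for name, series in acq.items():
            if type(series).__name__ != "CurrentClampSeries":
                logger.warning("NWB import: skipping unsupported series %r", name)
                continue
            partner = stim.get(name.replace("response", "stimulus"))
            if partner is None:
                logger.warning("NWB import: no stimulus for %r; skipped", name)
                continue
            v = np.asarray(series.data[:]) * series.conversion * 1e3  # V -> mV
            c = np.asarray(partner.data[:]) * partner.conversion * 1e12  # A -> pA
            sweeps.append(
                Sweep(
                    sweep_id=name,
                    clamp_mode="current_clamp",
                    sample_rate=series.rate / 1e3,
                    voltage=v,
                    current=c,
                    protocol=ProtocolDescriptor(kind="square_family", amplitude=0.0),
                )
            )
        return CellRecord(cell_id=nwb.identifier, sweeps=sweeps)


# ---------------------------------------------------------------------------
# public API


def write_cell_bundle(record: CellRecord, path: str, format: str = "hdf5") -> str:
    """Serialize ``record`` at ``path``; returns ``path``.

    Lossless for series values: stored as float64 (HDF5) or 17-significant-
    digit decimal (CSV), both of which round-trip IEEE doubles exactly.
    """
    if format == "hdf5":
        _write_hdf5(record, path)
    elif format == "csv_json":
        _write_csv_json(record, path)
    elif format == "nwb":
        raise ValueError("NWB write support is out of scope (read-only import)")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_cell_bundle(path: str, format: Optional[str] = None) -> CellRecord:
    """Read a cell bundle, inferring the container when ``format`` is None."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        if os.path.isdir(path):
            format = "csv_json"
        elif path.endswith(".nwb"):
            format = "nwb"
        else:
            format = "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv_json":
        return _read_csv_json(path)
    if format == "nwb":
        return _read_nwb(path)
    raise ValueError(f"unknown format {format!r}")


def sine_amplitude_grid(n_points: int, grid_pa: float = SINE_GRID_PA) -> np.ndarray:
    """Amplitude grid 50, 100, ... pA used by the sinusoidal protocol."""
    return grid_pa * np.arange(1, n_points + 1, dtype=np.float64)
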