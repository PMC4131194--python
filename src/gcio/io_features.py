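"""Sinusoidal input-output curves and the three gain statistics.

For each stimulation frequency f the input-output curve is the spike count
per 1 s sweep versus the peak amplitude of the injected sinusoid (50 pA
grid).  Points are masked for lack of spiking (leading zeros) and for
saturation (the tail from the first non-increase onward); statistics are then
computed on the successive increments d of the included counts:

* ``asl_f = mean(d) / sqrt(f)`` -- frequency-weighted average slope,
* ``var_f = var(d, ddof=1) / f`` -- frequency-weighted increment variance,
* ``offset_f = A* / f**0.25`` where ``A*`` is the smallest amplitude whose
  count strictly exceeds f/2 (half the input frequency, counts per 1 s being
  a rate in Hz).

Weight direction note: the frequency weighting is applied as a *division*
(sqrt(f) for the slope, f for the variance, f**(1/4) for the offset), which
compresses the frequency-driven growth of spike counts into pooled values of
order 1-2.  Pooling across frequencies is the arithmetic mean of the defined
per-frequency values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from gcio.ephys_features import detect_spikes
from gcio.trace_io import SINE_FREQUENCIES_HZ, SINE_GRID_PA, Sweep

#: minimum number of included points for the increment statistics
MIN_INCLUDED_POINTS = 3
#: minimum number of defined frequencies for a pooled cell value
MIN_DEFINED_FREQUENCIES = 3


class IOCurveError(ValueError):
    pass


@dataclass
class IOCurve:
    """Spike counts vs sinusoid peak amplitude at one frequency."""

    frequency: float  # Hz, one of 5/10/20/40/60/80
    amplitudes: np.ndarray  # pA, strictly increasing on the 50 pA grid
    counts: np.ndarray  # spikes per 1 s sweep
    included: np.ndarray = None  # boolean mask, single contiguous run

    def __post_init__(self) -> None:
        if not any(math.isclose(self.frequency, f) for f in SINE_FREQUENCIES_HZ):
            raise IOCurveError(f"frequency {self.frequency} not in protocol grid")
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        if self.amplitudes.shape != self.counts.shape or self.amplitudes.ndim != 1:
            raise IOCurveError("amplitudes and counts must be 1-D, equal length")
        steps = np.diff(self.amplitudes)
        if self.amplitudes.size > 1 and not np.allclose(steps, SINE_GRID_PA):
            raise IOCurveError(
                f"non-contiguous grid: amplitudes must increase by {SINE_GRID_PA} pA"
            )
        if np.any(self.counts < 0) or not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise IOCurveError("counts must be non-negative integers")
        self.counts = np.round(self.counts).astype(np.int64)
        if self.included is None:
            self.included = np.ones(self.counts.shape, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.shape != self.counts.shape:
                raise IOCurveError("included mask shape mismatch")
            idx = np.nonzero(self.included)[0]
            if idx.size and not np.array_equal(
                idx, np.arange(idx[0], idx[-1] + 1)
            ):
                raise IOCurveError("included mask must be a single contiguous run")

    @property
    def n_included(self) -> int:
        return int(np.count_nonzero(self.included))

    @property
    def defined(self) -> bool:
        """Whether increment statistics are defined at this frequency."""
        return self.n_included >= MIN_INCLUDED_POINTS

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IOCurve):
            return NotImplemented
        return (
            math.isclose(self.frequency, other.frequency)
            and np.array_equal(self.amplitudes, other.amplitudes)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.included, other.included)
        )


@dataclass
class IOFeatureSet:
    """Pooled, frequency-independent gain statistics for one cell."""

    asl: Optional[float]
    var: Optional[float]
    offset_norm: Optional[float]  # pA * Hz**(-1/4)
    per_frequency: list[dict] = field(default_factory=list)
    complete: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# curve construction and masking


def build_io_curve(
    sine_sweeps: Sequence[Sweep], on_duplicate: str = "error"
) -> IOCurve:
    """Assemble the input-output curve of one frequency from its sine sweeps.

    ``on_duplicate`` controls repeated amplitudes: ``"error"`` (fixtures) or
    ``"average"`` (real data; flagged with a warning).
    """
    if not sine_sweeps:
        raise IOCurveError("no sine sweeps")
    freqs = {s.protocol.frequency for s in sine_sweeps}
    if len(freqs) != 1:
        raise IOCurveError(f"sweeps mix frequencies: {sorted(freqs)}")
    frequency = freqs.pop()
    by_amp: dict[float, list[int]] = {}
    for s in sine_sweeps:
        n = len(detect_spikes(s))
        by_amp.setdefault(float(s.protocol.amplitude), []).append(n)
    amps = np.array(sorted(by_amp), dtype=np.float64)
    counts = []
    for a in amps:
        vals = by_amp[float(a)]
        if len(vals) > 1 and len(set(vals)) > 1:
            if on_duplicate == "error":
                raise IOCurveError(
                    f"duplicate amplitude {a} pA with conflicting counts {vals}"
                )
            warnings.warn(
                f"duplicate amplitude {a} pA: averaging counts {vals}", stacklevel=2
            )
        counts.append(int(round(float(np.mean(vals)))))
    return IOCurve(frequency=frequency, amplitudes=amps, counts=np.array(counts))


def mask_io_curve(curve: IOCurve) -> IOCurve:
    """Apply the lack/saturation mask.

    Leading zero counts are excluded (lack of spiking); the tail is excluded
    from the first point whose count fails to exceed the previous included
    count (saturation onset).  The result is a contiguous run; when fewer
    than three points survive, the curve is undefined at this frequency
    (all-False mask).  Idempotent.
    """
    counts = curve.counts
    n = counts.size
    start = 0
    if curve.included.any():
        start = int(np.nonzero(curve.included)[0][0])
    while start < n and counts[start] == 0:
        start += 1
    stop = start + 1
    limit = n
    if curve.included.any():
        limit = int(np.nonzero(curve.included)[0][-1]) + 1
    while stop < limit and counts[stop] > counts[stop - 1]:
        stop += 1
    mask = np.zeros(n, dtype=bool)
    if stop - start >= MIN_INCLUDED_POINTS:
        mask[start:stop] = True
    return replace(curve, included=mask)


# ---------------------------------------------------------------------------
# statistics


def compute_io_statistics(curve: IOCurve) -> tuple[Optional[float], Optional[float]]:
    """Per-frequency (asl_f, var_f) from the included increments.

    Increments are in spikes per 50 pA grid step; the slope is divided by
    sqrt(f), the sample variance (n-1 denominator) by f.  Returns
    ``(None, None)`` when the curve is undefined.
    """
    if not curve.defined:
        return None, None
    c = curve.counts[curve.included].astype(np.float64)
    d = np.diff(c)
    asl_f = float(np.mean(d) / math.sqrt(curve.frequency))
    var_f = float(np.var(d, ddof=1) / curve.frequency)
    return asl_f, var_f


def compute_offset(curve: IOCurve) -> Optional[float]:
    """Normalized offset: smallest amplitude whose count strictly exceeds
    f/2, divided by f**(1/4); None when the criterion is never met."""
    half = curve.frequency / 2.0
    above = np.nonzero(curve.counts > half)[0]
    if above.size == 0:
        return None
    amp = float(curve.amplitudes[above[0]])
    return amp / curve.frequency**0.25


def pool_features(curves: Sequence[IOCurve]) -> IOFeatureSet:
    """Pool the per-frequency statistics of one cell.

    Curves are masked if not already; pooled values are arithmetic means of
    the defined per-frequency values.  A cell with fewer than three defined
    frequencies is flagged incomplete (pooled slope/variance set to None).
    """
    per_frequency = []
    asls, vars_, offsets = [], [], []
    notes: list[str] = []
    for curve in sorted(curves, key=lambda c: c.frequency):
        masked = mask_io_curve(curve)
        asl_f, var_f = compute_io_statistics(masked)
        off_f = compute_offset(masked)
        per_frequency.append(
            {
                "frequency": masked.frequency,
                "asl_f": asl_f,
                "var_f": var_f,
                "offset_f": off_f,
                "n_included": masked.n_included,
            }
        )
        if asl_f is not None:
            asls.append(asl_f)
            vars_.append(var_f)
        else:
            notes.append(f"{masked.frequency:g} Hz undefined (mask < 3 points)")
        if off_f is not None:
            offsets.append(off_f)

    complete = len(asls) >= MIN_DEFINED_FREQUENCIES
    if not complete:
        notes.append(
            f"only {len(asls)} defined frequencies "
            f"(< {MIN_DEFINED_FREQUENCIES}): cell incomplete"
        )
    return IOFeatureSet(
        asl=float(np.mean(asls)) if complete else None,
        var=float(np.mean(vars_)) if complete else None,
        offset_norm=float(np.mean(offsets)) if offsets else None,
        per_frequency=per_frequency,
        complete=complete,
        notes=notes,
    )
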