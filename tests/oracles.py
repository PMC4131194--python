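"""Independent brute-force oracles, deliberately written with plain Python
loops and no imports from the package's computation paths.

These recompute the gain statistics from first principles (mask rule,
increment mean/variance, offset criterion) so the pipeline can be checked
against them to machine precision.
"""

import math


def oracle_mask(counts):
    """Return (start, stop) of the included run, or None if < 3 points."""
    n = len(counts)
    start = 0
    while start < n and counts[start] == 0:
        start += 1
    stop = start + 1
    while stop < n and counts[stop] > counts[stop - 1]:
        stop += 1
    if stop - start < 3:
        return None
    return (start, stop)


def oracle_asl_var(counts, frequency):
    """(asl_f, var_f) by direct arithmetic on the masked counts."""
    run = oracle_mask(counts)
    if run is None:
        return None, None
    start, stop = run
    included = [counts[i] for i in range(start, stop)]
    d = [included[i + 1] - included[i] for i in range(len(included) - 1)]
    mean_d = sum(d) / len(d)
    var_d = sum((x - mean_d) ** 2 for x in d) / (len(d) - 1)
    return mean_d / math.sqrt(frequency), var_d / frequency


def oracle_offset(counts, amplitudes, frequency):
    """Smallest amplitude with count strictly above f/2, over f**(1/4)."""
    for a, c in zip(amplitudes, counts):
        if c > frequency / 2.0:
            return a / frequency**0.25
    return None


def oracle_pool(per_freq_values):
    """Arithmetic mean of the defined (non-None) per-frequency values."""
    defined = [v for v in per_freq_values if v is not None]
    if not defined:
        return None
    return sum(defined) / len(defined)


def mixture_variance(w, mu1, var1, mu2, var2):
    """Closed-form variance of a two-component mixture (weight w on comp 1)."""
    mu = w * mu1 + (1 - w) * mu2
    return (
        w * (var1 + (mu1 - mu) ** 2) + (1 - w) * (var2 + (mu2 - mu) ** 2)
    )
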