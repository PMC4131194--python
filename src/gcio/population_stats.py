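"""Two-population inference on the per-cell feature table.

The core question: does a per-cell gain statistic (pooled slope or variance)
come from one Gaussian population or two?  Answered two ways: a least-squares
one- vs two-component Gaussian fit to the histogram compared with an
extra-sum-of-squares F-test, and K-means (k=2) with a one-way ANOVA of the
separation.  A Ward hierarchical clustering on the seven z-scored intrinsic
parameters quantifies whether passive/excitability maturation predicts the
functional group (it should not); age-binned group probabilities, parabolic
mean-variance fits and per-group regressions against input resistance
complete the battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

#: default seed for all stochastic steps
DEFAULT_SEED = 20140724

#: the seven intrinsic parameters used for the hierarchical clustering
INTRINSIC_PARAMS = (
    "rmp",
    "tau_m",
    "c_m",
    "r_in",
    "ap_threshold",
    "peak_dvdt",
    "max_rate",
)

AGE_BIN_WEEKS = tuple(range(3, 11))  # weekly bins, 3-10 weeks


class StatsError(RuntimeError):
    pass


@dataclass
class GaussianComparison:
    one_comp: dict  # {"mu", "sigma", "amp", "sse"}
    two_comp: dict  # {"mu1","sigma1","mu2","sigma2","w","amp","sse"}
    f_stat: float
    p_value: float
    preferred: str  # "one" | "two"
    n_bins: int


@dataclass
class ClusterResult:
    labels: np.ndarray  # "S" | "L" per cell
    centers: dict  # {"S": float, "L": float}
    mean_dist: dict  # mean |value - center| per cluster
    separation_p: float
    separation_f: float


@dataclass
class AgeGroupProbability:
    age_bin_weeks: int
    n_cells: int
    p_S: float
    p_L: float


@dataclass
class FitSummary:
    kind: str  # "linear" | "parabolic"
    coefficients: np.ndarray  # highest order first
    adjusted_r2: float
    p_value: float
    n: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Gaussian comparison


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _gauss2(x, a1, mu1, s1, a2, mu2, s2):
    return _gauss(x, a1, mu1, s1) + _gauss(x, a2, mu2, s2)


def _fd_bins(values: np.ndarray, min_bins: int = 10) -> int:
    edges = np.histogram_bin_edges(values, bins="fd")
    return max(len(edges) - 1, min_bins)


def compare_gaussians(
    values: Sequence[float], alpha: float = 0.05, min_bins: int = 16
) -> GaussianComparison:
    """One- vs two-component Gaussian comparison on the binned distribution.

    The histogram (Freedman-Diaconis bin width, floor of ``min_bins``) is fit
    with one and with two Gaussian components by least squares weighted by
    the Poisson bin noise (sigma = sqrt(max(count, 1))); the nested models
    are compared with an extra-sum-of-squares F-test on the weighted
    residuals.  ``preferred`` is "two" iff p < ``alpha``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 20:
        raise StatsError(f"need >= 20 values, got {values.size}")
    n_bins = _fd_bins(values, min_bins)
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    y = counts.astype(np.float64)
    w_sigma = np.sqrt(np.maximum(y, 1.0))
    span = float(values.max() - values.min())
    if span == 0:
        raise StatsError("degenerate sample: all values identical")
    sigma_bounds = (span / (4.0 * n_bins), 2.0 * span)
    amp_max = 4.0 * y.max() + 1.0

    # one component
    p0 = [y.max(), float(values.mean()), float(values.std())]
    try:
        popt1, _ = curve_fit(
            _gauss,
            centers,
            y,
            p0=p0,
            bounds=(
                [0.0, values.min() - span, sigma_bounds[0]],
                [amp_max, values.max() + span, sigma_bounds[1]],
            ),
            sigma=w_sigma,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise StatsError(f"one-component fit did not converge: {exc}") from exc
    sse1 = float(np.sum(((y - _gauss(centers, *popt1)) / w_sigma) ** 2))

    # two components, initialized from a 2-means split
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(values.reshape(-1, 1))
    mus = np.sort(km.cluster_centers_.ravel())
    split = 0.5 * (mus[0] + mus[1])
    sds = [
        float(
            np.clip(
                np.std(values[values <= split] if k == 0 else values[values > split]),
                sigma_bounds[0] * 2,
                sigma_bounds[1] / 2,
            )
        )
        for k in (0, 1)
    ]
    p0_2 = [y.max(), mus[0], sds[0], y.max(), mus[1], sds[1]]
    lo = [0.0, values.min() - span, sigma_bounds[0]] * 2
    hi = [amp_max, values.max() + span, sigma_bounds[1]] * 2
    try:
        popt2, _ = curve_fit(
            _gauss2, centers, y, p0=p0_2, bounds=(lo, hi), sigma=w_sigma, maxfev=40000
        )
        sse2 = float(np.sum(((y - _gauss2(centers, *popt2)) / w_sigma) ** 2))
    except RuntimeError:
        popt2, sse2 = None, np.inf

    if popt2 is None or sse2 > sse1:
        # nested-model guarantee: the two-component family contains the
        # one-component fit (second amplitude 0)
        popt2 = np.array([popt1[0], popt1[1], popt1[2], 0.0, popt1[1], popt1[2]])
        sse2 = sse1

    df1 = n_bins - 3
    df2 = n_bins - 6
    if df2 <= 0:
        raise StatsError("too few histogram bins for the F-test")
    if sse2 == 0.0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = max(0.0, ((sse1 - sse2) / (df1 - df2)) / (sse2 / df2))
        p_value = float(stats.f.sf(f_stat, df1 - df2, df2))

    a1, mu1, s1, a2, mu2, s2 = popt2
    w = a1 * s1 / (a1 * s1 + a2 * s2) if (a1 * s1 + a2 * s2) > 0 else 1.0
    return GaussianComparison(
        one_comp={"amp": popt1[0], "mu": popt1[1], "sigma": popt1[2], "sse": sse1},
        two_comp={
            "amp1": a1,
            "mu1": mu1,
            "sigma1": s1,
            "amp2": a2,
            "mu2": mu2,
            "sigma2": s2,
            "w": float(w),
            "sse": sse2,
        },
        f_stat=float(f_stat),
        p_value=float(p_value),
        preferred="two" if p_value < alpha else "one",
        n_bins=n_bins,
    )


def mixture_likelihood_crosscheck(
    values: Sequence[float], seed: int = DEFAULT_SEED
) -> dict:
    """Raw-likelihood 1- vs 2-component mixture cross-check (BIC)."""
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    out = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed).fit(values)
        out[k] = {
            "bic": float(gm.bic(values)),
            "means": np.sort(gm.means_.ravel()).tolist(),
        }
    out["preferred"] = "two" if out[2]["bic"] < out[1]["bic"] else "one"
    return out


# ---------------------------------------------------------------------------
# K-means


def kmeans_two(
    values: Sequence[float], seed: int = DEFAULT_SEED, n_init: int = 25
) -> ClusterResult:
    """K-means with k=2 on one statistic; "S" is the higher-valued center.

    ``separation_p`` is the p-value of a one-way ANOVA of the values grouped
    by cluster label.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.ptp(values) == 0:
        raise StatsError("no separation: all values identical")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(
        values.reshape(-1, 1)
    )
    centers = km.cluster_centers_.ravel()
    hi = int(np.argmax(centers))
    labels = np.where(km.labels_ == hi, "S", "L")
    result_centers = {"S": float(centers[hi]), "L": float(centers[1 - hi])}
    mean_dist = {}
    for grp in ("S", "L"):
        vals = values[labels == grp]
        mean_dist[grp] = float(np.mean(np.abs(vals - result_centers[grp])))
    s_vals, l_vals = values[labels == "S"], values[labels == "L"]
    if s_vals.size == 0 or l_vals.size == 0:
        raise StatsError("degenerate clustering: one cluster empty")
    f, p = stats.f_oneway(s_vals, l_vals)
    return ClusterResult(
        labels=labels,
        centers=result_centers,
        mean_dist=mean_dist,
        separation_p=float(p),
        separation_f=float(f),
    )


def kmeans_two_2d(
    rows: pd.DataFrame,
    columns: tuple[str, str] = ("asl", "var"),
    seed: int = DEFAULT_SEED,
) -> ClusterResult:
    """Non-default 2-D variant clustering on two statistics jointly
    (z-scored); "S" is the cluster with the higher mean on the first column."""
    x = rows.loc[:, list(columns)].to_numpy(dtype=np.float64)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    km = KMeans(n_clusters=2, n_init=25, random_state=seed).fit(z)
    means0 = x[km.labels_ == 0, 0].mean()
    means1 = x[km.labels_ == 1, 0].mean()
    hi = 0 if means0 > means1 else 1
    labels = np.where(km.labels_ == hi, "S", "L")
    v = x[:, 0]
    f, p = stats.f_oneway(v[labels == "S"], v[labels == "L"])
    return ClusterResult(
        labels=labels,
        centers={"S": float(max(means0, means1)), "L": float(min(means0, means1))},
        mean_dist={
            g: float(np.mean(np.abs(v[labels == g] - (means0 if (hi == 0) == (g == "S") else means1))))
            for g in ("S", "L")
        },
        separation_p=float(p),
        separation_f=float(f),
    )


# ---------------------------------------------------------------------------
# Ward clustering on the seven intrinsic parameters


def ward_cluster_seven(
    rows: pd.DataFrame, reference_labels: Optional[Sequence[str]] = None
) -> dict:
    """Ward-linkage hierarchical clustering on the seven z-scored intrinsic
    parameters, cut at two clusters.

    When ``reference_labels`` (S/L from K-means) are given, agreement is
    reported as best-permutation accuracy and adjusted Rand index.
    """
    missing = [c for c in INTRINSIC_PARAMS if c not in rows.columns]
    if missing:
        raise StatsError(f"missing intrinsic parameter columns: {missing}")
    x = rows.loc[:, list(INTRINSIC_PARAMS)].to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise StatsError("missing values among the intrinsic parameters")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    lk = linkage(z, method="ward")
    labels = fcluster(lk, t=2, criterion="maxclust")  # 1/2
    out = {"labels": labels, "linkage": lk}
    if reference_labels is not None:
        ref = np.asarray(reference_labels)
        ref_bin = (ref == "S").astype(int)
        ward_bin = (labels == 1).astype(int)
        acc = np.mean(ref_bin == ward_bin)
        out["best_permutation_accuracy"] = float(max(acc, 1.0 - acc))
        out["ari"] = float(adjusted_rand_score(ref_bin, ward_bin))
    return out


# ---------------------------------------------------------------------------
# age-binned probabilities and fits


def age_group_probabilities(
    age_days: Sequence[float], labels: Sequence[str]
) -> list[AgeGroupProbability]:
    """Weekly fractions of S and L cells (bin = floor(age_days / 7))."""
    age_days = np.asarray(age_days, dtype=np.float64)
    labels = np.asarray(labels)
    weeks = np.floor(age_days / 7.0).astype(int)
    out = []
    for wk in AGE_BIN_WEEKS:
        sel = weeks == wk
        n = int(np.count_nonzero(sel))
        if n == 0:
            warnings.warn(f"empty age bin: week {wk}", stacklevel=2)
            continue
        p_s = float(np.mean(labels[sel] == "S"))
        out.append(
            AgeGroupProbability(age_bin_weeks=wk, n_cells=n, p_S=p_s, p_L=1.0 - p_s)
        )
    return out


def _adjusted_r2(y: np.ndarray, y_hat: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    dof = n - n_params
    if dof <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def _regression_f_p(y: np.ndarray, y_hat: np.ndarray, n_predictors: int) -> float:
    n = y.size
    df_res = n - (n_predictors + 1)
    if df_res <= 0:
        return float("nan")
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_reg = float(np.sum((y_hat - np.mean(y)) ** 2))
    if ss_res == 0:
        return 0.0
    f = (ss_reg / n_predictors) / (ss_res / df_res)
    return float(stats.f.sf(f, n_predictors, df_res))


def mean_variance_parabola(
    age_days: Sequence[float], values: Sequence[float]
) -> FitSummary:
    """Quadratic fit of per-age-bin variance on per-age-bin mean.

    Transition-age mixtures inflate the variance at intermediate means, which
    this parabola captures; reported with adjusted R^2 and an ANOVA p-value.
    """
    age_days = np.asarray(age_days, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    weeks = np.floor(age_days / 7.0).astype(int)
    means, variances = [], []
    for wk in sorted(set(weeks)):
        v = values[weeks == wk]
        if v.size < 2:
            continue
        means.append(float(np.mean(v)))
        variances.append(float(np.var(v, ddof=1)))
    means = np.asarray(means)
    variances = np.asarray(variances)
    if means.size < 3:
        raise StatsError(f"need >= 3 age bins with >= 2 cells, got {means.size}")
    coeffs = np.polyfit(means, variances, deg=2)
    y_hat = np.polyval(coeffs, means)
    flags = []
    p = _regression_f_p(variances, y_hat, n_predictors=2)
    if means.size == 3:
        flags.append("0 residual df: exact fit, p undefined")
        p = float("nan")
    return FitSummary(
        kind="parabolic",
        coefficients=coeffs,
        adjusted_r2=_adjusted_r2(variances, y_hat, n_params=3),
        p_value=p,
        n=int(means.size),
        flags=flags,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitSummary:
    """Ordinary least squares y ~ x with adjusted R^2 and slope p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise StatsError(f"insufficient data for a linear fit (n={x.size})")
    res = stats.linregress(x, y)
    y_hat = res.intercept + res.slope * x
    return FitSummary(
        kind="linear",
        coefficients=np.array([res.slope, res.intercept]),
        adjusted_r2=_adjusted_r2(y, y_hat, n_params=2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def group_correlations(
    rows: pd.DataFrame,
    labels: Sequence[str],
    stats_cols: Sequence[str] = ("asl", "var", "offset_norm"),
    predictor: str = "r_in",
) -> dict:
    """OLS of each gain statistic on input resistance, within the S group,
    within the L group, and pooled."""
    labels = np.asarray(labels)
    out: dict = {}
    for col in stats_cols:
        out[col] = {}
        for scope in ("S", "L", "pooled"):
            sel = np.ones(len(rows), dtype=bool) if scope == "pooled" else labels == scope
            sub = rows.loc[sel, [predictor, col]].dropna()
            out[col][scope] = linear_fit(
                sub[predictor].to_numpy(), sub[col].to_numpy()
            )
    return out
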