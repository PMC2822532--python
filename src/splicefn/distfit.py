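"""Frequency distributions of transcript–function relations and their models.

Three relation histograms are studied per organism: the number of distinct
FLs per TU, the number of distinct TUs per FL, and the number of splice
variants per TU. Each is a map ``m -> frequency`` over positive occurrence
counts. The bodies of these histograms follow an exponential decay
``a·exp(-b·m)`` or a standard discrete Pareto (power law), while heavy
right tails follow the generalized discrete Pareto (GDP) law

    f(m) = C / (m + b)^(k+1),   m = 1..J,   k > 0,  b > -1,

with C the normalization over the finite support (slope k+1; b = 0 gives
the standard discrete Pareto, and slope ~2 is the Zipf–Lotka regime). A
two-component mixture P = s·P1 + (1-s)·P2 splits the histogram at a
breakpoint m*: the low-complexity body below it, the heavy tail at and
above it.

Fitting follows the unweighted nonlinear-least-squares workflow of the
original goodness-of-fit analysis by default; a truncated-multinomial
maximum-likelihood mode is available for the GDP (better suited to sparse
tails and used by the parameter-recovery simulations).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

from .model import OrganismDataset


class FitError(RuntimeError):
    """Raised when a distribution fit is degenerate or fails to converge."""


# --------------------------------------------------------------------------
# Frequency distributions
# --------------------------------------------------------------------------


@dataclass
class FrequencyDistribution:
    """Histogram of occurrence counts: m (>=1) -> number of objects."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        self.counts = {int(m): int(f) for m, f in self.counts.items() if f > 0}
        if not self.counts:
            raise ValueError("frequency distribution must be nonempty")
        if any(m < 1 for m in self.counts):
            raise ValueError("all occurrence counts m must be >= 1")

    @property
    def M(self) -> int:
        """Total number of objects."""
        return sum(self.counts.values())

    @property
    def total_events(self) -> int:
        """Total number of events, sum of m * frequency."""
        return sum(m * f for m, f in self.counts.items())

    @property
    def J(self) -> int:
        """Maximum observed occurrence count."""
        return max(self.counts)

    @property
    def n1(self) -> int:
        """Number of singletons (objects occurring exactly once)."""
        return self.counts.get(1, 0)

    def values(self) -> np.ndarray:
        """Expand back to the object-level sample (sorted)."""
        return np.repeat(
            np.fromiter(sorted(self.counts), dtype=np.int64),
            [self.counts[m] for m in sorted(self.counts)],
        )

    def support(self, m_range: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Observed m values, optionally restricted to [lo, hi]."""
        ms = np.array(sorted(self.counts), dtype=np.int64)
        if m_range is not None:
            lo, hi = m_range
            ms = ms[(ms >= lo) & (ms <= hi)]
        return ms


def histogram(values) -> FrequencyDistribution:
    """Build a FrequencyDistribution from a list of positive integers."""
    values = list(values)
    if not values:
        raise ValueError("cannot build a histogram from an empty sample")
    if any(v < 1 for v in values):
        raise ValueError("all values must be >= 1")
    counts: dict[int, int] = {}
    for v in values:
        counts[int(v)] = counts.get(int(v), 0) + 1
    return FrequencyDistribution(counts)


def _annotated(dataset: OrganismDataset):
    if dataset.catalogue is None:
        raise ValueError("catalogue not built")
    tus = dataset.annotated_tus()
    if not tus:
        raise ValueError("dataset has no annotated TUs")
    return tus


def fls_per_tu(dataset: OrganismDataset) -> FrequencyDistribution:
    """Distribution of the number of distinct FLs per annotated TU."""
    return histogram([len(tu.fls) for tu in _annotated(dataset)])


def tus_per_fl(dataset: OrganismDataset) -> FrequencyDistribution:
    """Distribution of the number of distinct TUs attributed with each FL."""
    tus = _annotated(dataset)
    per_fl: dict[str, int] = {}
    for tu in tus:
        for fl in tu.fls:
            per_fl[fl] = per_fl.get(fl, 0) + 1
    return histogram(list(per_fl.values()))


def svs_per_tu(dataset: OrganismDataset) -> FrequencyDistribution:
    """Distribution of the number of splice variants per annotated TU."""
    return histogram([tu.n_sv for tu in _annotated(dataset)])


# --------------------------------------------------------------------------
# Generalized discrete Pareto pmf
# --------------------------------------------------------------------------


def _check_gdp(k: float, b: float) -> None:
    if not k > 0:
        raise ValueError("GDP shape k must be > 0")
    if not b > -1:
        raise ValueError("GDP shift b must be > -1")


def gdp_norm(k: float, b: float, J: Optional[int], m_min: int = 1) -> float:
    """Normalization constant C of the GDP pmf on m = m_min..J.

    With ``J=None`` the support is infinite and C comes from the Hurwitz
    zeta function: sum_{m>=m_min} (m+b)^-(k+1) = zeta(k+1, m_min+b).
    """
    _check_gdp(k, b)
    if J is None:
        return 1.0 / float(special.zeta(k + 1.0, m_min + b))
    m = np.arange(m_min, J + 1, dtype=float)
    return 1.0 / float(np.sum((m + b) ** (-(k + 1.0))))


def gdp_pmf(m, k: float, b: float = 0.0, J: Optional[int] = None,
            m_min: int = 1):
    """GDP probability f(m) = C/(m+b)^(k+1) on support m_min..J.

    *m* may be a scalar or array; ``J=None`` selects the infinite-support
    (Hurwitz-zeta) normalization.
    """
    C = gdp_norm(k, b, J, m_min)
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < m_min) or (J is not None and np.any(m_arr > J)):
        raise ValueError(f"m outside support [{m_min}, {J}]")
    out = C * (m_arr + b) ** (-(k + 1.0))
    return float(out) if np.isscalar(m) else out


# --------------------------------------------------------------------------
# Fitted-parameter containers
# --------------------------------------------------------------------------


@dataclass
class ExponentialParams:
    """Best-fit a·exp(-b·m) with standard errors and parameter p-values."""

    a: float
    b: float
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    rmse: float

    def predict(self, m):
        return self.a * np.exp(-self.b * np.asarray(m, dtype=float))

    def pmf(self, m, m_min: int = 1, J: int = None):
        """exp(-b·m) renormalized to a pmf on m_min..J."""
        mm = np.arange(m_min, J + 1, dtype=float)
        z = np.sum(np.exp(-self.b * mm))
        return np.exp(-self.b * np.asarray(m, dtype=float)) / z


@dataclass
class GDPParams:
    """Best-fit GDP parameters; slope of the power law is k+1."""

    k: float
    b: float
    J: int
    m_min: int = 1
    C: float = field(default=None)
    se_k: float = float("nan")
    se_b: float = float("nan")
    p_k: float = float("nan")
    p_b: float = float("nan")
    rmse: float = float("nan")

    def __post_init__(self) -> None:
        _check_gdp(self.k, self.b)
        if self.C is None:
            self.C = gdp_norm(self.k, self.b, self.J, self.m_min)

    def pmf(self, m):
        return gdp_pmf(m, self.k, self.b, self.J, self.m_min)


@dataclass
class MixtureFit:
    """Two-regime mixture: body component below the breakpoint, tail at/above.

    ``s`` is the fraction of objects in the body regime; the mixture pmf is
    s·P1 (renormalized on 1..breakpoint-1) + (1-s)·P2 (renormalized on
    breakpoint..J), which sums to 1 over 1..J by construction. A degenerate
    tail (fewer than 2 support points) leaves ``comp2`` as None and s = 1,
    with P1 renormalized over the full support.
    """

    s: float
    comp1: object
    comp2: Optional[GDPParams]
    breakpoint: int
    J: int

    @staticmethod
    def _comp1_pmf(comp, m, m_min, m_max):
        if isinstance(comp, GDPParams):
            return gdp_pmf(m, comp.k, comp.b, J=m_max, m_min=m_min)
        return comp.pmf(m, m_min=m_min, J=m_max)

    def pmf(self, m):
        m_arr = np.atleast_1d(np.asarray(m, dtype=float))
        out = np.empty_like(m_arr)
        if self.comp2 is None:
            out[:] = self._comp1_pmf(self.comp1, m_arr, 1, self.J)
        else:
            body = m_arr < self.breakpoint
            if np.any(body):
                out[body] = self.s * self._comp1_pmf(
                    self.comp1, m_arr[body], 1, self.breakpoint - 1
                )
            if np.any(~body):
                out[~body] = (1.0 - self.s) * self.comp2.pmf(m_arr[~body])
        return float(out[0]) if np.isscalar(m) else out


# --------------------------------------------------------------------------
# Fitters (estimator-style: construct with options, fit, read params_)
# --------------------------------------------------------------------------


def _param_stats(popt, pcov, residuals, n_params):
    n = len(residuals)
    dof = max(n - n_params, 1)
    rmse = float(np.sqrt(np.sum(residuals**2) / dof))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    pvals = []
    for est, s in zip(popt, se):
        if s > 0 and np.isfinite(s):
            t = abs(est) / s
            pvals.append(2.0 * stats.t.sf(t, dof))
        else:
            pvals.append(0.0 if abs(est) > 0 else 1.0)
    return se, pvals, rmse


class ExponentialFit:
    """Unweighted NLS fit of frequencies to a·exp(-b·m) over an m-range.

    Attributes after fit: ``params_`` (:class:`ExponentialParams`).
    """

    def __init__(self, m_range: Optional[tuple[int, int]] = None):
        self.m_range = m_range

    def fit(self, freq: FrequencyDistribution) -> "ExponentialFit":
        ms = freq.support(self.m_range)
        if len(ms) < 3:
            raise FitError("need >=3 distinct m values in the fit range")
        ys = np.array([freq.counts[m] for m in ms], dtype=float)
        # log-linear start values
        slope, intercept = np.polyfit(ms, np.log(ys), 1)
        b0 = max(-slope, 1e-3)
        a0 = max(float(np.exp(intercept)), 1e-9)
        try:
            popt, pcov = optimize.curve_fit(
                lambda m, a, b: a * np.exp(-b * m),
                ms.astype(float), ys,
                p0=[a0, b0], bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - optimizer failure
            raise FitError(f"exponential fit did not converge: {exc}") from exc
        a_hat, b_hat = popt
        if b_hat < 1e-6:
            raise FitError("decay rate at the b=0 boundary (flat frequencies)")
        resid = ys - a_hat * np.exp(-b_hat * ms)
        se, pvals, rmse = _param_stats(popt, pcov, resid, 2)
        self.params_ = ExponentialParams(
            a=float(a_hat), b=float(b_hat),
            se_a=float(se[0]), se_b=float(se[1]),
            p_a=float(pvals[0]), p_b=float(pvals[1]), rmse=rmse,
        )
        return self


class GDPFit:
    """Fit of a frequency distribution to the GDP law on an m-range.

    ``method="ls"`` (default) is unweighted NLS of the observed counts
    against A·f(m) where f is the GDP pmf normalized over the fit range and
    A the number of objects inside the range. ``method="mle"`` maximizes
    the truncated multinomial likelihood instead. ``fix_b_zero`` constrains
    the fit to the standard discrete Pareto.
    """

    def __init__(
        self,
        m_range: Optional[tuple[int, int]] = None,
        fix_b_zero: bool = False,
        method: str = "ls",
    ):
        if method not in ("ls", "mle"):
            raise ValueError("method must be 'ls' or 'mle'")
        self.m_range = m_range
        self.fix_b_zero = fix_b_zero
        self.method = method

    # internal: pmf over the fit support
    @staticmethod
    def _pmf(ms, k, b, m_lo, m_hi):
        grid = np.arange(m_lo, m_hi + 1, dtype=float)
        z = np.sum((grid + b) ** (-(k + 1.0)))
        return (np.asarray(ms, dtype=float) + b) ** (-(k + 1.0)) / z

    def fit(self, freq: FrequencyDistribution) -> "GDPFit":
        m_range = self.m_range or (1, freq.J)
        m_lo, m_hi = int(m_range[0]), int(m_range[1])
        ms = freq.support((m_lo, m_hi))
        min_pts = 2 if self.fix_b_zero else 3
        if len(ms) < min_pts:
            raise FitError(
                f"need >={min_pts} distinct m values in the fit range"
            )
        ys = np.array([freq.counts[m] for m in ms], dtype=float)
        A = float(ys.sum())
        # log-log slope start value: slope = -(k+1)
        ll_slope, _ = np.polyfit(np.log(ms), np.log(ys), 1)
        k0 = float(np.clip(-ll_slope - 1.0, 0.05, 50.0))
        if self.method == "ls":
            popt, pcov = self._fit_ls(ms, ys, A, k0, m_lo, m_hi)
        else:
            popt, pcov = self._fit_mle(ms, ys, k0, m_lo, m_hi)
        if self.fix_b_zero:
            k_hat, b_hat = float(popt[0]), 0.0
        else:
            k_hat, b_hat = float(popt[0]), float(popt[1])
        model = A * self._pmf(ms, k_hat, b_hat, m_lo, m_hi)
        resid = ys - model
        se, pvals, rmse = _param_stats(popt, pcov, resid, len(popt))
        self.params_ = GDPParams(
            k=k_hat, b=b_hat, J=m_hi, m_min=m_lo,
            se_k=float(se[0]),
            se_b=float(se[1]) if not self.fix_b_zero else 0.0,
            p_k=float(pvals[0]),
            p_b=float(pvals[1]) if not self.fix_b_zero else float("nan"),
            rmse=rmse,
        )
        return self

    def _fit_ls(self, ms, ys, A, k0, m_lo, m_hi):
        if self.fix_b_zero:
            f = lambda m, k: A * self._pmf(m, k, 0.0, m_lo, m_hi)
            p0, lo, hi = [k0], [1e-9], [np.inf]
        else:
            f = lambda m, k, b: A * self._pmf(m, k, b, m_lo, m_hi)
            p0, lo, hi = [k0, 0.0], [1e-9, -1.0 + 1e-9], [np.inf, np.inf]
        try:
            return optimize.curve_fit(
                f, ms.astype(float), ys, p0=p0, bounds=(lo, hi), maxfev=50000
            )
        except RuntimeError as exc:
            raise FitError(f"GDP least-squares fit did not converge: {exc}") from exc

    def _fit_mle(self, ms, ys, k0, m_lo, m_hi):
        def nll(theta):
            k = theta[0]
            b = 0.0 if self.fix_b_zero else theta[1]
            p = self._pmf(ms, k, b, m_lo, m_hi)
            return -float(np.sum(ys * np.log(p)))

        x0 = [k0] if self.fix_b_zero else [k0, 0.5]
        bounds = [(1e-6, None)] + ([] if self.fix_b_zero else [(-1 + 1e-6, None)])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if not res.success:
            raise FitError(
                f"GDP maximum-likelihood fit did not converge: {res.message} "
                f"(nit={res.nit})"
            )
        cov = _numerical_cov(nll, res.x)
        return res.x, cov


def _numerical_cov(nll, x, eps: float = 1e-4) -> np.ndarray:
    """Covariance from the finite-difference Hessian of a neg-log-likelihood."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = (
                nll(x + ei + ej) - nll(x + ei - ej)
                - nll(x - ei + ej) + nll(x - ei - ej)
            ) / (4 * eps * eps)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full((n, n), np.nan)


# thin functional wrappers --------------------------------------------------


def fit_exponential(
    freq: FrequencyDistribution, m_range: Optional[tuple[int, int]] = None
) -> ExponentialParams:
    return ExponentialFit(m_range).fit(freq).params_


def fit_gdp(
    freq: FrequencyDistribution,
    m_range: Optional[tuple[int, int]] = None,
    fix_b_zero: bool = False,
    method: str = "ls",
) -> GDPParams:
    return GDPFit(m_range, fix_b_zero=fix_b_zero, method=method).fit(freq).params_


DEFAULT_BREAKPOINT = 10  # heavy tail observed at >9 splice variants per TU


def fit_mixture(
    freq: FrequencyDistribution,
    breakpoint: int = DEFAULT_BREAKPOINT,
    comp1_kind: str = "exponential",
    comp2_kind: str = "gdp",
    method: str = "ls",
) -> MixtureFit:
    """Two-regime mixture fit with the split at ``breakpoint``.

    Component 1 (exponential or GDP) is fitted on m < breakpoint, component
    2 (GDP) on m >= breakpoint; the weight s is the fraction of objects in
    the body regime. If the tail has fewer than two support points the tail
    component is left unset (s = 1), as happens when the breakpoint equals
    the maximum observed count.
    """
    J = freq.J
    breakpoint = int(breakpoint)
    if not 2 <= breakpoint <= J:
        raise ValueError(f"breakpoint must lie in [2, {J}]")
    if comp2_kind != "gdp":
        raise ValueError("tail component must be 'gdp'")
    body_range = (1, breakpoint - 1)
    tail_range = (breakpoint, J)
    body_ms = freq.support(body_range)
    if len(body_ms) < 2:
        raise FitError("body regime has <2 support points")
    if comp1_kind == "exponential":
        comp1 = fit_exponential(freq, body_range)
    elif comp1_kind == "gdp":
        comp1 = fit_gdp(freq, body_range, method=method)
    else:
        raise ValueError(f"unknown component kind {comp1_kind!r}")
    tail_ms = freq.support(tail_range)
    if len(tail_ms) < 2:
        return MixtureFit(s=1.0, comp1=comp1, comp2=None, breakpoint=breakpoint, J=J)
    comp2 = fit_gdp(freq, tail_range, method=method)
    body_mass = sum(freq.counts[m] for m in body_ms)
    s = body_mass / freq.M
    return MixtureFit(s=float(s), comp1=comp1, comp2=comp2,
                      breakpoint=breakpoint, J=J)


# --------------------------------------------------------------------------
# Descriptive statistics
# --------------------------------------------------------------------------


@dataclass
class DescriptiveRow:
    """One row of relation-level descriptive statistics.

    ``ratio`` is events per object (e.g. FLs per TU), ``n1``/``p1`` count
    and percentage of singletons, ``skewness`` the adjusted Fisher–Pearson
    sample skewness (G1) of the object-level occurrence counts.
    """

    total_events: int
    total_objects: int
    ratio: float
    max_m: int
    n1: int
    p1: float
    skewness: float


def describe(freq: FrequencyDistribution) -> DescriptiveRow:
    vals = freq.values()
    if np.all(vals == vals[0]):
        skew = 0.0  # convention for constant samples
    else:
        skew = float(stats.skew(vals, bias=False))
    return DescriptiveRow(
        total_events=freq.total_events,
        total_objects=freq.M,
        ratio=freq.total_events / freq.M,
        max_m=freq.J,
        n1=freq.n1,
        p1=100.0 * freq.n1 / freq.M,
        skewness=skew,
    )


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------


def write_histogram(freq: FrequencyDistribution, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["m", "frequency"])
        for m in sorted(freq.counts):
            w.writerow([m, freq.counts[m]])


def write_fit_report(fit: MixtureFit, path) -> None:
    """Mixture fit report: parameter, estimate, SE, p-value, rmse per row."""
    rows = [("s", fit.s, "", "", "")]
    c1 = fit.comp1
    if isinstance(c1, ExponentialParams):
        rows += [
            ("P1.a", c1.a, c1.se_a, c1.p_a, c1.rmse),
            ("P1.b", c1.b, c1.se_b, c1.p_b, c1.rmse),
        ]
    else:
        rows += [
            ("P1.k", c1.k, c1.se_k, c1.p_k, c1.rmse),
            ("P1.b", c1.b, c1.se_b, c1.p_b, c1.rmse),
        ]
    if fit.comp2 is None:
        rows += [("P2.k", "NAN", "", "", ""), ("P2.b", "NAN", "", "", "")]
    else:
        c2 = fit.comp2
        rows += [
            ("P2.k", c2.k, c2.se_k, c2.p_k, c2.rmse),
            ("P2.b", c2.b, c2.se_b, c2.p_b, c2.rmse),
        ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["parameter", "estimate", "std_error", "p_value", "rmse"])
        for row in rows:
            w.writerow(row)
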