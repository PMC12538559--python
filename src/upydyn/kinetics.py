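"""Rare-event kinetics from infrequent well-tempered metadynamics.

The unbiased transition time of a biased run is recovered by rescaling the
simulation clock with the running exponential of the deposited bias,

    t = sum_i dt_i exp(beta V(t_i)),

the discrete form of t = t_MetaD <exp(beta V)>.  The characteristic
timescale tau of an ensemble of such times is extracted by least-squares
fitting of the empirical CDF with the Poisson-process form
P(t) = 1 - exp(-t / tau); a Kolmogorov-Smirnov test of the sample against
Exp(tau_hat) is reported as the standard validity diagnostic (reported,
never used to drop runs).  Free-energy surfaces are recovered from biased
CV samples by exponential reweighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .model import BiasTrace

log = logging.getLogger("upydyn")


# ---------------------------------------------------------------------------
# Time rescaling
# ---------------------------------------------------------------------------

def unbiased_time(trace: BiasTrace, t_transition: float) -> float:
    """Rescale a biased transition time to the unbiased clock.

    The bias is treated as a left-continuous step function (constant between
    deposition rows): t = sum over rows of dt_i * exp(beta V_i), with the
    final partial interval up to ``t_transition``.  For V = 0 this returns
    ``t_transition`` exactly.
    """
    t = trace.times
    v = trace.v_bias
    if t_transition < t[0]:
        raise ValueError("t_transition precedes the trace")
    # the bias extends one deposition interval past the last row (a single
    # row means no deposition happened before the transition)
    max_t = t[-1] + (t[-1] - t[-2]) if len(t) > 1 else np.inf
    if t_transition > max_t + 1e-9:
        raise ValueError(
            f"t_transition {t_transition} beyond trace end {t[-1]}")
    beta = trace.beta
    # interval i spans [t_i, t_{i+1}) with bias v_i
    ends = np.minimum(np.append(t[1:], np.inf), t_transition)
    starts = np.minimum(t, t_transition)
    dt = np.maximum(ends - starts, 0.0)
    return float(np.sum(dt * np.exp(beta * v)))


# ---------------------------------------------------------------------------
# Poisson CDF fitting
# ---------------------------------------------------------------------------

@dataclass
class TransitionEnsemble:
    """Unbiased transition times (ps) with per-run censoring flags."""

    times: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.censored is None:
            self.censored = np.zeros(len(self.times), dtype=bool)
        else:
            self.censored = np.asarray(self.censored, bool)
        if np.any(self.times[~self.censored] <= 0):
            raise ValueError("transition times must be positive")
        if not np.any(~self.censored):
            raise ValueError("need at least one uncensored transition time")

    @property
    def uncensored(self) -> np.ndarray:
        return self.times[~self.censored]


@dataclass
class CDFFit:
    """Poisson-CDF fit: tau, its LS standard error, and goodness stats."""

    tau: float                   # ps
    tau_se: float
    tau_mle: float               # mean of uncensored times (diagnostic)
    n: int
    n_censored: int
    ecdf_times: np.ndarray
    ecdf_values: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    degenerate: bool = False
    low_n: bool = False

    def cdf(self, t: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(t, float) / self.tau)


def fit_poisson_cdf(ensemble: TransitionEnsemble | np.ndarray) -> CDFFit:
    """Fit P(t) = 1 - exp(-t/tau) to the empirical CDF of transition times.

    The ECDF uses plotting positions k/(n+1); censored runs are excluded
    from the fit but counted in the report.  The fit is performed on times
    scaled by their mean so tau is exactly scale-equivariant.
    """
    if not isinstance(ensemble, TransitionEnsemble):
        ensemble = TransitionEnsemble(np.asarray(ensemble, float))
    times = np.sort(ensemble.uncensored)
    n = len(times)
    n_cens = int(ensemble.censored.sum())
    ecdf = np.arange(1, n + 1) / (n + 1.0)
    scale = times.mean()
    degenerate = bool(n > 0 and np.ptp(times) == 0)
    low_n = n < 5
    if degenerate or n == 1:
        tau, tau_se = float(times[0]), np.nan
    else:
        popt, pcov = curve_fit(lambda t, tau: 1.0 - np.exp(-t / tau),
                               times / scale, ecdf, p0=[1.0])
        tau = float(popt[0] * scale)
        tau_se = float(np.sqrt(pcov[0, 0]) * scale)
    if low_n and not degenerate:
        log.warning("fewer than 5 uncensored times: tau is a point estimate")
    ks = stats.kstest(times, "expon", args=(0, tau))
    return CDFFit(tau=tau, tau_se=tau_se, tau_mle=float(times.mean()), n=n,
                  n_censored=n_cens, ecdf_times=times, ecdf_values=ecdf,
                  ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
                  degenerate=degenerate, low_n=low_n)


@dataclass
class TimescaleComparison:
    ratio: float                 # tau_b / tau_a
    log10_ratio: float
    log10_ratio_se: float


def compare_timescales(fit_a: CDFFit, fit_b: CDFFit) -> TimescaleComparison:
    """tau_b / tau_a with uncertainty propagated from the fit covariances."""
    for f in (fit_a, fit_b):
        if f.degenerate or not np.isfinite(f.tau) or f.tau <= 0:
            raise ValueError("cannot compare degenerate fits")
    ratio = fit_b.tau / fit_a.tau
    rel = np.sqrt((fit_a.tau_se / fit_a.tau) ** 2 + (fit_b.tau_se / fit_b.tau) ** 2)
    return TimescaleComparison(ratio=float(ratio),
                               log10_ratio=float(np.log10(ratio)),
                               log10_ratio_se=float(rel / np.log(10.0)))


# ---------------------------------------------------------------------------
# FES reweighting
# ---------------------------------------------------------------------------

@dataclass
class FESGrid:
    """Free energy on a CV grid, min-shifted to 0; unsampled cells are NaN."""

    edges: list[np.ndarray]
    free_energy: np.ndarray      # kJ/mol; NaN where unsampled
    counts: np.ndarray
    kt: float
    c_t_mode: str
    cv_names: tuple[str, ...] = ()

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[:-1] + e[1:]) for e in self.edges]

    @property
    def sampled(self) -> np.ndarray:
        return self.counts > 0


def reweight_fes(cv_samples: np.ndarray, v_bias: np.ndarray, kt: float,
                 edges: list[np.ndarray] | np.ndarray,
                 c_t: np.ndarray | None = None,
                 cv_names: tuple[str, ...] = ()) -> FESGrid:
    """Reweight biased CV samples onto a free-energy grid.

    Sample weights are w = exp((V - c_t)/kT) when an explicit ``c_t`` column
    is available; otherwise exp(V/kT) with a constant gauge shift (the
    static-bias approximation appropriate for a converged tempered bias;
    any constant offset cancels in the min-shifted F).  F = -kT ln(sum w)
    per cell, min-shifted to 0; empty cells are NaN, flagged via counts.
    """
    cv = np.asarray(cv_samples, float)
    if cv.ndim == 1:
        cv = cv[:, None]
    v = np.asarray(v_bias, float)
    if isinstance(edges, np.ndarray) and edges.ndim == 1:
        edges = [edges]
    edges = [np.asarray(e, float) for e in edges]
    if len(edges) != cv.shape[1]:
        raise ValueError("one edge array per CV dimension required")
    if c_t is not None:
        arg = (v - np.asarray(c_t, float)) / kt
        mode = "explicit-c_t"
    else:
        arg = v / kt
        mode = "static-bias"
    arg = arg - arg.max()                     # gauge shift for stability
    w = np.exp(arg)
    hist_w, _ = np.histogramdd(cv, bins=edges, weights=w)
    hist_n, _ = np.histogramdd(cv, bins=edges)
    with np.errstate(divide="ignore"):
        F = -kt * np.log(hist_w)
    F[hist_n == 0] = np.nan
    F -= np.nanmin(F)
    return FESGrid(edges=edges, free_energy=F, counts=hist_n, kt=kt,
                   c_t_mode=mode, cv_names=tuple(cv_names))


def fes_from_trace(trace: BiasTrace, edges, kt: float | None = None) -> FESGrid:
    """Convenience: reweight directly from a BiasTrace."""
    kt = kt if kt is not None else 1.0 / trace.beta
    return reweight_fes(trace.cv_values, trace.v_bias, kt, edges,
                        c_t=trace.c_t, cv_names=trace.cv_names)
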