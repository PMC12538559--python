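"""Dynamic-domain classification and exchange-event detection.

Pooled tauSOAP values are clustered with a 1-D Gaussian mixture (k = 3);
components sorted by mean map onto the three monomer states:

    lowest mean  -> III (travelling: detached centers, static-looking
                         neighborhoods, tauSOAP near 0)
    middle mean  -> I   (stacked bound: the dominant, moderately
                         fluctuating state)
    highest mean -> II  (stacked unbound: strongest neighborhood
                         reconfiguration)

Transitions between assigned domains define the exchange events:
I -> II or I -> III is a defect formation, II -> I or III -> I a
self-healing, II <-> III an exchange of defect configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

log = logging.getLogger("upydyn")

DOMAIN_BY_RANK = ("III", "I", "II")   # ascending component mean


# ---------------------------------------------------------------------------
# KDE
# ---------------------------------------------------------------------------

def kde_density(samples: np.ndarray, grid: np.ndarray,
                bandwidth: str | float = "scott",
                ) -> np.ndarray:
    """Gaussian-kernel density of ``samples`` evaluated on ``grid``.

    Degenerate (zero-variance) samples produce a narrow Gaussian spike at
    the repeated value, with a warning.
    """
    samples = np.asarray(samples, float).ravel()
    if len(samples) < 2:
        raise ValueError("KDE needs at least 2 samples")
    if np.ptp(samples) == 0:
        log.warning("zero-variance KDE input: returning delta-like curve")
        width = max(1e-3 * max(abs(samples[0]), 1.0), 1e-12)
        return stats.norm.pdf(grid, loc=samples[0], scale=width)
    kde = stats.gaussian_kde(samples, bw_method=bandwidth)
    return kde(grid)


# ---------------------------------------------------------------------------
# GMM domains
# ---------------------------------------------------------------------------

@dataclass
class DomainModel:
    """Fitted 1-D Gaussian mixture with rank-based domain labels."""

    means: np.ndarray           # sorted ascending
    variances: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...]     # domain label per sorted component
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "variances": self.variances.tolist(),
                "weights": self.weights.tolist(), "labels": list(self.labels),
                "degenerate": self.degenerate}

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Maximum-posterior component index (into the sorted order)."""
        v = np.asarray(values, float).ravel()[:, None]
        logp = (np.log(self.weights)[None, :]
                - 0.5 * np.log(2 * np.pi * self.variances)[None, :]
                - 0.5 * (v - self.means[None, :]) ** 2 / self.variances[None, :])
        return np.argmax(logp, axis=1).reshape(np.shape(values))

    def predict_domains(self, values: np.ndarray) -> np.ndarray:
        comp = self.predict(values)
        lab = np.array(self.labels, dtype=object)
        return lab[comp]


def fit_domains(tau_values, k: int = 3, seed: int = 0, n_init: int = 10,
                ) -> DomainModel:
    """EM fit of a k-component 1-D Gaussian mixture over pooled tauSOAP.

    Components are sorted by mean and labeled III < I < II (for k = 3).
    Degenerate fits (vanishing variance) are retried with a variance floor.
    """
    vals = np.asarray(getattr(tau_values, "values", tau_values), float).ravel()
    if len(vals) < 10 * k:
        raise ValueError(f"need at least {10 * k} pooled values to fit {k} domains")
    degenerate = False
    if np.ptp(vals) == 0:
        log.warning("all pooled values identical: degenerate domain model")
        v = float(np.var(vals)) + 1e-12
        return DomainModel(means=np.full(k, vals[0]), variances=np.full(k, v),
                           weights=np.full(k, 1.0 / k),
                           labels=DOMAIN_BY_RANK if k == 3
                           else tuple(f"C{i}" for i in range(k)),
                           degenerate=True)
    # variance floor: sparse extreme clusters (e.g. the static travelling
    # band piling up at 0) may otherwise collapse below machine precision
    reg = max(1e-6, 1e-6 * float(np.var(vals)))
    # deterministic quantile-spread init: random/k-means restarts tend to
    # split the dominant mid band instead of seeding the sparse low/high bands
    q = np.quantile(vals, np.linspace(0.02, 0.98, k))
    ptp = np.ptp(vals)
    # the lowest band (static/travelling centers) is near-degenerate by
    # construction: seed it tight so it locks onto the spike when present
    var0 = np.full(k, (ptp / 12.0) ** 2)
    var0[0] = (ptp / 60.0) ** 2
    if k > 2:
        # middle-heavy weights: the dominant band sits between sparse extremes
        w0 = np.full(k, 0.8 / (k - 2))
        w0[0] = w0[-1] = 0.1
    else:
        w0 = np.full(k, 1.0 / k)
    gm_q = GaussianMixture(n_components=k, random_state=seed, reg_covar=reg,
                           means_init=q[:, None],
                           precisions_init=(1.0 / var0)[:, None, None],
                           weights_init=w0)
    gm_q.fit(vals[:, None])
    if gm_q.converged_:
        gm = gm_q
    else:
        # fall back on k-means-seeded random restarts
        log.warning("quantile-spread EM did not converge; using restart fit")
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed,
                             reg_covar=reg)
        gm.fit(vals[:, None])
        if not gm.converged_:
            log.warning("GMM EM did not converge within the iteration budget")
            degenerate = True
    order = np.argsort(gm.means_.ravel(), kind="stable")
    if k == 3:
        labels = DOMAIN_BY_RANK
    else:
        labels = tuple(f"C{i}" for i in range(k))
    return DomainModel(means=gm.means_.ravel()[order],
                       variances=gm.covariances_.ravel()[order],
                       weights=gm.weights_.ravel()[order],
                       labels=labels, degenerate=degenerate)


def _merge_short_runs(seq: np.ndarray, dwell_min: int) -> np.ndarray:
    """Merge runs shorter than ``dwell_min`` into the preceding state
    (leading short runs take the following state). Iterates to stability."""
    seq = np.asarray(seq, dtype=object).copy()
    if dwell_min <= 1:
        return seq
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(seq) + 1):
            if i == len(seq) or seq[i] != seq[start]:
                runs.append((start, i))
                start = i
        if len(runs) < 2:
            break
        for ri, (s, e) in enumerate(runs):
            if e - s < dwell_min:
                if ri > 0:
                    repl = seq[runs[ri - 1][1] - 1]
                else:
                    repl = seq[runs[ri + 1][0]]
                if seq[s] != repl:
                    seq[s:e] = repl
                    changed = True
                    break
    return seq


def assign_domains(tau_values, model: DomainModel, dwell_min: int = 5,
                   ) -> np.ndarray:
    """Per-center per-frame domain labels with flicker suppression.

    ``tau_values``: (n_frames, M) tauSOAP values (or a TauSOAPSeries).
    Runs shorter than ``dwell_min`` frames are merged into the flanking
    state.
    """
    vals = np.asarray(getattr(tau_values, "values", tau_values), float)
    labels = model.predict_domains(vals)
    if labels.ndim == 1:
        return _merge_short_runs(labels, dwell_min)
    out = np.empty_like(labels)
    for i in range(labels.shape[1]):
        out[:, i] = _merge_short_runs(labels[:, i], dwell_min)
    return out


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

_EVENT_TYPE = {
    ("I", "II"): "defect", ("I", "III"): "defect",
    ("II", "I"): "self-heal", ("III", "I"): "self-heal",
    ("II", "III"): "exchange", ("III", "II"): "exchange",
}


@dataclass
class EventLog:
    """Domain-transition events: (center, frame, from, to, type)."""

    events: list[tuple[int, int, str, str, str]]
    dwell_min: int = 1

    def counts(self) -> dict[str, int]:
        out = {"defect": 0, "self-heal": 0, "exchange": 0}
        for *_, t in self.events:
            out[t] += 1
        return out

    def counts_by_class(self, tip_labels: dict[int, str]) -> dict[str, dict[str, int]]:
        out = {"tip": {"defect": 0, "self-heal": 0, "exchange": 0},
               "backbone": {"defect": 0, "self-heal": 0, "exchange": 0}}
        for center, _, _, _, t in self.events:
            out[tip_labels[center]][t] += 1
        return out


def detect_events(labels: np.ndarray, center_ids: list[int] | None = None,
                  dwell_min: int = 1) -> EventLog:
    """Extract defect / self-heal / exchange events from domain labels.

    ``labels``: (n_frames, M) array of 'I'/'II'/'III' strings; an event is
    recorded at the frame where the new domain first holds.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.ndim == 1:
        labels = labels[:, None]
    n_f, M = labels.shape
    ids = center_ids if center_ids is not None else list(range(M))
    events = []
    for c in range(M):
        for f in range(1, n_f):
            a, b = labels[f - 1, c], labels[f, c]
            if a != b:
                events.append((ids[c], f, a, b, _EVENT_TYPE[(a, b)]))
    return EventLog(events=events, dwell_min=dwell_min)


# ---------------------------------------------------------------------------
# HB - SASA correlation
# ---------------------------------------------------------------------------

def _sigmoid(x, a, x0, w, b):
    return a / (1.0 + np.exp((x - x0) / w)) + b


@dataclass
class HBSasaCorrelation:
    spearman_rho: float
    spearman_p: float
    fit_params: dict | None      # a, x0, w, b of the decreasing sigmoid
    fit_rmse: float | None
    undefined: bool = False


def correlate_hb_sasa(hb_mean: np.ndarray, sasa_mean: np.ndarray,
                      ) -> HBSasaCorrelation:
    """Spearman correlation and decreasing-sigmoid fit of time-averaged
    N_HB-dim0 against per-monomer SASA.

    The fitted curve is y = a / (1 + exp((x - x0)/w)) + b: a bounded
    decreasing step between the intact (4 H-bonds) and ruptured (0) plateaus.
    """
    x = np.asarray(sasa_mean, float)
    y = np.asarray(hb_mean, float)
    if len(x) < 4:
        raise ValueError("need at least 4 monomers")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant input: HB-SASA correlation undefined")
        return HBSasaCorrelation(np.nan, np.nan, None, None, undefined=True)
    rho, p = stats.spearmanr(y, x)
    try:
        p0 = [np.ptp(y), float(np.median(x)), max(np.ptp(x) / 5.0, 1e-6),
              float(np.min(y))]
        popt, _ = curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
        resid = y - _sigmoid(x, *popt)
        fit = dict(zip(("a", "x0", "w", "b"), (float(v) for v in popt)))
        rmse = float(np.sqrt(np.mean(resid ** 2)))
    except RuntimeError:
        fit, rmse = None, None
    return HBSasaCorrelation(float(rho), float(p), fit, rmse)
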