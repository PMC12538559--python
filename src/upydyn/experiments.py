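"""End-to-end synthetic experiments exercising the full pipeline.

Each function sets up the synthetic study conditions (stack sizes, planted
rates, ensemble sizes), runs the corresponding estimator, and returns the
measured quantities together with the problem size.  They are shared by the
numbered analysis drivers, the acceptance script, and the test suite, so
every reported number is produced by one code path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import domains, kinetics, metrics, synthetic
from .descriptors import SOAPSpec, lens_series, tau_soap_series
from .model import TipSpec, label_tips
from .synthetic import SyntheticParams, build_stack, make_bundle, simulate_exchange


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def tau_recovery_experiment(seed: int = 0, n_replicates: int = 200,
                            n_runs: int = 30, true_tau: float = 1e6) -> dict:
    """Fit tau on ``n_replicates`` ensembles of n_runs draws from Exp(tau*).

    Measures the bias (median signed relative error), the dispersion
    (median absolute relative error), and the factor-2 coverage of the
    CDF-fit estimator.
    """
    rng = np.random.default_rng(seed)
    rel = np.empty(n_replicates)
    for i in range(n_replicates):
        t = rng.exponential(true_tau, n_runs)
        fit = kinetics.fit_poisson_cdf(t)
        rel[i] = fit.tau / true_tau - 1.0
    within2 = np.mean((rel > -0.5) & (rel < 1.0))
    return {
        "median_rel_err": float(np.median(rel)),
        "median_abs_rel_err": float(np.median(np.abs(rel))),
        "frac_within_factor2": float(within2),
        "n": n_replicates,
    }


def timescale_ratio_experiment(seed: int = 0, tau_fast: float = 1e2,
                               ratio: float = 1e7, n_runs: int = 30,
                               bias_rate: float = 1.5, pace: float = 10.0) -> dict:
    """Tip-vs-backbone contrast on synthetic biased runs.

    Two ensembles with planted rates differing by ``ratio`` are generated as
    well-tempered-style staircase traces, each run's unbiased time is
    reconstructed by time rescaling, and the fitted tau ratio is compared
    with the planted one.
    """
    tau_slow = tau_fast * ratio
    fits = []
    for j, tau in enumerate((tau_fast, tau_slow)):
        runs = synthetic.sample_biased_transitions(
            tau, bias_rate=bias_rate, pace=pace, n_runs=n_runs,
            seed=seed * 2 + j + 1)
        times = [kinetics.unbiased_time(r.trace, r.t_transition) for r in runs]
        fits.append(kinetics.fit_poisson_cdf(np.array(times)))
    cmp = kinetics.compare_timescales(fits[0], fits[1])
    recon_err = max(
        abs(kinetics.unbiased_time(r.trace, r.t_transition) - r.unbiased_time)
        / r.unbiased_time
        for r in synthetic.sample_biased_transitions(
            tau_fast, bias_rate, pace, 10, seed=seed + 7)
    )
    return {
        "tau_fast": fits[0].tau, "tau_slow": fits[1].tau,
        "log10_ratio": cmp.log10_ratio, "planted_log10_ratio": float(np.log10(ratio)),
        "max_rescale_rel_err": float(recon_err),
        "n": n_runs,
    }


def double_well(s: np.ndarray) -> np.ndarray:
    """Reference double-well free energy (kJ/mol) on s in [0, 4]:
    minima near s = 0.6 and s = 3.4, ~12 kJ/mol barrier."""
    return 12.0 * ((s - 2.0) ** 2 / 1.96 - 1.0) ** 2


def fes_recovery_experiment(seed: int = 0, n_samples: int = 100_000,
                            kt: float = 2.478) -> dict:
    """Recover a known double-well FES from samples biased by a known V.

    Samples are drawn from p(s) prop. exp(-(F* + V)/kT) on a fine grid by
    inverse-CDF sampling (the independent oracle), then reweighted with
    w = exp(V/kT); the RMSE is measured over sampled cells against F*.
    """
    rng = np.random.default_rng(seed)
    fine = np.linspace(0.0, 4.0, 4001)
    F = double_well(fine)
    V = -0.8 * F                     # partially compensating, metadynamics-like
    p = np.exp(-(F + V) / kt)
    p /= p.sum()
    idx = rng.choice(len(fine), size=n_samples, p=p)
    s = fine[idx] + rng.uniform(-0.0005, 0.0005, n_samples)
    edges = np.linspace(0.0, 4.0, 81)
    grid = kinetics.reweight_fes(s, V[idx], kt, edges)
    centers = grid.centers[0]
    ref = double_well(centers)
    ref = ref - ref[grid.sampled].min()
    # compare where sampling is meaningful
    mask = grid.sampled & (grid.counts > 5)
    rmse = float(np.sqrt(np.nanmean((grid.free_energy[mask] - ref[mask]) ** 2)))
    return {"rmse": rmse, "n": n_samples, "n_cells": int(mask.sum())}


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def rdf_experiment(n_dimers: int = 20, bin_width: float = 0.02) -> dict:
    """RDF peak positions on the ideal frame-0 lattice of a 20D stack."""
    params = SyntheticParams(n_dimers=n_dimers)
    topo, frame0 = build_stack(params)
    centers = np.stack([frame0[m.atoms[0]] for m in topo.monomers])
    r, g = metrics.rdf_per_monomer(centers[None], synthetic.default_box(params),
                                   r_max=1.2, bin_width=bin_width)
    peaks = metrics.rdf_peaks(r, g, min_height=1e-6, k=2)
    return {"first_peak": float(peaks[0]), "second_peak": float(peaks[1]),
            "bin_width": bin_width, "n": 2 * n_dimers}


def bundle_ap_experiment(spacing_far: float = 10.0, spacing_contact: float = 0.8,
                         n_dimers: int = 5) -> dict:
    """Aggregation propensity of a 3-stack bundle, far apart vs at contact."""
    params = SyntheticParams(n_dimers=n_dimers)
    out = {}
    for name, spacing in (("far", spacing_far), ("contact", spacing_contact)):
        topo, frame0 = make_bundle(3, params, spacing)
        out[f"ap_{name}"] = metrics.aggregation_propensity(frame0, topo)
    out["n"] = 3 * 2 * n_dimers
    return out


# ---------------------------------------------------------------------------
# Domains / events on KMC ground truth
# ---------------------------------------------------------------------------

def default_kmc_params(seed: int = 0, n_dimers: int = 20,
                       n_frames: int = 400) -> SyntheticParams:
    """Study conditions for the exchange-dynamics experiments: tip-dominated
    rupture, occasional sliding and rebinding, decorative thermal jitter."""
    return SyntheticParams(
        n_dimers=n_dimers, k_tip=1e-3, k_back=0.0, k_slide=5e-4,
        k_rebind=1e-4, noise_sigma=0.01, wobble_unbound=8.0,
        dt_frame=50.0, n_frames=n_frames, seed=seed)


_GT_TO_DOMAIN = {"bound": "I", "stacked-unbound": "II", "travelling": "III"}


def domain_recovery_experiment(seed: int = 0, n_dimers: int = 20,
                               n_frames: int = 400, dwell_min: int = 10,
                               soap_spec: SOAPSpec | None = None) -> dict:
    """KMC trajectory -> tauSOAP -> GMM domains vs planted ground truth.

    Measures the adjusted Rand index between assigned and true per-frame
    states, the backbone defect-event count (zero when k_back = 0), and the
    tauSOAP class means (expected ordering: travelling < bound < unbound).
    """
    params = default_kmc_params(seed, n_dimers, n_frames)
    topo, frame0 = build_stack(params)
    traj, gt = simulate_exchange(topo, frame0, params)
    spec = soap_spec or SOAPSpec()
    tau = tau_soap_series(traj, topo, spec)
    model = domains.fit_domains(tau, k=3, seed=seed)
    assigned = domains.assign_domains(tau, model, dwell_min=dwell_min)
    truth = gt.labels[1:]         # tauSOAP starts at frame 1
    true_dom = np.vectorize(_GT_TO_DOMAIN.get)(truth)
    from sklearn.metrics import adjusted_rand_score
    ari = adjusted_rand_score(true_dom.ravel(), assigned.ravel())
    # event localization uses the dynamic end region: end dimers and their
    # first neighbors (tips/subtips), whose environments share the tip dynamics
    tips = label_tips(topo, TipSpec(2))
    log_ = domains.detect_events(assigned, center_ids=tau.monomer_ids,
                                 dwell_min=dwell_min)
    by_class = log_.counts_by_class(tips)
    # stratified tauSOAP means by ground-truth state
    means = {}
    for state, dom in _GT_TO_DOMAIN.items():
        m = truth == state
        means[state] = float(tau.values[m].mean()) if m.any() else np.nan
    return {
        "ari": float(ari),
        "backbone_defects": by_class["backbone"]["defect"],
        "tip_defects": by_class["tip"]["defect"],
        "self_heals": log_.counts()["self-heal"],
        "tau_means": means,
        "gmm_means": model.means.tolist(),
        "n": int(truth.size),
        "trajectory": (traj, topo, gt, tau, model, assigned),
    }


def gmm_planted_experiment(seed: int = 0, n: int = 10_000) -> dict:
    """GMM recovery of a planted 3-component tauSOAP-like mixture."""
    rng = np.random.default_rng(seed)
    comps = [(0.1, 0.02), (0.5, 0.05), (0.8, 0.02)]
    vals = np.concatenate([rng.normal(m, s, n // 3) for m, s in comps])
    model = domains.fit_domains(vals, k=3, seed=seed)
    planted = np.array([0.1, 0.5, 0.8])
    return {
        "mean_abs_err": float(np.max(np.abs(model.means - planted))),
        "labels": list(model.labels),
        "n": len(vals),
    }


def hb_sasa_sign_experiment(seed: int = 0, n_seeds: int = 20,
                            n_dimers: int = 5, n_frames: int = 150) -> dict:
    """Sign of Spearman(mean N_HB-dim0, mean SASA) across independent runs.

    On rupture-prone synthetic stacks, monomers losing their original
    H-bonds gain solvent exposure, so the correlation should be negative in
    (nearly) every run; the one-sided sign-test p-value is reported.
    """
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_seeds):
        params = SyntheticParams(
            n_dimers=n_dimers, k_tip=4e-4, k_back=0.0, k_slide=3e-4,
            k_rebind=1e-4, noise_sigma=0.01, dt_frame=50.0,
            n_frames=n_frames, seed=int(rng.integers(2 ** 31)))
        topo, frame0 = build_stack(params)
        traj, _ = simulate_exchange(topo, frame0, params)
        mm = metrics.monomer_metrics(traj, topo, sasa_stride=10)
        res = domains.correlate_hb_sasa(mm.hb_dim0_mean, mm.sasa_mean)
        rhos.append(res.spearman_rho)
    rhos = np.array(rhos)
    n_neg = int(np.sum(rhos < 0))
    p_sign = float(stats.binomtest(n_neg, n_seeds, 0.5,
                                   alternative="greater").pvalue)
    return {"n_negative": n_neg, "n_seeds": n_seeds, "sign_test_p": p_sign,
            "mean_rho": float(rhos.mean()), "n": n_seeds}


def lens_tausoap_consistency(seed: int = 0, n_dimers: int = 10,
                             n_frames: int = 150) -> dict:
    """Spearman correlation between tauSOAP and LENS on KMC data (non-empty
    neighborhoods only): the two descriptors should agree in rank."""
    params = default_kmc_params(seed, n_dimers, n_frames)
    topo, frame0 = build_stack(params)
    traj, _ = simulate_exchange(topo, frame0, params)
    tau = tau_soap_series(traj, topo)
    lens = lens_series(traj, topo, cutoff=0.6)
    nonempty = ~(tau.empty_mask[1:] | tau.empty_mask[:-1])
    rho, p = stats.spearmanr(tau.values[nonempty], lens[nonempty])
    return {"spearman_rho": float(rho), "p": float(p),
            "n": int(nonempty.sum())}
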