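#!/usr/bin/env python
"""Monomer-exchange dynamics of the 20D stack via tauSOAP domains.

Runs the kinetic-Monte-Carlo exchange simulation, computes tauSOAP per
monomer, clusters the pooled values into the three dynamic domains
(I stacked-bound, II stacked-unbound, III travelling), detects defect /
self-healing events, and scores everything against the planted ground
truth.  Also reports the H-bond/SASA anticorrelation.  Writes
results/exchange_summary.json and domain time series.
"""

import json
from pathlib import Path

from upydyn import domains, metrics
from upydyn.experiments import domain_recovery_experiment
from upydyn.model import TipSpec, label_tips

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

res = domain_recovery_experiment(seed=1)
traj, topo, gt, tau, model, assigned = res.pop("trajectory")

print(f"domain means (III, I, II sorted ascending): "
      f"{[round(m, 3) for m in res['gmm_means']]}")
print(f"tauSOAP class means: "
      f"{ {k: round(v, 3) for k, v in res['tau_means'].items()} }")
print(f"adjusted Rand index vs ground truth: {res['ari']:.3f}")
print(f"defect events: tip {res['tip_defects']}, "
      f"backbone {res['backbone_defects']} (end-region depth 2); "
      f"self-heals {res['self_heals']}")

end_region = [m for m, lab in label_tips(topo, TipSpec(2)).items()
              if lab == "tip"]
with open(OUT / "tausoap_domains.csv", "w") as fh:
    fh.write("# dwell filter 10 frames; domains I/II/III by GMM rank\n")
    fh.write("# end-region (tip/subtip) monomers, every 5th frame; backbone "
             "monomers stay in domain I throughout\n")
    fh.write("frame,monomer,tausoap,domain,true_state\n")
    for f in range(0, assigned.shape[0], 5):
        for j, m in enumerate(tau.monomer_ids):
            if m in end_region:
                fh.write(f"{f + 1},{m},{tau.values[f, j]:.4f},"
                         f"{assigned[f, j]},{gt.labels[f + 1, j]}\n")

mm = metrics.monomer_metrics(traj, topo, sasa_stride=10)
corr = domains.correlate_hb_sasa(mm.hb_dim0_mean, mm.sasa_mean)
print(f"Spearman(N_HB-dim0, sasa) = {corr.spearman_rho:.3f} "
      f"(p = {corr.spearman_p:.2e})")

tips = label_tips(topo, TipSpec(1))
summary = dict(res)
summary["hb_sasa_spearman"] = corr.spearman_rho
summary["hb_sasa_sigmoid_fit"] = corr.fit_params
summary["per_monomer"] = [
    {"monomer": int(m), "hb_dim0_mean": float(h), "sasa_mean": float(s),
     "tip": tips[m]}
    for m, h, s in zip(mm.monomer_ids, mm.hb_dim0_mean, mm.sasa_mean)]
(OUT / "exchange_summary.json").write_text(json.dumps(summary, indent=1))
print(f"wrote {OUT / 'exchange_summary.json'}")
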