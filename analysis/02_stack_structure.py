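#!/usr/bin/env python
"""Structural characterization of pre-stacked polymers of 2, 5, 10, 20 dimers.

For each stack size: the per-monomer RDF of core centers (stacking peak at
0.37 nm, dimerization peak at 0.6 nm), the N_HB-dim0 time series with its
KDE, and dimer planarity.  Writes results/rdf_<size>.csv,
hb_dim0_kde.csv and structure_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from upydyn import domains, metrics
from upydyn.synthetic import SyntheticParams, build_stack, simulate_exchange

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

summary = {}
kde_data = {}
for n_dimers in (2, 5, 10, 20):
    # self-healing-dominated rates: ruptures occur but the stacks stay
    # mostly intact, which is the structural (RDF/planarity) regime
    params = SyntheticParams(n_dimers=n_dimers, k_tip=5e-4, k_back=0.0,
                             k_slide=2e-4, k_rebind=2e-3, noise_sigma=0.01,
                             dt_frame=50.0, n_frames=200, seed=n_dimers)
    topo, frame0 = build_stack(params)
    traj, gt = simulate_exchange(topo, frame0, params)

    centers = metrics.core_centers(traj, topo)
    r, g = metrics.rdf_per_monomer(centers, traj.box, r_max=1.5,
                                   bin_width=0.02)
    g_ref = float(g[r >= 0.2].max())
    peaks = metrics.rdf_peaks(r, g, min_height=0.2 * g_ref, k=2, min_r=0.2)
    with open(OUT / f"rdf_{n_dimers}d.csv", "w") as fh:
        fh.write("# per-monomer RDF, shell-volume corrected, no bulk density\n")
        fh.write("r_nm,g\n")
        for ri, gi in zip(r, g):
            fh.write(f"{ri:.4f},{gi:.6f}\n")

    hb = metrics.hb_dim0_series(traj, topo)
    planarity = metrics.dimer_planarity(traj, topo)
    kde_data[n_dimers] = hb.values.ravel()
    summary[f"{n_dimers}D"] = {
        "rdf_peaks_nm": peaks.tolist(),
        "rdf_peak_heights": [float(g[np.argmin(np.abs(r - p))]) for p in peaks],
        "mean_hb_dim0": float(hb.values.mean()),
        "planar_fraction": planarity["planar_fraction"],
        "n_ruptures": sum(e.type == "rupture" for e in gt.events),
    }
    print(f"{n_dimers:>2}D: RDF peaks {np.round(peaks, 2)} nm, "
          f"<N_HB-dim0> = {hb.values.mean():.2f}, "
          f"planar fraction {planarity['planar_fraction']:.2f}")

grid = np.linspace(-0.5, 4.5, 251)
with open(OUT / "hb_dim0_kde.csv", "w") as fh:
    fh.write("n_hb," + ",".join(f"kde_{n}d" for n in kde_data) + "\n")
    dens = {n: domains.kde_density(v, grid) for n, v in kde_data.items()}
    for i, x in enumerate(grid):
        fh.write(f"{x:.3f}," + ",".join(f"{dens[n][i]:.5f}" for n in dens) + "\n")

(OUT / "structure_summary.json").write_text(json.dumps(summary, indent=1))
print(f"wrote {OUT / 'structure_summary.json'}")
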