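# upydyn

Analysis toolkit for the monomer-exchange dynamics of ureido-pyrimidinone
(UPy) supramolecular polymers — 1-D stacks of dimers held together by four
self-complementary hydrogen bonds (a DDAA array) and π–π stacking.  The
package quantifies how such stacks form structural defects (dimer rupture),
how the freed monomers slide and re-attach (self-healing), and how fast
these rare events occur, for researchers studying supramolecular polymer
dynamics from molecular-dynamics trajectories.

## What it computes

**Hydrogen-bond coordination.**  The number of dimerization H-bonds is a
continuous coordination count built from the rational switching function

    s(r) = 1                               for r ≤ D0
    s(r) = (1 − x^n)/(1 − x^m),  x = (r − D0)/R0,   otherwise

with R0 = 0.12 nm, D0 = 0.27 nm, n = 6, m = 12.  N_HB–dim of a dimer is
the sum of s over its four donor–acceptor pairs; N_HB–dim0 is the same sum
always evaluated against the t = 0 partner, which makes it a rupture
detector for the original dimers (it is deliberately blind to re-pairing
with a different partner).

**Structural metrics.**  Per-monomer RDF of core–core distances
(normalized by monomer count, not bulk density, so stacking peaks grow
with stack length), Shrake–Rupley SASA per monomer, aggregation propensity
AP = Σ SASA(isolated stacks)/SASA(assembly), inter-stack atomic contacts
n_c split into end-region (tips and subtips) vs backbone, and dimer
planarity from best-fit core planes.

**Dynamic domains.**  Each monomer's interaction center (center of mass of
its H-bond quadruple) gets a SOAP power-spectrum fingerprint of its
neighborhood (r_cut = 0.6 nm); τSOAP is the frame-to-frame distance of
these fingerprints, min–max normalized to [0, 1].  A 1-D Gaussian mixture
over the pooled τSOAP values separates three domains — I stacked-bound,
II stacked-unbound, III travelling — and domain transitions are the
exchange events: I→II/III is a defect formation, II/III→I a self-healing,
II↔III an exchange.  LENS (neighbor-list turnover) is the set-based
cross-check.

**Rare-event kinetics.**  Biased (infrequent well-tempered metadynamics)
transition times are rescaled to the unbiased clock via
t = Σ_i Δt_i exp(βV(t_i)); an ensemble of such times is fitted with the
Poisson CDF P(t) = 1 − exp(−t/τ); free-energy surfaces are recovered from
biased CV samples by exponential reweighting.

**Synthetic ground truth.**  Because every estimator needs validation, the
package includes a kinetic-Monte-Carlo (Gillespie) generator of stack
trajectories with planted rupture/slide/rebind dynamics (tip rupture rate
≫ backbone rate), exact per-frame state labels, and well-tempered-style
bias staircases whose unbiased transition times are known by construction.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
stacks.  For example, the exchange-dynamics analysis:

```
$ python analysis/03_exchange_dynamics.py
domain means (III, I, II sorted ascending): [0.0, 0.154, 0.319]
tauSOAP class means: {'bound': 0.163, 'stacked-unbound': 0.557, 'travelling': 0.004}
adjusted Rand index vs ground truth: 0.972
defect events: tip 3, backbone 0 (end-region depth 2); self-heals 0
Spearman(N_HB-dim0, sasa) = -0.356 (p = 2.43e-02)
```

Reading: the three Gaussian components sit at τSOAP ≈ 0 (travelling
monomers look static because their neighborhoods are empty), ≈ 0.15
(stacked-bound) and ≈ 0.32 (stacked-unbound, the most dynamic
neighborhoods); frame-level domain assignments agree with the planted
kinetic-Monte-Carlo states at ARI 0.97; all detected defect events sit in
the end region (the planted backbone rupture rate is zero); and monomers
with lower time-averaged H-bond coordination expose more surface area
(negative Spearman correlation — the hydration signature of defect
formation).

The rare-event analysis recovers a planted seven-decade tip/backbone
timescale contrast:

```
$ python analysis/04_defect_kinetics.py
tip: tau = 8.502e+01 ps (MLE 7.995e+01), KS p = 0.96, planted 1.0e+02
backbone: tau = 1.222e+09 ps (MLE 1.203e+09), KS p = 0.98, planted 1.0e+09
log10(tau_backbone / tau_tip) = 7.16 +- 0.01 (planted 7)
```

The `upydyn` command line exposes the same pipeline on datasets on disk:
`upydyn generate --out ds --seed 1`, then `upydyn analyze --dataset ds
--out report`.

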