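# Methods

This note documents the models, estimators, and design choices behind
`upydyn`, and what the synthetic validation does and does not establish.

## Units and conventions

Coordinates in nm, times in ps, energies in kJ/mol, k_B = 0.0083144621
kJ/(mol K).  All pair distances use the minimum-image convention in
orthorhombic boxes; molecules are whole by construction in the synthetic
data and are expected whole in user-supplied trajectories.

## H-bond coordination

The dimerization H-bond count uses the rational switching function with
R0 = 0.12 nm, D0 = 0.27 nm and exponents n = 6, m = 12.  Only R0 and D0
are physically anchored; the exponents are the common default for this
functional form and are exposed in `SwitchingParams`.  The removable
singularity at x = 1 is evaluated as n/m; the function is continuous and
non-increasing (tested on a 10⁴-point grid).  N_HB–dim0 keeps the t = 0
pairing for the whole trajectory: it detects rupture of original dimers
and is intentionally blind to dimerization with a new partner (the
event-level analyses use the τSOAP domains instead, which see any
neighborhood change).

## RDF normalization

The per-monomer RDF divides the frame-averaged pair-distance histogram by
the shell volume 4πr²Δr and the number of monomers, but *not* by a bulk
density.  Rationale: for a quasi-1-D stack a bulk-density normalization
would suppress exactly the size dependence of interest — with more stacked
neighbors at a given separation the peak should grow.  Peak extraction
(`rdf_peaks`) takes the first k local maxima above a height threshold and
above `min_r` (default 0); the synthetic analyses use min_r = 0.2 nm
because the generator's point-like centers carry no excluded volume, so an
isolated close pass between two detached monomers is amplified by the
1/r² shell correction into a spurious spike.

## SASA, aggregation propensity, contacts, planarity

SASA is Shrake–Rupley with deterministic golden-spiral sphere points
(default 960/atom, error < 2% against the analytic sphere; a floor of 32
points is enforced), probe 0.14 nm, and a single default atomic radius of
0.15 nm when no per-atom radii are supplied (the synthetic motifs have no
chemistry to differentiate).  Aggregation propensity evaluates each
stack's SASA alone in its current conformation and divides the sum by the
assembly SASA, so AP = 1 for non-interacting stacks and grows as surface
is buried.  Inter-stack contacts count atom pairs across stacks within a
cutoff (default 0.5 nm; the choice is recorded in outputs) in either
all-solute or core-only scope.  Dimer planarity is the angle between the
two monomers' best-fit core planes (smallest-variance SVD axis), folded to
[0°, 90°]; "planar" defaults to < 20°.

Tip labelling: depth 1 (end dimers) is the default for H-bond statistics;
depth 2 (end dimers plus first neighbors — tips and subtips) is the
default for inter-stack contact analyses and for event localization.  The
depth-2 choice for events is deliberate: the first neighbors of a ruptured
end dimer have genuinely dynamic SOAP neighborhoods (the unbound pair sits
inside their cutoff), so they belong to the dynamic end region rather than
the insulated backbone.

## SOAP, τSOAP, LENS

Each monomer's interaction center is the center of mass of its 4-atom
H-bond quadruple.  The neighborhood density (other centers within
r_cut = 0.6 nm, single species) is smeared with Gaussians of width
σ = 0.05 nm and expanded in an orthonormal polynomial radial basis
((r_cut − r)^(n+2), Löwdin-orthonormalized; n_max = 8) times spherical
harmonics (l_max = 6).  The expansion uses the closed-form spherical-
harmonic decomposition of a displaced Gaussian (exponentially scaled
modified spherical Bessel functions) with 96-point Gauss–Legendre radial
quadrature; the rotation-invariant power spectrum p_{nn'l} is
L2-normalized.  Tests validate the implementation against a direct 3-D
quadrature of the density that bypasses the Bessel route.  An empty
neighborhood maps to a reference unit vector (zero spectrum, unit padding
component), so a center that stays isolated has zero frame-to-frame
distance — detached monomers "look static".

τSOAP_i(t) is the Euclidean distance between center i's normalized SOAP
vectors at consecutive frames, min–max normalized over the whole dataset
(per-center normalization is available).  A degenerate range (fully static
data) yields all zeros.  Δt is one frame interval; a stride is available.
LENS is |N_t Δ N_{t−1}| / (|N_t| + |N_{t−1}|) over neighbor-id sets, 0
when both sets are empty.

## Domain model and events

Domains are a k = 3 Gaussian mixture over the pooled 1-D τSOAP values.
Components sorted by mean map to III (travelling, lowest), I (stacked
bound, middle), II (stacked unbound, highest).  EM initialization is a
deliberate design choice: the primary start places component means at the
2/50/98 percentiles with middle-heavy weights and a tight variance on the
lowest component.  The pooled distribution is a dominant mid band flanked
by sparse extremes, and k-means-seeded restarts reliably split the mid
band instead of seeding the near-degenerate low band at τSOAP ≈ 0; the
quantile start converges to the band structure directly (k-means restarts
remain as fallback when it does not converge).  A variance floor of 1e-6
keeps the travelling spike from collapsing below machine precision.
Recovery of a well-separated planted 3-Gaussian mixture is unaffected
(means recovered to < 1e-3).

Assignment is maximum-posterior per value, followed by a dwell filter that
merges runs shorter than `dwell_min` frames into the flanking state
(default 5; the exchange-dynamics analyses use 10 frames = 0.5 ns, an
order of magnitude below the shortest planted dwell time, and record the
choice).  Events are the label transitions: I→II/III defect, II/III→I
self-heal, II↔III exchange.

The H-bond/SASA relation is summarized by the Spearman rank correlation
between per-monomer time-averaged N_HB–dim0 and SASA plus a least-squares
decreasing sigmoid y = a/(1 + exp((x − x0)/w)) + b — a bounded step
between the intact (≈4) and ruptured (≈0) plateaus; the functional form
is a package choice recorded in outputs.

## Rare-event kinetics

Unbiased transition times rescale the simulation clock with the running
exponential of the bias, treating V(t) as a left-continuous step function
(constant between depositions): t = Σ_i Δt_i exp(βV_i) with a partial
last interval.  This reproduces the constant-bias closed form exactly on
any grid and inverts the synthetic staircase generator to 1e-9.

τ is fitted by nonlinear least squares of 1 − exp(−t/τ) to the empirical
CDF at plotting positions k/(n+1), computed in mean-scaled units so the
estimator is scale-equivariant; the exponential MLE (the sample mean) is
reported alongside, as is a Kolmogorov–Smirnov test of the sample against
Exp(τ̂) — reported as a validity diagnostic, never used to drop runs.
Censored runs are excluded from the fit but counted.  At n = 30 the
estimator's relative standard error is ≈ n^(−1/2) ≈ 18%; the calibration
experiment therefore reports the median *signed* relative error (a bias
measure, ≈ 1–3%) together with the median absolute error (≈ 14%,
statistics, not bias) and the factor-2 coverage (> 95%).

FES reweighting uses w = exp((V − c_t)/kT) when an explicit c_t column is
present, else exp(V/kT) with a constant gauge shift ("static-bias" mode,
recorded in the grid metadata).  The full time-dependent reweighting
offset requires the bias-grid history, which COLVAR-style tables do not
carry; for a converged tempered bias the difference is a constant that the
min-shift removes.  Empty cells are NaN and flagged, never zero.

## Synthetic stack generator

Monomers are rigid 5-point motifs: a core-center point plus a planar DDAA
row of 4 H-bond atoms (0.15 nm spacing, 0.2 nm donor–acceptor gap across
the dimer).  Dimers sit at core–core distance 0.6 nm; consecutive dimers
stack every 0.37 nm along z.  The core-center atom is the monomer's
explicit geometric center (the motif centroid sits 0.16 nm off-core and
would shift the dimerization RDF peak).

Exchange dynamics is a direct Gillespie KMC over three event types:

- rupture, per intact dimer, at k_tip for frame-0 end dimers and k_back
  otherwise (static initial labels keep the per-class statistics exactly
  Poisson);
- slide, per unbound monomer at k_slide: ±1 lattice site (reflecting at
  the ends).  The first slide detaches the monomer to a "travelling" lane
  at radius 1.2 nm from the stack axis, each monomer on its own
  golden-angle azimuth.  The radius is chosen strictly outside the 0.6 nm
  SOAP/LENS cutoff of every stacked center and the azimuth spread keeps
  travelling monomers out of each other's cutoffs, so detached centers
  have empty neighborhoods (τSOAP ≈ 0);
- rebind, at k_rebind, for opposite-column unbound monomers at the same
  site when at least one is *stacked*-unbound.  Two travelling monomers in
  the detached lanes cannot re-form a dimer mid-stack (the lattice has no
  excluded volume, and an interior "ghost dimer" would contaminate
  backbone neighborhoods).

On rupture both monomers shift 0.25 nm outward along the dimer axis, so
their H-bond pair distances leave the switching plateau (N_HB–dim0 drops)
and their solvent exposure rises; rebinding restores the bound geometry.

Thermal noise is decorative: per monomer and frame, a rigid-body Gaussian
displacement (σ = 0.01 nm; ×8 for stacked-unbound monomers, emulating the
larger fluctuations of a monomer that lost its four H-bonds) plus a
rigid-body orientational jitter (σ = 0.12 rad) about the H-bond-quadruple
center — the rotation tilts the motif plane (making planarity statistics
meaningful) without moving the SOAP center at all.  Noise comes from an
RNG stream separate from the KMC stream, so the planted ground truth is
bit-identical under any noise amplitude; the whole run is bit-reproducible
from one seed.

Bias staircases mirror well-tempered deposition: height increments
h_k = h_0 exp(−V_k/((γ−1)k_BT)) with γ = 10, h_0 = 1.5 kJ/mol, pace
10 ps.  The biased stopping time is constructed by exact inversion of the
acceleration integral, so the rescaling estimator recovers the planted
exponential draw to machine precision.

### Study conditions

The exchange-dynamics experiments use a 20-dimer stack, k_tip = 1e-3/ps,
k_back = 0, k_slide = 5e-4/ps, k_rebind = 1e-4/ps, 400 frames at 50 ps.
These rates are free parameters (no quantitative sliding/rebinding rates
are available to anchor them); they were chosen once so that all three
states are populated within the simulated window and are reported in every
output's metadata.  The structure comparisons (RDF/planarity across 2–20
dimers) use self-healing-dominated rates (k_rebind = 2e-3/ps) so the
stacks stay mostly intact, which is the structural regime.

### What the synthetic validation shows — and does not

Passing tests establish that the estimators recover *planted* quantities
under the generator's assumptions: Markovian single-rate events, rigid
motifs, state-dependent but Gaussian noise, geometrically idealized
detachment.  Real MD trajectories add conformational flexibility,
solvent-mediated correlations, non-exponential waiting-time corrections,
gradual (not instantaneous) rupture, and chemically heterogeneous radii —
none of which the generator emulates.  Quantities whose *absolute* values
depend on those features (SASA magnitudes, contact counts, τSOAP band
positions) should be re-examined on real data; the invariances, planted-
parameter recoveries, and ordering relations tested here are the parts
that transfer.

## Numerical notes

- The polynomial radial-basis overlap matrix is ill-conditioned at
  n_max = 8; Löwdin orthonormalization is accurate to ~1e-6, adequate for
  a fingerprint that is L2-normalized and compared by distance.
- Histogram bins are half-open [r, r + Δr); edge ties go to the lower bin
  (numpy convention).
- GMM determinism: one seed controls EM; identical inputs give identical
  models regardless of input order.
- Degenerate inputs are handled explicitly: zero-variance KDE warns and
  returns a spike; all-identical τSOAP values give a flagged degenerate
  domain model; single or identical transition times give a flagged
  point-estimate fit; a single stack is rejected for AP.
- Problem sizes in tests and the acceptance script (400-frame 20D runs,
  200×30 τ replicates, 1e5 reweighting samples) were sized to exercise the
  asymptotics the estimators rely on while keeping a full run in tens of
  seconds on one CPU.
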