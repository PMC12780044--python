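# Methods

`tpskit` implements the analysis machinery of AI-guided transition path
sampling (TPS) for lipid flip-flop and membrane nanoporation, exercised
end-to-end on synthetic stochastic dynamics and synthetic membrane
configurations.  This note records the models, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the design
decisions taken where the design was genuinely open.

## The sampling model

A transition path connects two metastable states (lower/upper leaflet for
flip-flop, flat/porous membrane for nucleation) and enters each state only at
its endpoints (first-entrance convention).  The Markov chain in path space
uses **two-way shooting**: a shooting point (SP) is drawn from the current
path, two trajectory segments are propagated from it with independent noise,
and if the segment endpoints lie in different states the spliced trial path
(one segment time-reversed) replaces the current path with
Metropolis–Hastings probability

    min(1, p_sel(x_SP | trial) / p_sel(x_SP | current)),

where `p_sel` is the normalized SP-selection weight of the shooting point
within each path.  For reversible dynamics this acceptance preserves the
equilibrium transition-path ensemble (TPE) for *any* selection distribution,
which is what lets the selection adapt to a learned committor without biasing
the ensemble.  Under uniform selection the rule reduces to the classic
eligible-length ratio for flexible-length paths.  Unresolved shots (segment
cap `max_steps` reached before entering a state) are rejected moves, logged
distinctly.

The toy propagator is overdamped (velocity-free) Euler–Maruyama Langevin
dynamics in kT units, `dx = -∇U dt + sqrt(2 dt / β) N(0,1)`.  "Two-way"
shooting then means two independent noise realizations from the SP, one
relabeled as time-reversed — the diffusive-limit TPS convention.  Molecular
dynamics proper (force fields, thermostats, restraint protocols) is outside
the package's scope.

## Committor learning

Each shot yields a record `(x_SP, n = 2, k)` with `k` the number of segment
endpoints in the designated final state.  The committor network
`phi(x | w) = sigmoid(q(x | w))` is fit by minimizing the mean negative
log-likelihood of shot outcomes,

    -L(w)/N = -(1/N) Σ_i ln[ C(n_i, k_i) phi_i^{k_i} (1 - phi_i)^{n_i - k_i} ],

plus an L2 penalty.  A two-output softmax head is mathematically identical to
the single-logit sigmoid for a binary outcome; the sigmoid is used.  The
architecture follows the compression-stage pattern of the study: per stage a
linear width reduction with train-time dropout, then a residual block of
depth 4 with ELU activations; the final stage is a bare linear unit (e.g.
68→46→31→21→14→10→1 for flip-flop features, 147→85→50→29→14→17→1 for
pore-nucleation features; the toy studies use much smaller stacks such as
1→16→16→1).

The network, backpropagation (including input gradients for the reactive-flux
analysis) and the Adam optimizer are implemented directly on NumPy arrays.
This keeps the likelihood, the logit access and the gradients exact,
inspectable and dependency-light; at the problem sizes the package targets
(10²–10⁴ records, 10²–10⁴ parameters) full-batch/minibatch NumPy training is
fast.  Defaults: Adam with learning rate 1e-3 (toy studies use 5e-3 to 1e-2),
batch 256, dropout 0.1 where enabled, phi clamped at 1e-7 inside the loss
(the likelihood is unbounded at phi ∈ {0,1} with mismatched k).  Training
stops early at the minimum validation loss; validation is split by MC-chain
id (hold out one chain), falling back to a random 20% split when only one
chain exists.

## Shooting-point selection

The informative SPs sit near phi = 0.5, where the trial-path probability
P(TP|x) = 2 phi (1 - phi) peaks.  The selection target is Cauchy(0, 1) on the
committor logit `q = ln[phi/(1-phi)]`: frames of the current path are weighted
by `Cauchy(q_i) / P̂(q_i | TP)`, with `P̂(q | TP)` a histogram of the logits of
accepted transition-path frames.  Selection is uniform for the first 100 MC
steps, the histogram is built at step 100 and refreshed every 250; 50
equal-width bins span the observed q-range clipped to [-10, 10], and empty
bins inherit the smallest nonzero bin density so that frames there keep a
finite weight.  Path endpoints are never eligible (they lie inside states).
The histogram pools frames per chain by default.

Note that adaptive selection changes only the *mixing* of the chain, never
its stationary distribution (the MH correction above).  The package's
enumeration oracle (below) checks exactly this.

## Diagnostics

* **Efficiency** — `eta_dn(n) = 1 - (n_exp - n_gen)/n` with
  `n_exp = Σ 2 phi (1-phi)` cumulated over SPs and `n_gen` the cumulative
  count of generated transition paths (k = 1 shots); and
  `eta_T = T_TP / T_all`, the fraction of propagated time inside newly
  accepted transition paths.  `T_TP` counts only accepted new paths; `T_all`
  counts every propagated segment including rejected shots.
* **Accuracy** — the true committor P of an SP is modeled as Beta-distributed
  around the estimate phi with matched mean and
  `Var[P] = (1 - alpha) phi (1 - phi)`; convolution with the binomial shot
  distribution gives a beta-binomial likelihood for k with
  `w = alpha/(1-alpha)`.  `alpha` is estimated by maximizing the flat-prior
  log-posterior on a dense grid (resolution 1e-3) with bounded local
  refinement — the curve can be flat near the boundaries, where derivative
  methods are fragile.  `alpha = 1`: the model fully explains the outcomes;
  `alpha = 0`: outcomes look fully committed (P ∈ {0,1}), no predictive
  power.  The alpha → 0/1 limits are implemented as the exact mixture/binomial
  limits of the density.
* **Bootstrap/CV** — 10 rounds of leave-one-chain-out, 100 bootstrap
  resamples of the held-out chain each; all 1000 draws pool into
  2.5/25/50/75/97.5 percentiles (box-and-whisker convention).  Percentiles
  are pooled across rounds rather than taken per round, matching the pooled
  totals the convention implies.
* **Calibration** — dedicated validation shots with n = 20 per point; a
  least-squares line `q_lin = c q + d` between the observed logit
  `ln[k/(n-k)]` and the model logit.  Records with k ∈ {0, n} have infinite
  observed logit and are excluded from the line fit (the objective is
  undefined there); alpha entering the spread
  `Δphi_lin = sqrt(1 - alpha (1 - 1/n)) sqrt(phi_lin (1 - phi_lin))` is
  estimated on all validation records.

## Mechanism analysis

The reactive-flux direction `v(phi) = <∇phi>_phi / |<∇phi>_phi|` averages the
committor gradient on iso-committor surfaces (default: 10 equal phi-bins on
(0.05, 0.95); near the state boundaries a quasi-linear committor must fail,
so extreme-phi samples are excluded).  Gradients are taken with respect to
z-scored features — `v` mixes heterogeneous units (nm, angles, counts), and
standardization makes the direction comparable across features; `v` is
therefore reported in standardized feature space, with the per-feature scales
stored alongside.  The minimum pairwise cosine between bin directions scores
linearity ("hardly changes with phi"); a planted radial committor drives it
below 0.5, a planted linear one keeps it above 0.99.

Projected TPE densities use the k-nearest-neighbor estimate `rho ~ r_k^{-2}`
in 2D; committor iso-surfaces on a 2D projection average the feature vectors
of the k nearest samples per grid node, project onto `v` and evaluate the
quasi-linear 1D committor.  Grid nodes whose k-th-neighbor radius exceeds 3×
the median are flagged as outside the data support rather than extrapolated.

Mechanism classification thresholds the smoothed (window 10, centered,
truncated at the ends) time-averaged pore coordinate at 1.0: a
membrane-spanning water pore is present above, absent below.

## Pore geometry

The pore coordinate combines nucleation and expansion:

* `xi_ch` — fraction of `N_slabs` equal slabs across the membrane region
  `[midplane - Z_mem/2, midplane + Z_mem/2]` occupied by at least one polar
  particle (headgroup P/N, water O) within lateral radius `R_cyl` of the
  nucleation center.  Occupancy is hard (binary): the package only analyzes
  configurations and needs no differentiable indicator; a smoothing hook is
  left in the interface.
* `R` — pore radius from the water count `N_w` within lateral cutoff `D`:
  `R = sqrt(N_w v_w / (pi Z_mem))` with `v_w = 0.030 nm³` per water (bulk
  density), configurable.
* `xi_P = xi_ch / xi_ch_s` while `xi_ch < xi_ch_s`, else
  `1 + max(0, R - R_0)/R_0` — continuous at the switch, with `xi_P = 1` a
  just fully nucleated pore of radius `R_0` and `xi_P ≈ 2` the relaxed open
  pore.  This combination rule is this package's reading of the coordinate's
  source definition; it is isolated behind a single function for easy
  correction.

The coarse-grained preset carries the published values (`N_slabs = 4`,
`Z_mem = 1.8`, `R_cyl = 1.0`, `D = 1.2`, `xi_ch_s = 0.9`, `R_0 = 0.38`, all
nm); the nominal atomistic preset only refines the slab count (10) since the
original atomistic parameterization is not reproduced here.  The nucleation
center is the weighted circular mean of headgroup positions over the periodic
box with Gaussian axial weight of width `Z_mem/2` — midplane-proximal
(pore-lining) heads dominate; the exact weighting of the source definition is
not reproduced and this choice is likewise isolated.

Pore lifetimes pool free runs that either end at spontaneous pore closure or
are right-censored at a wall time; the censored-exponential MLE is
`tau = (Σ all durations) / (number of observed closures)`, the maximizer of
`L(k) = Π_closed k e^{-k t_i} · Π_censored e^{-k t_i}`.

## Synthetic generators: what they emulate, and what not

* **Double well (1D)** — quartic, barrier 5 kT, minima ±1: the flip-flop
  z-coordinate caricature.  Its closed-form committor
  `phi(x) = ∫_a^x e^{βU} / ∫_a^b e^{βU}` is the oracle for committor
  recovery.
* **Two-channel surface (2D)** — two wells at (±1, 0) behind a Gaussian
  ridge with two gates: a direct gate at (0, 0) (the "dry tunneling"
  analogue) and a detour through a metastable intermediate at (0, 1.4) (the
  "pore" analogue).  Geometry: gate widths σx = 0.35, σy = 0.42, intermediate
  depth 1 kT below its exit saddles.  The widths and the intermediate depth
  were chosen once so that the two channels are distinct (ridge several kT
  above both gates) yet exchange within a few thousand MC steps — a deep
  intermediate traps the sampler in path space, the analogue of the
  long-lived pores seen in the real systems, which would make a desk-scale
  relaxation demonstration impractical.  The reference relaxation conditions
  are 3000 MC steps with uniform SP selection: barriers (T, P) = (7, 10) kT
  for the tunnel-dominant case and (11, 5) kT for the pore-dominant case.
  Uniform selection is used for this demonstration deliberately: adaptive
  selection concentrates SPs at the current channel's transition state and
  slows channel exchange without changing the sampled ensemble, so the
  relaxation physics shows cleanest unguided.  The channel indicator is the
  path-time average of y with the channel boundary at y = 0.8.  Channel
  switching is itself a rare event in path space, so waiting times are
  broadly distributed across noise seeds: individual chains can take
  substantially more or less than the reference run length to relax, and the
  per-chain occupancy statistic fluctuates accordingly.
* **Discrete birth-death chains** — reversible by construction, so the
  two-way-shooting acceptance rule is exact; every first-entrance path's
  equilibrium weight `pi(x_0) Π T(x_i, x_{i+1})` can be enumerated, giving a
  brute-force TPE oracle.  The reference chain has 5 sites, right-hop
  probability 0.55, no stays (stay probabilities blow up the enumeration
  combinatorially); enumeration to 29 hops leaves < 2e-4 truncated mass.
* **Membrane configurations** — geometry only, no energetics: jittered head
  planes at ±1.3 nm (DMPC scale, leaflet separation 2.6 nm), tail particles
  in the core, bulk water outside at 33.4 nm⁻³.  A planted pore is a
  cylindrical water column at bulk density plus a toroidal lining: nearby
  heads pulled toward the midplane and rim lipids placed on the pore mouth.
  The rim is what makes the circular-mean center estimator informative, as it
  is in real toroidal pores.  Not emulated: lipid chemistry, force-field
  structure, head-tail connectivity, curvature elasticity — so passing tests
  demonstrate the correctness of the geometry/estimator pipeline, not
  membrane physics.
* **Dispersed shot records** — the generative model of the accuracy
  estimator itself: phi from a sampler (default uniform(0.05, 0.95)), P ~
  Beta with matched mean and `Var[P] = (1-alpha) phi (1-phi)`, k ~
  Binomial(n, P); alpha ∈ {0, 1} handled as exact mixture/point-mass limits.
* **Censored lifetimes** — exponential draws with deterministic
  right-censoring; the reference recovery uses rate 2.5 and censor time
  0.48 (≈30% censored), i.e. a 0.4-time-unit mean lifetime.

All generators draw from a single named seed and record it in their output.

## Numerical choices and degenerate inputs

* Committor logits are clamped to |q| ≤ logit(1 - 1e-7) wherever a
  probability is formed; the stable log-sigmoid form is used in the loss.
* The alpha grid includes the endpoints exactly; the refinement stays inside
  the open interval.
* Histogram reweighting floors empty bins at the smallest nonzero density;
  an all-zero weight vector falls back to uniform with a logged warning.
* k-NN density floors zero radii (duplicate points) at machine scale.
* `smooth_series` truncates its centered window at the series ends.
* Degenerate chains (forced one-way hops) have no equilibrium mass in the
  initial state; the enumeration then weights starting sites uniformly.
* Every stochastic stage derives per-step seeds from a base seed via
  `SeedSequence`, so a chain restarted from a checkpoint (same current path,
  selector state, model, step index) reproduces the remaining log
  bit-identically.

## Reference problem sizes

The validation studies (tests and `scripts/acceptance.py`) use: 5000 shot
records for double-well committor recovery; 1e5 MC steps for the
enumeration-oracle comparison; 1e4 records per planted alpha; 100 replicate
chains for the efficiency identity; 1e4 censored lifetimes; 5 planted-pore
configurations; 1e4 samples in 10 dimensions for flux linearity; 2 chains ×
3000 MC steps per direction for the mechanism-relaxation demonstration; 2000
validation shots (n = 20) for calibration.  These sizes make each oracle
comparison statistically decisive at the stated tolerances while keeping the
whole battery at desk scale.

## Known limitations

* The committor network trains on CPU NumPy; it is not meant for the
  ~660-feature, 10⁴-record scale of a production study's post-processing,
  though nothing but time prevents it.
* The acceptance rule assumes reversible underlying dynamics (true for
  overdamped Langevin and birth-death chains); irreversible propagators
  would need generation-probability corrections the package does not
  implement.
* The pore coordinate's combination rule and the circular-mean weighting are
  package readings of their source definitions (see above), isolated for
  correction.
* `eta_T` of a toy chain is not comparable to molecular-dynamics values: toy
  segments are cheap and short relative to path lengths, so the time ratio
  reflects toy geometry, not sampler quality.
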