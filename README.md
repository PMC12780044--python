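# tpskit

**AI-guided transition path sampling: on-the-fly committor learning, sampler
diagnostics, and membrane-pore reaction-coordinate analysis.**

Rare events such as lipid flip-flop — the translocation of a lipid between
the two leaflets of a bilayer — and the nucleation of membrane-spanning water
pores happen on timescales far beyond brute-force simulation.  Transition
path sampling (TPS) harvests unbiased reactive trajectories by a Markov chain
in path space; guiding it with a neural-network *committor* — the probability
φ(x) that a trajectory launched from configuration x reaches the product
state before the reactant state — makes the harvesting efficient, and the
learned committor itself encodes the reaction mechanism.

`tpskit` implements this analysis stack for researchers studying rare
transitions in molecular and stochastic systems:

* **two-way-shooting TPS** over pluggable propagators, with
  Metropolis–Hastings acceptance that keeps the transition-path ensemble
  exact under any shooting-point bias (`tpskit.tps_core`);
* **committor networks** trained on shot outcomes (k hits out of n = 2
  two-way shots) by the binomial likelihood, with logit and input-gradient
  access (`tpskit.committor_model` — NumPy forward/backward, no GPU
  framework needed at this scale);
* **Cauchy-logit shooting-point selection** with histogram reweighting of
  P(q|TP) (`tpskit.sp_selection`);
* **diagnostics**: sampler efficiencies η_Δn = 1 − (n_exp − n_gen)/n and
  η_T = T_TP/T_all, the beta-binomial committor *accuracy* α (excess shot
  variance not explained by the model), bootstrap/cross-validation, and
  logit–logit calibration against dedicated validation shots
  (`tpskit.diagnostics`);
* **mechanism analysis**: reactive-flux directions v(φ) = ⟨∇φ⟩_φ/|⟨∇φ⟩_φ|,
  quasi-linear committor models φ ≈ f(x·v), k-NN densities and committor
  iso-surfaces, and pore/tunnel mechanism classification
  (`tpskit.mechanism_analysis`);
* **pore geometry**: the pore reaction coordinate ξ_P (slab-chain occupancy
  ξ_ch plus cylindrical pore radius R; ξ_P > 1 means a membrane-spanning
  pore) and the censored-exponential pore-lifetime MLE
  (`tpskit.pore_geometry`);
* **synthetic systems with known answers** — bistable Langevin toys with two
  competing transition channels, enumerable discrete chains, membrane-like
  point configurations with plantable pores, dispersed shot records and
  censored lifetimes — so every stage is testable without external data
  (`tpskit.toy_systems`).

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Learn the committor of a 5 kT double well from two-way shooting outcomes and
compare with the closed form, then estimate the model's accuracy α and a
censored pore lifetime:

```python
import numpy as np
from tpskit import (
    make_double_well_1d, analytic_committor_1d, generate_censored_lifetimes,
    estimate_accuracy, pore_lifetime_mle,
)
from tpskit.toy_systems import shoot_committor_batch
import tpskit.committor_model as cm

pot = make_double_well_1d(barrier_kT=5.0, x_min_sep=2.0)
rng = np.random.default_rng(7)
x_sp = rng.uniform(-0.8, 0.8, 5000)                      # shooting points
k = sum(shoot_committor_batch(pot, x_sp, -1.0, 1.0, dt=2e-3, beta=1.0,
                              max_steps=200_000, seed=s) for s in (1, 2))

model = cm.build_network(cm.NetworkSpec((1, 16, 16, 1), dropout=0.0, l2=1e-5), seed=0)
cm.train(model, (x_sp[:, None], np.full(5000, 2), k), epochs_max=400,
         seed=1, lr=5e-3, patience=60)

grid = np.array([-0.4, -0.2, 0.0, 0.2, 0.4])
print("x        phi_net  phi_exact")
for x, p_hat, p in zip(grid, model.predict(grid[:, None]),
                       analytic_committor_1d(pot, 1.0, -1, 1, grid)):
    print(f"{x:+.1f}     {p_hat:.3f}    {p:.3f}")

fit = estimate_accuracy((model.predict(x_sp[:, None])[:, None], np.full(5000, 2), k))
print(f"accuracy alpha = {fit.alpha_hat:.3f}")

t, c = generate_censored_lifetimes(rate=2.5, t_censor=0.48, N=200, seed=3)
lt = pore_lifetime_mle(t, c)
print(f"pore lifetime tau = {lt.tau_hat:.3f} ({lt.n_events} closures of {lt.n_total} runs)")
```

Output:

```
x        phi_net  phi_exact
-0.4     0.058    0.054
-0.2     0.208    0.201
+0.0     0.527    0.500
+0.2     0.827    0.799
+0.4     0.946    0.946
accuracy alpha = 0.966
pore lifetime tau = 0.494 (125 closures of 200 runs)
```

The network reproduces the analytic committor across the barrier region to a
few percent; α ≈ 0.97 says the model explains nearly all of the shot-outcome
variance beyond the irreducible binomial noise.  The lifetime estimator
τ = Σtᵢ/n pools the 75 right-censored runs into the aggregate open time while
dividing only by observed closures (true mean here: 1/2.5 = 0.4; with 125
closures the standard error is τ/√n ≈ 0.044).

A full end-to-end run — seed transition paths on the two-channel toy
landscape, sequential TPS with on-the-fly committor training, diagnostics
and mechanism reports, all archived with a manifest — is one command:

```sh
tpskit demo --out tps_demo --steps 300 --seed 1
```

Other subcommands: `simulate-toy`, `run-tps --config config.yaml`,
`train-committor`, `diagnose`, `analyze-mechanism`, `pore-coordinate`,
`lifetime`.

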