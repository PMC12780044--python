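"""End-to-end validation studies at desk scale.

Each study runs one slice of the pipeline against an independent oracle --
closed-form committor, brute-force path enumeration, quadrature, generative
recovery -- and returns the measured quantities.  The problem sizes are the
package's reference conditions (documented in the methods note); both the
acceptance test suite and ``scripts/acceptance.py`` call these functions.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from . import committor_model as cm
from . import diagnostics, mechanism_analysis, sp_selection
from .pore_geometry import PoreParams, pore_lifetime_mle, xi_p
from .toy_systems import (
    DiscreteChainSpec,
    analytic_committor_1d,
    enumerate_tpe_discrete,
    generate_censored_lifetimes,
    generate_membrane_config,
    generate_shot_records,
    make_double_well_1d,
    make_two_channel_2d,
    shoot_committor_batch,
)
from .tps_core import (
    DiscreteChainEngine,
    LangevinEngine,
    StateDefinition,
    make_seed_path,
    run_chain,
    smooth_series,
)


def _sub(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, k]).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# 1. committor recovery on the 1D double well (analytic oracle)
# ---------------------------------------------------------------------------

def committor_recovery_study(seed: int, n_records: int = 5000) -> dict:
    """Train a committor net on two-way shot outcomes; compare with the
    closed-form committor on the barrier region |x| <= 0.5 (barrier 5 kT)."""
    pot = make_double_well_1d(5.0, 2.0)
    rng = np.random.default_rng(_sub(seed, 1))
    xs = rng.uniform(-0.8, 0.8, n_records)
    k = (shoot_committor_batch(pot, xs, -1, 1, 2e-3, 1.0, 200_000, _sub(seed, 2))
         + shoot_committor_batch(pot, xs, -1, 1, 2e-3, 1.0, 200_000, _sub(seed, 3)))
    model = cm.build_network(cm.NetworkSpec((1, 16, 16, 1), dropout=0.0, l2=1e-5),
                             seed=_sub(seed, 4))
    cm.train(model, (xs[:, None], np.full(n_records, 2), k),
             epochs_max=400, seed=_sub(seed, 5), lr=5e-3, patience=60)
    grid = np.linspace(-0.5, 0.5, 101)
    err = np.abs(model.predict(grid[:, None])
                 - analytic_committor_1d(pot, 1.0, -1, 1, grid))
    return {"max_abs_error": float(err.max()), "n": n_records}


# ---------------------------------------------------------------------------
# 2. TPE correctness on an enumerable discrete chain
# ---------------------------------------------------------------------------

def tpe_sampling_study(seed: int, n_steps: int = 100_000) -> dict:
    """AI-guided TPS on a 5-site birth-death chain vs the brute-force
    enumerated transition-path distribution (total-variation distance)."""
    spec = DiscreteChainSpec.uniform(5, p_right=0.55, p_stay=0.0)
    exact, truncated, _ = enumerate_tpe_discrete(spec, max_len=29)
    engine = DiscreteChainEngine(spec, max_steps=10_000)
    seed_path = make_seed_path(engine, np.array([2.0]), engine.state_defs, "B",
                               seed=_sub(seed, 1))
    featurize = lambda F: np.atleast_2d(np.asarray(F, dtype=float)) / (spec.n_sites - 1)
    model = cm.build_network(cm.NetworkSpec((1, 8, 8, 1), dropout=0.0, l2=1e-5),
                             seed=_sub(seed, 2))
    selector = sp_selection.SPSelector(model=model, featurize=featurize)

    def trainer(mdl, recs, mc):
        cm.train(mdl, recs, epochs_max=80, seed=_sub(seed, 3) + mc, lr=1e-2)

    schedule = lambda mc: mc in (100, 500, 1000, 2000) or (mc > 0 and mc % 10_000 == 0)
    res = run_chain(engine, seed_path, n_steps, model, selector, engine.state_defs,
                    seed=_sub(seed, 4), final_state="B", featurize=featurize,
                    trainer=trainer, train_schedule=schedule)
    counts: Counter = Counter()
    for i in range(res.log.n_steps):
        frames = res.paths[res.log.path_id[i]].frames.ravel()
        counts[tuple(int(v) for v in frames)] += 1
    tv = 0.5 * sum(abs(counts.get(p, 0) / n_steps - pr) for p, pr in exact.items())
    tv += 0.5 * sum(c / n_steps for p, c in counts.items() if p not in exact)
    return {"tv": float(tv), "acceptance": res.log.acceptance_fraction,
            "truncated_mass": float(truncated), "n": n_steps}


# ---------------------------------------------------------------------------
# 3. accuracy-estimator recovery
# ---------------------------------------------------------------------------

def accuracy_recovery_study(seed: int, n_records: int = 10_000) -> dict:
    """alpha-hat vs planted alpha in {0.1..0.9} (n = 2 shots) plus both limits."""
    biases = []
    for i, alpha in enumerate(np.round(np.arange(0.1, 0.95, 0.1), 2)):
        recs = generate_shot_records(n_records, 2, float(alpha), seed=_sub(seed, 10 + i))
        fit = diagnostics.estimate_accuracy(recs)
        biases.append(fit.alpha_hat - alpha)
    binom_recs = generate_shot_records(n_records, 2, 1.0, seed=_sub(seed, 30))
    alpha_binom = diagnostics.estimate_accuracy(binom_recs).alpha_hat
    rng = np.random.default_rng(_sub(seed, 31))
    k_anti = np.where(rng.random(n_records) < 0.5, 2, 0)
    anti = (np.full((n_records, 1), 0.5), np.full(n_records, 2), k_anti)
    alpha_anti = diagnostics.estimate_accuracy(anti).alpha_hat
    return {"max_abs_bias": float(np.max(np.abs(biases))),
            "alpha_binomial": float(alpha_binom),
            "alpha_anti_informative": float(alpha_anti), "n": n_records}


# ---------------------------------------------------------------------------
# 4. beta-binomial pmf vs quadrature of the convolution
# ---------------------------------------------------------------------------

def betabinom_validation_study() -> dict:
    """Compare the closed-form pmf against numerical quadrature of the
    binomial-beta convolution and check normalization."""
    max_quad_err = 0.0
    max_norm_err = 0.0
    for n in (1, 2, 5, 20):
        for phi in (0.1, 0.4, 0.5, 0.85):
            for alpha in (0.05, 0.3, 0.6, 0.9):
                w = alpha / (1 - alpha)
                total = 0.0
                for k in range(n + 1):
                    ref, _ = quad(
                        lambda P: binom.pmf(k, n, P)
                        * beta_dist.pdf(P, w * phi, w * (1 - phi)),
                        0.0, 1.0, epsabs=1e-13, limit=200,
                    )
                    mine = math.exp(diagnostics.betabinom_logpmf(k, n, phi, alpha))
                    max_quad_err = max(max_quad_err, abs(mine - ref))
                    total += mine
                max_norm_err = max(max_norm_err, abs(total - 1.0))
    return {"quadrature_max_abs_error": float(max_quad_err),
            "normalization_max_abs_error": float(max_norm_err), "n": 4 * 4 * 4}


# ---------------------------------------------------------------------------
# 5. efficiency identities
# ---------------------------------------------------------------------------

def efficiency_study(seed: int, n_chains: int = 100, chain_len: int = 500) -> dict:
    """eta_dn under Bernoulli(2 phi (1-phi)) generated TPs, and the
    hand-built time-efficiency T_TP/T_all = 3/12."""
    rng = np.random.default_rng(_sub(seed, 1))
    finals = []
    for _ in range(n_chains):
        phi = rng.uniform(0.1, 0.9, chain_len)
        gen = rng.random(chain_len) < 2 * phi * (1 - phi)
        finals.append(diagnostics.efficiency_dn(phi, gen)[-1])
    finals = np.asarray(finals)

    class Log:
        t_tp = np.array([3.0])
        t_all = np.array([12.0])

    return {"eta_dn_mean": float(finals.mean()),
            "eta_dn_sem": float(finals.std(ddof=1) / math.sqrt(n_chains)),
            "eta_t_hand_log": diagnostics.efficiency_time(Log()),
            "n": n_chains}


# ---------------------------------------------------------------------------
# 6. censored-exponential lifetime estimator
# ---------------------------------------------------------------------------

def lifetime_study(seed: int, n_runs: int = 10_000) -> dict:
    """Recovery of a 0.4 time-unit mean pore lifetime at ~30% censoring, and
    agreement of the closed form with the numerical likelihood maximizer."""
    rate, t_censor = 2.5, 0.48  # exp(-rate * t_censor) ~ 0.30 censored
    t, c = generate_censored_lifetimes(rate, t_censor, n_runs, seed=_sub(seed, 1))
    fit = pore_lifetime_mle(t, c)
    res = minimize_scalar(lambda k: -fit.loglik(k), bounds=(1e-3, 100.0),
                          method="bounded", options={"xatol": 1e-12})
    rel_dev = abs(1.0 / res.x - fit.tau_hat) / fit.tau_hat
    sem = fit.tau_hat / math.sqrt(fit.n_events)
    return {"tau_hat": float(fit.tau_hat), "tau_true": 1.0 / rate,
            "sem": float(sem), "maximizer_rel_dev": float(rel_dev),
            "censored_fraction": float(np.mean(c)), "n": n_runs}


# ---------------------------------------------------------------------------
# 7. pore-coordinate geometry
# ---------------------------------------------------------------------------

def pore_geometry_study(seed: int, n_configs: int = 5) -> dict:
    """Planted-pore recovery with the coarse-grained parameter preset."""
    params = PoreParams.martini()
    devs, radii = [], []
    for i in range(n_configs):
        cfg = generate_membrane_config(pore_radius=0.4, seed=_sub(seed, 40 + i))
        st = xi_p(cfg, params)
        radii.append(st.R)
        devs.append(abs(st.R - 0.4))
    return {"radius_mean": float(np.mean(radii)),
            "radius_max_abs_error": float(np.max(devs)), "n": n_configs}


# ---------------------------------------------------------------------------
# 8. reactive-flux linearity
# ---------------------------------------------------------------------------

class _PlantedLinear:
    def __init__(self, v, b):
        self.v, self.b = v, b

    def predict(self, X):
        from scipy.special import expit

        return expit(np.atleast_2d(X) @ self.v + self.b)

    def input_gradient(self, X):
        p = self.predict(X)
        return (p * (1 - p))[:, None] * self.v[None, :]


class _PlantedRadial:
    def __init__(self, r0):
        self.r0 = r0

    def predict(self, X):
        from scipy.special import expit

        return expit(np.linalg.norm(np.atleast_2d(X), axis=1) - self.r0)

    def input_gradient(self, X):
        X = np.atleast_2d(X)
        r = np.maximum(np.linalg.norm(X, axis=1), 1e-12)
        p = self.predict(X)
        return (p * (1 - p) / r)[:, None] * X


def flux_linearity_study(seed: int, n_samples: int = 10_000, dim: int = 10) -> dict:
    """Planted quasi-linear committor phi = sigmoid(x.v0 + b): the global and
    per-bin flux directions must align with v0; a radial committor must not."""
    rng = np.random.default_rng(_sub(seed, 1))
    v0 = rng.normal(size=dim)
    v0 /= np.linalg.norm(v0)
    model = _PlantedLinear(2.0 * v0, b=0.3)
    X = rng.normal(size=(n_samples, dim))
    fd = mechanism_analysis.flux_direction(model, X)
    rad = mechanism_analysis.flux_direction(_PlantedRadial(math.sqrt(dim)), X)
    return {"global_cosine": float(abs(fd.v @ v0)),
            "min_pairwise_cosine": float(fd.cosine_matrix.min()),
            "radial_linearity_score": float(rad.linearity_score), "n": n_samples}


# ---------------------------------------------------------------------------
# 9. mechanism relaxation on the two-channel toy
# ---------------------------------------------------------------------------

def mechanism_relaxation_study(seed: int, n_steps: int = 3000,
                               n_chains: int = 2) -> dict:
    """Chains seeded in the disfavored channel must relax to the dominant one.

    With the direct channel dominant (barriers 7 vs 10 kT) pore-seeded chains
    dry out; with the pore channel dominant (11 vs 5 kT) dry-seeded chains
    nucleate and stay wet.  The channel indicator is the path-time average of
    y, smoothed over 10 MC steps, with the channel boundary at y = 0.8.
    """
    y_thresh = 0.8

    def run_one(bT, bP, start_channel, s):
        pot = make_two_channel_2d(bT, bP, 1.0)
        states = [StateDefinition("L", below=-0.8), StateDefinition("U", above=0.8)]
        engine = LangevinEngine(pot, 5e-3, 1.0, 50_000, states)
        y0 = pot.params["y0"]
        x0 = [0.0, y0] if start_channel == "P" else [0.0, 0.0]
        sp = make_seed_path(engine, x0, states, "U", seed=_sub(s, 90))
        res = run_chain(engine, sp, n_steps, seed=s, final_state="U",
                        xi_fn=lambda fr: fr[1])
        return smooth_series(res.log.xi_hat, 10)

    out = {"n": n_steps}
    for label, (bT, bP, start, target) in {
        "T_dominant": (7.0, 10.0, "P", "T"),
        "P_dominant": (11.0, 5.0, "T", "P"),
    }.items():
        fracs, starts_ok = [], []
        for c in range(n_chains):
            sm = run_one(bT, bP, start, _sub(seed, 100 + 10 * c + (0 if target == "T" else 1)))
            in_target = (sm <= y_thresh) if target == "T" else (sm > y_thresh)
            starts_ok.append(bool(~in_target[0]))
            fracs.append(float(in_target[len(in_target) // 2:].mean()))
        out[f"{label}_final_occupancy_min"] = float(min(fracs))
        out[f"{label}_seeded_in_other_channel"] = all(starts_ok)
    return out


# ---------------------------------------------------------------------------
# 10. calibration of validation shots
# ---------------------------------------------------------------------------

def calibration_study(seed: int, n_records: int = 2000, n_shots: int = 20) -> dict:
    """Logit-logit calibration line on dispersion-free validation shots."""
    recs = generate_shot_records(
        n_records, n_shots, 1.0,
        phi_sampler=lambda rng, N: rng.uniform(0.1, 0.9, N), seed=_sub(seed, 1))
    fit = diagnostics.calibration_fit(recs)
    limit = diagnostics.CalibrationFit(c=1.0, d=0.0, alpha=1.0,
                                       n_shots=10**9, n_used=1)
    return {"slope": float(fit.c), "intercept": float(fit.d),
            "alpha": float(fit.alpha),
            "spread_limit_alpha1_large_n": float(limit.spread(0.0)),
            "n": n_records}
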