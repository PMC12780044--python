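"""Sampler diagnostics: efficiency, committor accuracy, calibration.

Two efficiency measures summarize an AI-guided TPS run: eta_dn compares the
number of generated transition paths with the number expected from the
model's own committor estimates (n_exp = cumulative sum of
P(TP|x) = 2 phi (1-phi) over shooting points), and eta_T = T_TP / T_all is
the fraction of propagated simulation time spent inside newly accepted
transition paths.

The accuracy alpha of a committor model is defined through an overdispersion
model for shot outcomes: the true committor P of a shooting point is taken
as Beta-distributed around the model estimate phi with matched mean and
Var[P] = (1 - alpha) phi (1 - phi).  Convolving the Beta with the binomial
shot distribution gives a beta-binomial likelihood for k,

    p(k | n, phi, alpha) = C(n, k) B(w phi + k, w (1-phi) + n - k) / B(w phi, w (1-phi)),

with w = alpha / (1 - alpha); alpha is estimated by maximizing the flat-prior
log-posterior sum_i ln p(k_i | n_i, phi_i, alpha).  alpha = 1 means the model
fully explains the outcome variance (pure binomial); alpha = 0 means the data
are best explained by fully committed states P in {0, 1} -- no predictive
power.

Calibration against dedicated validation shots (n = 20 per point) fits a line
on logit scale, q_lin = c q + d, between the observed logit ln[k/(n-k)] and
the model logit, and summarizes the residual spread by
Delta phi_lin = sqrt(1 - alpha (1 - 1/n)) sqrt(phi_lin (1 - phi_lin)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, expit, gammaln

from .committor_model import as_shot_arrays, p_tp

__all__ = [
    "AccuracyFit",
    "CalibrationFit",
    "efficiency_dn",
    "efficiency_time",
    "betabinom_logpmf",
    "estimate_accuracy",
    "bootstrap_accuracy",
    "calibration_fit",
]


# ---------------------------------------------------------------------------
# efficiency
# ---------------------------------------------------------------------------

def efficiency_dn(phi, generated) -> np.ndarray:
    """Efficiency series eta_dn(n) = 1 - (n_exp - n_gen)/n.

    ``phi`` are the model committor estimates at the shooting points in MC
    order; ``generated`` flags the shots that produced a transition path (for
    two-way shooting, exactly the k = 1 outcomes).  n_exp is the cumulative
    sum of 2 phi (1-phi); n_gen the cumulative count of generated TPs.
    """
    phi = np.asarray(phi, dtype=float)
    gen = np.asarray(generated, dtype=float)
    if phi.shape != gen.shape:
        raise ValueError("phi and generated must have equal length")
    n_exp = np.cumsum(p_tp(phi))
    n_gen = np.cumsum(gen)
    steps = np.arange(1, len(phi) + 1, dtype=float)
    return 1.0 - (n_exp - n_gen) / steps


def efficiency_dn_from_records(records) -> np.ndarray:
    """eta_dn from shooting records carrying model phi and outcome k."""
    recs = [r for r in records if r.k is not None]
    phi = np.asarray([r.phi for r in recs], dtype=float)
    gen = np.asarray([r.k == 1 for r in recs], dtype=float)
    return efficiency_dn(phi, gen)


def efficiency_time(chain_log) -> float:
    """eta_T = T_TP / T_all, the time fraction in newly accepted TPs.

    Accepts a ChainLog (cumulative t_tp / t_all arrays) or any object with
    scalar ``t_tp`` and ``t_all`` attributes.
    """
    t_tp = np.asarray(getattr(chain_log, "t_tp"))
    t_all = np.asarray(getattr(chain_log, "t_all"))
    tp = float(t_tp[-1]) if t_tp.ndim else float(t_tp)
    al = float(t_all[-1]) if t_all.ndim else float(t_all)
    if al <= 0:
        raise ValueError("T_all must be positive")
    return tp / al


# ---------------------------------------------------------------------------
# beta-binomial accuracy model
# ---------------------------------------------------------------------------

def _ln_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def betabinom_logpmf(k, n, phi, alpha) -> np.ndarray:
    """Log pmf of the binomial-beta convolution (vectorized over k, n, phi).

    alpha = 1 returns the binomial log pmf (P = phi exactly); alpha = 0 the
    two-point mixture limit (mass phi at k = n, 1 - phi at k = 0).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(k < 0) or np.any(k > n) or np.any(k != np.round(k)):
        raise ValueError("require integer 0 <= k <= n")
    if np.any((phi <= 0) | (phi >= 1)):
        raise ValueError("phi must lie strictly in (0, 1)")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    k, n, phi = np.broadcast_arrays(k, n, phi)
    if alpha >= 1.0:
        with np.errstate(divide="ignore"):
            return _ln_binom(n, k) + k * np.log(phi) + (n - k) * np.log1p(-phi)
    if alpha <= 0.0:
        with np.errstate(divide="ignore"):
            return np.where(k == n, np.log(phi),
                            np.where(k == 0, np.log1p(-phi), -np.inf))
    w = alpha / (1.0 - alpha)
    a = w * phi
    b = w * (1.0 - phi)
    return _ln_binom(n, k) + betaln(a + k, b + n - k) - betaln(a, b)


@dataclass
class AccuracyFit:
    """Maximum-posterior committor accuracy with its posterior curve."""

    alpha_hat: float
    alpha_grid: np.ndarray
    log_posterior: np.ndarray
    n_records: int
    percentiles: Optional[dict] = None  # {2.5: ..., 25: ..., 50: ..., 75: ..., 97.5: ...}
    samples: Optional[np.ndarray] = None  # pooled bootstrap/CV alpha draws

    def __post_init__(self):
        if self.log_posterior.size and np.max(self.log_posterior) > self._at(self.alpha_hat) + 1e-6:
            raise ValueError("alpha_hat does not maximize the stored curve")

    def _at(self, alpha: float) -> float:
        i = int(np.argmin(np.abs(self.alpha_grid - alpha)))
        return float(self.log_posterior[i])


def _log_posterior(alpha, k, n, phi) -> float:
    return float(np.sum(betabinom_logpmf(k, n, phi, alpha)))


def estimate_accuracy(records, grid_resolution: float = 1e-3) -> AccuracyFit:
    """Estimate the accuracy alpha by maximizing the flat-prior log-posterior.

    A dense grid over [0, 1] (default resolution 1e-3) is scanned and the
    maximum refined locally; the grid curve is stored with the fit.  The
    records must carry the model committor estimate phi for each shot.
    """
    X, n, k, _ = as_shot_arrays(records)
    phi = X[:, 0] if X.ndim == 2 else X
    if len(k) == 0:
        raise ValueError("no records")
    phi = np.clip(np.asarray(phi, dtype=float), 1e-9, 1.0 - 1e-9)
    grid = np.linspace(0.0, 1.0, int(round(1.0 / grid_resolution)) + 1)
    curve = np.array([_log_posterior(a, k, n, phi) for a in grid])
    i = int(np.argmax(curve))
    alpha_hat = float(grid[i])
    # local refinement inside the open interval
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi - lo > 1e-12 and 0.0 < alpha_hat < 1.0:
        res = minimize_scalar(
            lambda a: -_log_posterior(min(max(a, 1e-12), 1 - 1e-12), k, n, phi),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun >= curve[i]:
            alpha_hat = float(res.x)
    return AccuracyFit(alpha_hat, grid, curve, len(k))


PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def bootstrap_accuracy(
    records,
    chain_ids=None,
    n_cv: int = 10,
    n_boot: int = 100,
    seed: int = 0,
    fit: Optional[Callable] = None,
    min_chain_records: int = 10,
    grid_resolution: float = 1e-2,
) -> AccuracyFit:
    """Cross-validated bootstrap distribution of the accuracy alpha.

    Repeats ``n_cv`` times: hold out one MC chain (cycling through the
    chains), obtain committor estimates for it -- via ``fit(X_train, n, k,
    seed) -> model`` retrained on the held-in chains if given, else using the
    phi stored with the records -- then estimate alpha on ``n_boot``
    bootstrap resamples (with replacement) of the held-out chain.  All
    n_cv * n_boot draws are pooled into 2.5/25/50/75/97.5 percentiles (the
    box-and-whisker convention).  Chains with fewer than
    ``min_chain_records`` records are skipped.
    """
    X, n, k, chain = as_shot_arrays(records)
    if chain_ids is not None:
        chain = np.asarray(chain_ids)
    chains = np.unique(chain)
    if len(chains) < 2:
        raise ValueError("need at least 2 chains for cross-validation")
    rng = np.random.default_rng(seed)
    samples = []
    for r in range(n_cv):
        held = chains[r % len(chains)]
        val = chain == held
        if val.sum() < min_chain_records:
            continue
        if fit is not None:
            model = fit(X[~val], n[~val], k[~val], int(rng.integers(2**31)))
            phi_val = np.asarray(model.predict(X[val]), dtype=float)
        else:
            phi_val = X[val, 0]
        phi_val = np.clip(phi_val, 1e-9, 1 - 1e-9)
        kv, nv = k[val], n[val]
        m = len(kv)
        for _ in range(n_boot):
            idx = rng.integers(0, m, m)
            f = estimate_accuracy((phi_val[idx][:, None], nv[idx], kv[idx]),
                                  grid_resolution=grid_resolution)
            samples.append(f.alpha_hat)
    if not samples:
        raise ValueError("all chains skipped (too few records)")
    samples = np.asarray(samples)
    base = estimate_accuracy(records)
    pct = {p: float(np.percentile(samples, p)) for p in PERCENTILES}
    return AccuracyFit(base.alpha_hat, base.alpha_grid, base.log_posterior,
                       base.n_records, percentiles=pct, samples=samples)


# ---------------------------------------------------------------------------
# calibration against dedicated validation shots
# ---------------------------------------------------------------------------

@dataclass
class CalibrationFit:
    """Logit-logit line fit of observed vs predicted committor."""

    c: float  # slope
    d: float  # intercept
    alpha: float  # jointly estimated accuracy on the validation records
    n_shots: int  # shots per validation point (n_i)
    n_used: int  # records entering the line fit (k not in {0, n})

    def phi_lin(self, q) -> np.ndarray:
        """Bias-corrected committor phi_lin = sigmoid(c q + d)."""
        return expit(self.c * np.asarray(q, dtype=float) + self.d)

    def spread(self, q) -> np.ndarray:
        """Delta phi_lin = sqrt(1 - alpha (1 - 1/n)) sqrt(phi_lin (1 - phi_lin))."""
        p = self.phi_lin(q)
        return math.sqrt(max(1.0 - self.alpha * (1.0 - 1.0 / self.n_shots), 0.0)) * np.sqrt(p * (1.0 - p))


def calibration_fit(records, model=None) -> CalibrationFit:
    """Least-squares logit-logit calibration of a committor model.

    Records must carry validation-shot outcomes with n_i >= 2 (the study used
    n_i = 20) and the model committor phi_i (either stored, or recomputed via
    ``model.predict`` when the records carry feature vectors).  Records with
    k = 0 or k = n have infinite observed logit and are excluded from the
    line fit; the accuracy alpha entering the spread is estimated on all
    records.
    """
    X, n, k, _ = as_shot_arrays(records)
    if model is not None:
        phi = np.asarray(model.predict(X), dtype=float)
    else:
        phi = X[:, 0]
    phi = np.clip(phi, 1e-9, 1 - 1e-9)
    if np.any(n < 2):
        raise ValueError("calibration requires n_i >= 2 per record")
    usable = (k > 0) & (k < n)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 records with 0 < k < n")
    q_pred = np.log(phi[usable] / (1.0 - phi[usable]))
    q_obs = np.log(k[usable] / (n[usable] - k[usable]))
    A = np.stack([q_pred, np.ones_like(q_pred)], axis=1)
    (c, d), *_ = np.linalg.lstsq(A, q_obs, rcond=None)
    alpha = estimate_accuracy((phi[:, None], n, k)).alpha_hat
    return CalibrationFit(float(c), float(d), float(alpha),
                          int(np.max(n)), int(usable.sum()))
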