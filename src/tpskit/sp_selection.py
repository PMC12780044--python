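"""Shooting-point selection along the current transition path.

Shots launched near the phi = 0.5 iso-surface are the most informative
(P(TP|x) = 2 phi (1 - phi) peaks there), but pinning every shot to the
transition state would under-explore the path.  The target compromise is a
Cauchy(0, 1) distribution on the committor logit q = ln[phi/(1-phi)]: frames
of the current path are reweighted by Cauchy(q)/P(q|TP), where P(q|TP) is a
histogram estimate of the logit distribution over transition-path frames.
Selection starts uniform, the histogram is first built after 100 MC steps and
refreshed every 250.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import cauchy

logger = logging.getLogger(__name__)

__all__ = [
    "LogitHistogram",
    "SPSelector",
    "selection_weights",
    "selection_weights_from_logits",
    "select_sp",
    "update_schedule",
]

DEFAULT_BINS = 50
DEFAULT_CLIP = (-10.0, 10.0)
DEFAULT_BUILD_AT = 100
DEFAULT_REFRESH_EVERY = 250


@dataclass
class LogitHistogram:
    """Normalized histogram estimate of P(q | TP).

    Equal-width bins over the observed q-range clipped to ``clip``; the
    density integrates to 1 over the binned range.  ``floor`` (the smallest
    nonzero bin density) substitutes for empty bins during reweighting so
    that frames falling in unpopulated bins keep a finite weight.
    """

    edges: np.ndarray
    density: np.ndarray
    n_samples: int
    clip: tuple = DEFAULT_CLIP
    update_count: int = 0

    @classmethod
    def from_samples(cls, q, bins: int = DEFAULT_BINS, clip=DEFAULT_CLIP) -> "LogitHistogram":
        q = np.clip(np.asarray(q, dtype=float), clip[0], clip[1])
        lo, hi = float(q.min()), float(q.max())
        if hi - lo < 1e-9:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        counts, _ = np.histogram(q, bins=edges)
        dens = counts / (counts.sum() * np.diff(edges))
        return cls(edges, dens, int(len(q)), clip)

    @property
    def floor(self) -> float:
        nz = self.density[self.density > 0]
        return float(nz.min()) if nz.size else 1.0

    def lookup(self, q) -> np.ndarray:
        """Per-sample density with empty-bin flooring; out-of-range clamps."""
        q = np.clip(np.asarray(q, dtype=float), self.edges[0], self.edges[-1])
        idx = np.clip(np.searchsorted(self.edges, q, side="right") - 1, 0, len(self.density) - 1)
        d = self.density[idx]
        return np.where(d > 0, d, self.floor)


def selection_weights_from_logits(q, hist: LogitHistogram | None,
                                  eligible: np.ndarray | None = None) -> np.ndarray:
    """Normalized per-frame SP-selection probabilities from frame logits.

    With no histogram: uniform over eligible frames.  Otherwise
    w_i ~ Cauchy(q_i; 0, 1) / P_hat(q_i | TP); if every weight underflows to
    zero the selection falls back to uniform with a logged warning.
    Endpoints are ineligible (they lie inside states).
    """
    q = np.asarray(q, dtype=float)
    n = len(q)
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
        if n >= 2:
            eligible[0] = eligible[-1] = False
    w = np.zeros(n)
    if not eligible.any():
        raise ValueError("no eligible shooting-point frames")
    if hist is None:
        w[eligible] = 1.0
    else:
        qe = np.clip(q[eligible], hist.clip[0], hist.clip[1])
        w[eligible] = cauchy.pdf(qe) / hist.lookup(qe)
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        logger.warning("all SP-selection weights zero/non-finite; falling back to uniform")
        w[:] = 0.0
        w[eligible] = 1.0
        total = w.sum()
    return w / total


def selection_weights(path, model, hist: LogitHistogram | None,
                      featurize=None) -> np.ndarray:
    """Spec-level wrapper: weights over the frames of a Path object."""
    frames = np.asarray(path.frames, dtype=float)
    if hist is None or model is None:
        return selection_weights_from_logits(np.zeros(len(frames)), None)
    X = featurize(frames) if featurize is not None else frames
    q = model.logit(X)
    return selection_weights_from_logits(q, hist)


def select_sp(weights, rng_or_seed) -> int:
    """Categorical draw of a frame index from normalized weights."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("selection weights must be normalized")
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) else np.random.default_rng(rng_or_seed)
    return int(rng.choice(len(w), p=w))


def update_schedule(mc_index: int, build_at: int = DEFAULT_BUILD_AT,
                    refresh_every: int = DEFAULT_REFRESH_EVERY) -> str:
    """Histogram lifecycle: uniform before ``build_at``, build there, refresh
    every ``refresh_every`` steps after, reuse otherwise."""
    if mc_index < 0:
        raise ValueError("mc_index must be >= 0")
    if mc_index < build_at:
        return "uniform"
    if mc_index == build_at:
        return "build"
    if (mc_index - build_at) % refresh_every == 0:
        return "refresh"
    return "reuse"


@dataclass
class SPSelector:
    """Stateful SP selection for a TPS chain.

    Pools committor logits of the frames of accepted transition paths (that
    is what P(q|TP) conditions on), builds the histogram per
    ``update_schedule``, and turns any path into normalized per-frame
    selection weights.  With no model attached the selection stays uniform.
    """

    model: object | None = None
    featurize: object | None = None
    bins: int = DEFAULT_BINS
    clip: tuple = DEFAULT_CLIP
    build_at: int = DEFAULT_BUILD_AT
    refresh_every: int = DEFAULT_REFRESH_EVERY
    pool_max: int = 200_000
    hist: LogitHistogram | None = None
    _q_pool: list = field(default_factory=list)

    def _logits(self, frames: np.ndarray) -> np.ndarray:
        X = self.featurize(frames) if self.featurize is not None else frames
        return np.asarray(self.model.logit(X), dtype=float)

    def observe_path(self, path) -> None:
        """Register the interior frames of a newly accepted transition path."""
        if self.model is None:
            return
        frames = np.asarray(path.frames, dtype=float)
        if len(frames) > 2:
            self._q_pool.append(self._logits(frames[1:-1]))

    def maybe_update(self, mc_index: int) -> str:
        action = update_schedule(mc_index, self.build_at, self.refresh_every)
        if self.model is None:
            return "uniform"
        if action in ("build", "refresh") and self._q_pool:
            q = np.concatenate(self._q_pool)
            if len(q) > self.pool_max:
                q = q[-self.pool_max:]
            prev = self.hist.update_count if self.hist is not None else 0
            self.hist = LogitHistogram.from_samples(q, self.bins, self.clip)
            self.hist.update_count = prev + 1
        return action

    def weights_for(self, path) -> np.ndarray:
        frames = np.asarray(path.frames, dtype=float)
        if self.model is None or self.hist is None:
            return selection_weights_from_logits(np.zeros(len(frames)), None)
        return selection_weights_from_logits(self._logits(frames), self.hist)
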