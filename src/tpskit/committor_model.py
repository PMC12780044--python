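"""Parametric committor models trained on shooting outcomes.

The committor phi(x | w) is represented by a small feed-forward network built
from compression stages: each stage is a linear width reduction (with
train-time dropout) followed by a residual block of ELU layers, and the final
stage is a single linear unit producing the logit q(x); phi = sigmoid(q).
(A two-output softmax head is mathematically identical to the single-logit
sigmoid for a binary outcome, so the latter is used.)

Training minimizes the mean negative log-likelihood of two-way shooting
outcomes,

    -L(w)/N = -(1/N) sum_i ln[ C(n_i, k_i) phi(x_i)^k_i (1 - phi(x_i))^(n_i - k_i) ],

with an L2 weight penalty and early stopping at the minimum validation loss
(validation split by MC-chain id).  The network is implemented directly on
NumPy arrays -- forward, backpropagation (including gradients with respect to
the inputs, needed for reactive-flux analysis) and Adam are all contained in
this module, which keeps the likelihood, the logit access and the input
gradients exact and inspectable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "NetworkSpec",
    "CommittorModel",
    "TrainResult",
    "TrainingError",
    "build_network",
    "nll_loss",
    "binom_nll",
    "train",
    "p_tp",
    "as_shot_arrays",
]

PHI_EPS = 1e-7
_Q_CLAMP = math.log((1.0 - PHI_EPS) / PHI_EPS)  # |q| beyond this clamps phi


# ---------------------------------------------------------------------------
# network specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of a committor network.

    ``widths`` runs from the input dimension to the final scalar logit, e.g.
    (68, 46, 31, 21, 14, 10, 1) for the 68-feature flip-flop model or
    (147, 85, 50, 29, 14, 17, 1) for the pore-nucleation model.  Each
    interior step is a linear compression plus a residual ELU block of depth
    ``resnet_depth``; the last step is a bare linear unit.
    """

    widths: tuple
    resnet_depth: int = 4
    activation: str = "elu"
    dropout: float = 0.1
    l2: float = 1e-4

    def __post_init__(self):
        w = tuple(int(x) for x in self.widths)
        object.__setattr__(self, "widths", w)
        if len(w) < 2:
            raise ValueError("need at least input and output widths")
        if w[-1] != 1:
            raise ValueError("final width must be 1 (scalar logit)")
        if any(x < 1 for x in w):
            raise ValueError("widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation != "elu":
            raise ValueError("only ELU activation is supported")

    def to_json(self) -> str:
        return json.dumps(
            {"widths": list(self.widths), "resnet_depth": self.resnet_depth,
             "activation": self.activation, "dropout": self.dropout, "l2": self.l2}
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(tuple(d["widths"]), d["resnet_depth"], d["activation"],
                   d["dropout"], d["l2"])


# ---------------------------------------------------------------------------
# layers (NumPy forward/backward)
# ---------------------------------------------------------------------------

class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        # in place: optimizer instances hold references to dW/db
        np.matmul(self._x.T, dy, out=self.dW)
        np.sum(dy, axis=0, out=self.db)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]


class _ELU:
    def forward(self, x, train):
        neg = x <= 0.0
        self._deriv = np.where(neg, np.exp(np.minimum(x, 0.0)), 1.0)
        return np.where(neg, self._deriv - 1.0, x)

    def backward(self, dy):
        return dy * self._deriv

    def params(self):
        return []


class _Dropout:
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class _ResBlock:
    """x + f(x) with f a chain of ``depth`` (linear, ELU) pairs of equal width."""

    def __init__(self, width: int, depth: int, rng: np.random.Generator):
        self.chain = []
        for _ in range(depth):
            self.chain.append(_Linear(width, width, rng))
            self.chain.append(_ELU())

    def forward(self, x, train):
        h = x
        for layer in self.chain:
            h = layer.forward(h, train)
        return x + h

    def backward(self, dy):
        dh = dy
        for layer in reversed(self.chain):
            dh = layer.backward(dh)
        return dy + dh

    def params(self):
        out = []
        for layer in self.chain:
            out.extend(layer.params())
        return out


# ---------------------------------------------------------------------------
# the committor model
# ---------------------------------------------------------------------------

class CommittorModel:
    """Map features -> phi in (0, 1) with logit and input-gradient access."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = []
        w = spec.widths
        for i in range(len(w) - 2):
            self.layers.append(_Linear(w[i], w[i + 1], rng))
            self.layers.append(_Dropout(spec.dropout))
            self.layers.append(_ResBlock(w[i + 1], spec.resnet_depth, rng))
        self.layers.append(_Linear(w[-2], 1, rng))

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, train=False, rng=None):
        h = np.atleast_2d(np.asarray(X, dtype=float))
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                h = layer.forward(h, train, rng)
            else:
                h = layer.forward(h, train)
        return h[:, 0]

    def _backward(self, dq):
        dh = np.asarray(dq, dtype=float)[:, None]
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh

    def logit(self, X) -> np.ndarray:
        """Raw network output q(x) = ln[phi/(1-phi)]."""
        return self._forward(X, train=False)

    def predict(self, X) -> np.ndarray:
        """Committor estimate phi = sigmoid(q), strictly inside (0, 1)."""
        return expit(np.clip(self.logit(X), -_Q_CLAMP, _Q_CLAMP))

    def input_gradient(self, X) -> np.ndarray:
        """d phi / d x per sample, via backpropagation to the inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        q = self._forward(X, train=False)
        dq_dx = self._backward(np.ones(len(X)))
        phi = expit(np.clip(q, -_Q_CLAMP, _Q_CLAMP))
        return (phi * (1.0 - phi))[:, None] * dq_dx

    # -- parameter plumbing --------------------------------------------------
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _, _ in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (p, _, _), w in zip(self.params(), weights):
            p[...] = w

    # -- portable checkpoints (no pickled code) ------------------------------
    def save(self, path, feature_names: Sequence[str] | None = None) -> None:
        arrays = {f"w{i}": p for i, (p, _, _) in enumerate(self.params())}
        meta = {"spec": self.spec.to_json()}
        if feature_names is not None:
            meta["feature_names"] = json.dumps(list(feature_names))
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "CommittorModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(NetworkSpec.from_json(meta["spec"]))
        model.set_weights([data[f"w{i}"] for i in range(len(model.params()))])
        return model


def build_network(spec: NetworkSpec, seed: int = 0) -> CommittorModel:
    """Deterministically initialized committor network from a spec."""
    return CommittorModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# the shooting-outcome likelihood
# ---------------------------------------------------------------------------

def _ln_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def binom_nll(q, n, k) -> float:
    """Mean negative log-likelihood of shot outcomes given logits q.

    Includes the binomial coefficient; evaluated in the numerically stable
    log-sigmoid form with phi clamped to [eps, 1-eps], eps = 1e-7.
    """
    q = np.clip(np.asarray(q, dtype=float), -_Q_CLAMP, _Q_CLAMP)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    # ln sigmoid(q) = -ln(1 + e^{-q}), computed stably; NaN inputs (diverged
    # weights) propagate silently and are caught by the training guard
    with np.errstate(invalid="ignore"):
        log_phi = -np.logaddexp(0.0, -q)
        log_1mphi = -np.logaddexp(0.0, q)
    ll = _ln_binom(n, k) + k * log_phi + (n - k) * log_1mphi
    return float(-np.mean(ll))


def as_shot_arrays(records, featurize=None):
    """Normalize shooting records to (X, n, k, chain_id) arrays.

    Accepts a list of objects with attributes (x_sp, n, k, chain_id), a
    pandas DataFrame with columns (phi or x..., n, k), or a tuple of arrays.
    Records with k = None (unresolved shots) are dropped.
    """
    if isinstance(records, tuple):
        X, n, k = records[:3]
        chain = records[3] if len(records) > 3 else np.zeros(len(k), dtype=int)
        return (np.atleast_2d(np.asarray(X, dtype=float)),
                np.asarray(n), np.asarray(k), np.asarray(chain))
    if hasattr(records, "columns"):  # DataFrame
        cols = [c for c in records.columns if c.startswith("x")]
        X = records[cols].to_numpy(dtype=float) if cols else records[["phi"]].to_numpy(dtype=float)
        chain = records["chain_id"].to_numpy() if "chain_id" in records.columns else np.zeros(len(records), dtype=int)
        return X, records["n"].to_numpy(), records["k"].to_numpy(), chain
    recs = [r for r in records if r.k is not None]
    X = np.stack([np.atleast_1d(np.asarray(r.x_sp, dtype=float)) for r in recs])
    if featurize is not None:
        X = featurize(X)
    n = np.asarray([r.n for r in recs])
    k = np.asarray([r.k for r in recs])
    chain = np.asarray([getattr(r, "chain_id", 0) for r in recs])
    return X, n, k, chain


def nll_loss(records, model: CommittorModel, featurize=None) -> float:
    """Mean negative log-likelihood of shooting outcomes under the model."""
    X, n, k, _ = as_shot_arrays(records, featurize)
    if len(k) == 0:
        raise ValueError("no usable shooting records")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    return binom_nll(model.logit(X), n, k)


def p_tp(phi):
    """Transition-path probability of a two-way shot: P(TP|x) = 2 phi (1-phi)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("phi must lie in [0, 1]")
    out = 2.0 * phi * (1.0 - phi)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TrainingError(RuntimeError):
    pass


@dataclass
class TrainResult:
    train_curve: np.ndarray
    val_curve: np.ndarray
    best_epoch: int
    final_train_loss: float = field(init=False)

    def __post_init__(self):
        self.final_train_loss = float(self.train_curve[-1]) if len(self.train_curve) else math.nan


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, l2=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p) for p, _, _ in params]
        self.v = [np.zeros_like(p) for p, _, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for i, (p, g, is_weight) in enumerate(self.params):
            grad = g + self.l2 * p if is_weight else g
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            p -= self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)


def train(
    model: CommittorModel,
    records,
    cv_chain_ids: Sequence[int] | None = None,
    epochs_max: int = 300,
    seed: int = 0,
    *,
    lr: float = 1e-3,
    batch_size: int = 256,
    patience: int = 50,
    featurize=None,
    val_fraction: float = 0.2,
) -> TrainResult:
    """Fit the committor to shooting records with early stopping.

    Validation records are those whose chain id is in ``cv_chain_ids`` (by
    default the last chain); with a single chain a random ``val_fraction``
    split is used instead.  Training minimizes the mean shot NLL plus the
    spec's L2 penalty with Adam; the weights at the minimum validation loss
    are restored on return.  Raises :class:`TrainingError` (with the epoch
    index) if the loss turns non-finite.
    """
    X, n, k, chain = as_shot_arrays(records, featurize)
    if len(k) < 4:
        raise ValueError("too few records to train")
    rng = np.random.default_rng(seed)

    chains = np.unique(chain)
    if cv_chain_ids is None and len(chains) >= 2:
        cv_chain_ids = [chains[-1]]
    if cv_chain_ids is not None and len(chains) >= 2:
        val_mask = np.isin(chain, cv_chain_ids)
        if not val_mask.any() or val_mask.all():
            raise ValueError("validation chain split is empty or total")
    else:
        val_mask = rng.random(len(k)) < val_fraction
        if not val_mask.any():
            val_mask[rng.integers(len(k))] = True
    tr = ~val_mask
    Xt, nt, kt = X[tr], n[tr], k[tr]
    Xv, nv, kv = X[val_mask], n[val_mask], k[val_mask]

    opt = _Adam(model.params(), lr=lr, l2=model.spec.l2)
    n_train = len(kt)
    train_curve, val_curve = [], []
    best = (math.inf, -1, model.get_weights())

    for epoch in range(epochs_max):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, batch_size):
            idx = order[start:start + batch_size]
            q = model._forward(Xt[idx], train=True, rng=rng)
            phi = expit(np.clip(q, -_Q_CLAMP, _Q_CLAMP))
            # d(mean NLL)/dq = (n*phi - k) / batch
            dq = (nt[idx] * phi - kt[idx]) / len(idx)
            model._backward(dq)
            opt.step()
            epoch_loss += binom_nll(q, nt[idx], kt[idx]) * len(idx)
        epoch_loss /= n_train
        v = binom_nll(model.logit(Xv), nv, kv)
        if not (math.isfinite(epoch_loss) and math.isfinite(v)):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        train_curve.append(epoch_loss)
        val_curve.append(v)
        if v < best[0] - 1e-6:
            best = (v, epoch, model.get_weights())
        elif epoch - best[1] >= patience:
            break

    model.set_weights(best[2])
    return TrainResult(np.asarray(train_curve), np.asarray(val_curve), best[1])
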