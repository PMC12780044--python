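"""Post-hoc mechanism discovery from a trained committor.

If the committor is effectively a function of one linear combination of the
input features, phi(x) ~ f(x . v), then the reactive-flux direction
v(phi) = <grad phi>_phi / |<grad phi>_phi| -- the normalized committor
gradient averaged on iso-committor surfaces -- is the same unit vector on
every surface.  This module estimates v globally and per phi-bin, scores
linearity by the minimum pairwise cosine between bin directions, projects
data onto v, refits low-dimensional committor models on such projections,
and provides k-nearest-neighbor density and committor-iso-surface estimates
for 2D projections of the transition-path ensemble.  A separate classifier
labels each TPS MC step as pore-mediated or tunneling from the smoothed
time-averaged pore coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from . import committor_model as cm
from .tps_core import smooth_series

__all__ = [
    "FluxDirection",
    "ProjectionField",
    "flux_direction",
    "project_features",
    "fit_lowdim_committor",
    "knn_density",
    "knn_committor_surface",
    "classify_mechanism",
]


@dataclass
class FluxDirection:
    """Global and per-phi-bin reactive-flux directions in feature space."""

    v: np.ndarray  # global unit vector
    bin_centers: np.ndarray
    bin_directions: np.ndarray  # (n_bins, n_features), unit rows
    cosine_matrix: np.ndarray  # pairwise cosines between bin directions
    linearity_score: float  # min pairwise cosine ("hardly changes with phi")
    feature_std: Optional[np.ndarray] = None
    feature_names: Optional[tuple] = None


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero gradient vector")
    return v / nrm


def flux_direction(
    model,
    samples: np.ndarray,
    phi_bins: int = 10,
    phi_range: tuple = (0.05, 0.95),
    standardize: bool = True,
    feature_names: Sequence[str] | None = None,
) -> FluxDirection:
    """Iso-committor-averaged committor gradient directions.

    ``model`` must expose ``predict`` and ``input_gradient``.  Samples whose
    phi falls outside ``phi_range`` are excluded (near the state boundaries
    a quasi-linear committor has to fail, so those gradients carry no
    mechanism signal).  With ``standardize`` the gradient is taken with
    respect to z-scored features (gradients multiplied by per-feature std
    over the sample set), so that v is comparable across heterogeneous
    units.  Empty bins are omitted with a warning entry.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    phi = np.asarray(model.predict(samples), dtype=float)
    grads = np.asarray(model.input_gradient(samples), dtype=float)
    std = samples.std(axis=0, ddof=0) if standardize else np.ones(samples.shape[1])
    std = np.where(std > 0, std, 1.0)
    grads = grads * std  # chain rule to standardized coordinates

    lo, hi = phi_range
    keep = (phi > lo) & (phi < hi)
    if not keep.any():
        raise ValueError("no samples inside the phi range")
    edges = np.linspace(lo, hi, phi_bins + 1)
    centers, dirs = [], []
    for i in range(phi_bins):
        sel = keep & (phi >= edges[i]) & (phi < edges[i + 1])
        if not sel.any():
            continue
        centers.append(0.5 * (edges[i] + edges[i + 1]))
        dirs.append(_unit(grads[sel].mean(axis=0)))
    dirs = np.asarray(dirs)
    v = _unit(grads[keep].mean(axis=0))
    cos = dirs @ dirs.T
    score = float(cos.min()) if len(dirs) else float("nan")
    return FluxDirection(v, np.asarray(centers), dirs, cos, score,
                         feature_std=std if standardize else None,
                         feature_names=tuple(feature_names) if feature_names else None)


def project_features(samples: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scalar reaction coordinate x . v per sample."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    v = np.asarray(v, dtype=float)
    if samples.shape[1] != v.shape[0]:
        raise ValueError(
            f"dimension mismatch: samples have {samples.shape[1]} features, v has {v.shape[0]}"
        )
    return samples @ v


def fit_lowdim_committor(
    records,
    inputs: np.ndarray,
    chain_ids=None,
    spec: cm.NetworkSpec | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.25,
    **train_kwargs,
):
    """Train a small committor model on hand-picked coordinates.

    ``inputs`` holds the low-dimensional coordinates per record (e.g. z,
    xi_P and the linear projection x . v).  Returns ``(model, result,
    alpha)`` where alpha is the accuracy of the low-dimensional model on a
    held-out subset -- the quantity to compare against the full model.
    """
    _, n, k, chain = cm.as_shot_arrays(records)
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[0] != len(k):
        raise ValueError("inputs and records length mismatch")
    if spec is None:
        spec = cm.NetworkSpec((X.shape[1], 8, 8, 1), dropout=0.0, l2=1e-5)
    if chain_ids is not None:
        chain = np.asarray(chain_ids)
    rng = np.random.default_rng(seed)
    hold = rng.random(len(k)) < holdout_fraction
    model = cm.build_network(spec, seed=seed)
    result = cm.train(model, (X[~hold], n[~hold], k[~hold], chain[~hold]),
                      seed=seed, **train_kwargs)
    phi_hold = model.predict(X[hold])
    alpha = None
    if hold.sum() >= 10:
        from .diagnostics import estimate_accuracy

        alpha = estimate_accuracy((phi_hold[:, None], n[hold], k[hold])).alpha_hat
    return model, result, alpha


def knn_density(
    points_2d: np.ndarray,
    k: int = 50,
    eval_points: np.ndarray | None = None,
    normalize_on: np.ndarray | None = None,
) -> np.ndarray:
    """k-nearest-neighbor density in 2D: rho ~ r_k^-2.

    ``r_k`` is the radius of the smallest circle around each evaluation
    point containing ``k`` data points.  Duplicate points with r = 0 are
    floored at machine scale.  With ``normalize_on`` (a regular grid of
    evaluation points with uniform cell area) the density is rescaled to
    integrate to 1 over that grid.
    """
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    if k < 2 or len(pts) < k:
        raise ValueError("require 2 <= k <= number of points")
    ev = pts if eval_points is None else np.atleast_2d(np.asarray(eval_points, dtype=float))
    nn = NearestNeighbors(n_neighbors=k).fit(pts)
    r = nn.kneighbors(ev)[0][:, -1]
    r = np.maximum(r, np.finfo(float).tiny ** 0.25)
    dens = r**-2.0
    if normalize_on is not None:
        g = np.atleast_2d(np.asarray(normalize_on, dtype=float))
        rg = nn.kneighbors(g)[0][:, -1]
        rg = np.maximum(rg, np.finfo(float).tiny ** 0.25)
        xs, ys = np.unique(g[:, 0]), np.unique(g[:, 1])
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        dens = dens / ((rg**-2.0).sum() * cell)
    return dens


@dataclass
class ProjectionField:
    """Committor field on a 2D grid via k-NN feature averaging."""

    grid: np.ndarray  # (G, 2) evaluation nodes in (s, t)
    mean_features: np.ndarray  # (G, n_features) local feature averages <x>_{s,t}
    projection: np.ndarray  # (G,) <x>_{s,t} . v
    phi: np.ndarray  # (G,) quasi-linear committor at the node
    k: int
    out_of_support: np.ndarray  # (G,) bool, nodes far from any data


def knn_committor_surface(
    samples_st: np.ndarray,
    features: np.ndarray,
    grid: np.ndarray,
    k: int,
    v: np.ndarray,
    phi_of_projection: Callable[[np.ndarray], np.ndarray],
    support_factor: float = 3.0,
) -> ProjectionField:
    """Quasi-linear committor iso-surfaces in a 2D projection.

    For each grid node in the (s, t) plane, the feature vectors of its k
    nearest samples are averaged, projected onto v, and passed through the
    1D committor ``phi_of_projection`` -- phi(<x>_{s,t} . v).  Nodes whose
    k-th-neighbor radius exceeds ``support_factor`` times the median radius
    are flagged as outside the data support (no extrapolation is attempted;
    the flag is reported, values are still returned).
    """
    st = np.atleast_2d(np.asarray(samples_st, dtype=float))
    X = np.atleast_2d(np.asarray(features, dtype=float))
    G = np.atleast_2d(np.asarray(grid, dtype=float))
    if k > len(st):
        raise ValueError("k exceeds the number of samples")
    nn = NearestNeighbors(n_neighbors=k).fit(st)
    dist, idx = nn.kneighbors(G)
    mean_feats = X[idx].mean(axis=1)
    proj = mean_feats @ np.asarray(v, dtype=float)
    phi = np.asarray(phi_of_projection(proj), dtype=float)
    r_k = dist[:, -1]
    flagged = r_k > support_factor * np.median(r_k)
    return ProjectionField(G, mean_feats, proj, phi, k, flagged)


def classify_mechanism(xi_series, threshold: float = 1.0, window: int = 10):
    """Label each TPS MC step as pore (Pi_P) or tunneling (Pi_T).

    The time-averaged pore coordinate xi_hat per MC step is smoothed over
    ``window`` steps; values >= ``threshold`` indicate a membrane-spanning
    water pore.  Returns ``(labels, switches)`` where labels is an array of
    "P"/"T" and switches lists the indices where the label changes.
    """
    xi = np.asarray(xi_series, dtype=float)
    if xi.ndim != 1 or len(xi) == 0:
        raise ValueError("xi_series must be a non-empty 1D series")
    sm = smooth_series(xi, window=window)
    labels = np.where(sm >= threshold, "P", "T")
    switches = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
    return labels, switches
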