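"""The membrane pore reaction coordinate xi_P and pore-lifetime estimation.

xi_P combines pore nucleation with pore expansion on a particle
configuration (positions, particle types, periodic box):

* the "pore chain" xi_ch in [0, 1] asks what fraction of the membrane region
  -- ``N_slabs`` equal slabs along z at the nucleation center -- is already
  occupied by polar particles (headgroup P/N, water O) within a lateral
  cylinder of radius ``R_cyl``;
* the pore radius R is estimated from the count of waters inside a lateral
  cutoff ``D`` across the membrane region, assuming a cylindrical pore:
  R = sqrt(N_w v_w / (pi Z_mem)) with v_w the volume per water;
* xi_P = xi_ch / xi_ch_s while the chain is incomplete (xi_ch < xi_ch_s) and
  1 + max(0, R - R_0)/R_0 once nucleated, continuous at the switch.  xi_P > 1
  indicates a membrane-spanning water pore; R_0 is the radius of a just
  fully nucleated pore.

The nucleation center is a weighted circular mean of the headgroup positions
over the periodic box, with Gaussian weight in the axial distance from the
midplane so that midplane-proximal (pore-lining) heads dominate.

Pore lifetimes from free runs terminated either at spontaneous pore closure
or at a wall time are pooled with the censored-exponential maximum-likelihood
estimator tau = sum_i t_i / n (all durations, censored included, over the
number of observed closures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .toy_systems import MembraneConfig

__all__ = [
    "PoreParams",
    "PoreState",
    "LifetimeFit",
    "pore_center",
    "xi_chain",
    "pore_radius",
    "xi_p",
    "depletion_features",
    "pore_lifetime_mle",
]

POLAR_TYPES = ("head_P", "head_N", "water_O")
HEAD_TYPES = ("head_P", "head_N")


@dataclass(frozen=True)
class PoreParams:
    """Geometry parameters of the pore coordinate (lengths in nm)."""

    N_slabs: int = 4
    Z_mem: float = 1.8  # membrane-region thickness probed by the chain
    R_cyl: float = 1.0  # lateral radius of the chain cylinder
    D: float = 1.2  # lateral cutoff for water counting
    xi_ch_s: float = 0.9  # chain value at which the coordinate switches to expansion
    R0: float = 0.38  # radius of a just fully nucleated pore
    v_w: float = 0.030  # volume per water, nm^3 (bulk density)

    def __post_init__(self):
        if min(self.Z_mem, self.R_cyl, self.D, self.R0, self.v_w) <= 0 or self.N_slabs < 1:
            raise ValueError("all lengths must be positive, N_slabs >= 1")
        if not 0.0 < self.xi_ch_s <= 1.0:
            raise ValueError("xi_ch_s must lie in (0, 1]")

    @classmethod
    def martini(cls) -> "PoreParams":
        """Coarse-grained parameter set: 4 slabs over Z_mem = 1.8 nm,
        R_cyl = 1.0 nm, D = 1.2 nm, switch at xi_ch_s = 0.9, R0 = 0.38 nm."""
        return cls()

    @classmethod
    def atomistic(cls) -> "PoreParams":
        """Nominal atomistic set: a finer 10-slab chain over the same
        membrane region (the coarse set above is the one with published
        values; this preset only refines the subdivision)."""
        return cls(N_slabs=10)


def _lateral_delta(xy: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image lateral displacement vectors to the center."""
    d = xy - center
    d -= box[:2] * np.round(d / box[:2])
    return d


def pore_center(config: MembraneConfig, params: PoreParams) -> np.ndarray:
    """Nucleation center (x, y): weighted circular mean of the headgroups.

    Per lateral axis the head positions are mapped to angles on the periodic
    box and averaged with Gaussian weight exp(-(z - midplane)^2 / (2 w^2)),
    w = Z_mem / 2, so heads pulled toward the midplane (the pore lining)
    dominate.  Equivariant under periodic translation of the configuration.
    """
    heads = config.select(*HEAD_TYPES)
    if len(heads) == 0:
        raise ValueError("configuration has no head particles")
    w = np.exp(-((heads[:, 2] - config.midplane_z) ** 2) / (2.0 * (params.Z_mem / 2.0) ** 2))
    if w.sum() <= 1e-300:
        raise ValueError("zero total head weight")
    center = np.empty(2)
    for ax in range(2):
        theta = 2.0 * math.pi * heads[:, ax] / config.box[ax]
        c = float(np.sum(w * np.cos(theta)))
        s = float(np.sum(w * np.sin(theta)))
        center[ax] = (math.atan2(s, c) % (2.0 * math.pi)) * config.box[ax] / (2.0 * math.pi)
    return center


def xi_chain(config: MembraneConfig, center: np.ndarray, params: PoreParams):
    """Chain coordinate: fraction of membrane slabs occupied by polar atoms.

    The region [midplane - Z_mem/2, midplane + Z_mem/2] is split into
    ``N_slabs`` equal slabs; a slab is occupied (1) when at least one polar
    particle lies in it within lateral distance R_cyl of the center.
    Returns (xi_ch, per-slab occupancies).
    """
    polar = config.select(*POLAR_TYPES)
    occ = np.zeros(params.N_slabs)
    if len(polar):
        lat = np.linalg.norm(_lateral_delta(polar[:, :2], np.asarray(center), config.box), axis=1)
        inside = polar[lat <= params.R_cyl]
        z = inside[:, 2] - (config.midplane_z - params.Z_mem / 2.0)
        slab = np.floor(z / (params.Z_mem / params.N_slabs)).astype(int)
        ok = (slab >= 0) & (slab < params.N_slabs)
        occ[np.unique(slab[ok])] = 1.0
    return float(occ.mean()), occ


def pore_radius(config: MembraneConfig, center: np.ndarray, params: PoreParams) -> float:
    """Cylindrical pore radius from the water count in the membrane region.

    N_w waters within lateral distance D of the center and |z - midplane| <
    Z_mem/2 give R = sqrt(N_w v_w / (pi Z_mem)).
    """
    waters = config.select("water_O")
    if len(waters) == 0:
        return 0.0
    lat = np.linalg.norm(_lateral_delta(waters[:, :2], np.asarray(center), config.box), axis=1)
    axial = np.abs(waters[:, 2] - config.midplane_z)
    n_w = int(np.sum((lat <= params.D) & (axial < params.Z_mem / 2.0)))
    return math.sqrt(n_w * params.v_w / (math.pi * params.Z_mem))


@dataclass
class PoreState:
    """Evaluated pore coordinate and its constituents for one configuration."""

    center: np.ndarray
    xi_ch: float
    R: float
    xi_p: float
    occupancies: np.ndarray


def xi_p(config: MembraneConfig, params: PoreParams | None = None,
         center: np.ndarray | None = None) -> PoreState:
    """Combined pore coordinate.

    xi_P = xi_ch / xi_ch_s below the switch (xi_ch < xi_ch_s) and
    1 + max(0, R - R0)/R0 at or above it; the two branches join continuously
    at xi_P = 1 for a just fully nucleated pore of radius R0.
    """
    if params is None:
        params = PoreParams.martini()
    if center is None:
        center = pore_center(config, params)
    chain, occ = xi_chain(config, center, params)
    R = pore_radius(config, center, params)
    if chain < params.xi_ch_s:
        value = chain / params.xi_ch_s
    else:
        value = 1.0 + max(0.0, R - params.R0) / params.R0
    return PoreState(np.asarray(center), chain, R, value, occ)


# ---------------------------------------------------------------------------
# depletion / nearest-neighbor distance features
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = {
    "waterO": ("water_O",),
    "P": ("head_P",),
    "NP": ("head_P", "head_N"),
    "NPw": ("head_P", "head_N", "water_O"),
    "tailC": ("tail_C",),
    "allC": ("tail_C",),
}
_RANKS = (1, 2, 3)
_MEANS = (2, 3, 4, 5, 10)


def depletion_features(config: MembraneConfig, center: np.ndarray,
                       atom_groups: dict | None = None,
                       params: PoreParams | None = None) -> dict:
    """Sorted nearest-neighbor distances of atom groups to the pore center.

    For each group and each metric -- isotropic 3D distance to the center at
    the midplane, lateral (xy) distance, and axial distance |z - midplane| --
    reports the 1st/2nd/3rd nearest-neighbor distance and the means over the
    first 2, 3, 4, 5 and 10.  Features whose group is smaller than the
    requested rank are NaN (missing).  Additionally ``dz_NP14_max``: per
    leaflet, the mean axial distance of the 4 axially nearest N/P atoms, and
    the larger of the two leaflet means -- the headgroup-depletion feature of
    the nucleation committor.
    """
    if atom_groups is None:
        atom_groups = DEFAULT_GROUPS
    center = np.asarray(center, dtype=float)
    mid = config.midplane_z
    feats: dict[str, float] = {}

    def metric_distances(pos: np.ndarray) -> dict[str, np.ndarray]:
        lat_vec = _lateral_delta(pos[:, :2], center, config.box)
        lat = np.linalg.norm(lat_vec, axis=1)
        axial = np.abs(pos[:, 2] - mid)
        iso = np.hypot(lat, axial)
        return {"iso": np.sort(iso), "lateral": np.sort(lat), "axial": np.sort(axial)}

    for gname, types in atom_groups.items():
        pos = config.select(*types)
        dists = metric_distances(pos) if len(pos) else {m: np.empty(0) for m in ("iso", "lateral", "axial")}
        for metric, d in dists.items():
            for r in _RANKS:
                feats[f"{gname}_{metric}_d{r}"] = float(d[r - 1]) if len(d) >= r else math.nan
            for m in _MEANS:
                feats[f"{gname}_{metric}_mean{m}"] = float(d[:m].mean()) if len(d) >= m else math.nan

    # largest per-leaflet depletion of the 4 axially nearest N/P atoms
    np_pos = config.select(*HEAD_TYPES)
    leaflet_means = []
    for sel in (np_pos[:, 2] >= mid, np_pos[:, 2] < mid):
        axial = np.sort(np.abs(np_pos[sel, 2] - mid))
        leaflet_means.append(float(axial[:4].mean()) if len(axial) >= 4 else math.nan)
    feats["dz_NP14_upper"] = leaflet_means[0]
    feats["dz_NP14_lower"] = leaflet_means[1]
    feats["dz_NP14_max"] = float(np.nanmax(leaflet_means)) if not all(map(math.isnan, leaflet_means)) else math.nan
    return feats


# ---------------------------------------------------------------------------
# censored-exponential pore lifetime
# ---------------------------------------------------------------------------

@dataclass
class LifetimeFit:
    """Censored-exponential MLE of the mean open-pore lifetime."""

    tau_hat: float
    n_events: int  # observed closures
    n_total: int
    rate_grid: np.ndarray
    log_likelihood: np.ndarray

    def loglik(self, rate: float) -> float:
        """Profile log-likelihood L(k) = n ln k - k * sum(t)."""
        return self.n_events * math.log(rate) - rate * self._t_sum

    _t_sum: float = 0.0


def pore_lifetime_mle(durations, censored_flags) -> LifetimeFit:
    """Maximum-likelihood mean lifetime from randomly censored exponentials.

    tau = sum_i t_i / n: aggregate open time (censored runs included at their
    termination time) over the number n of observed closures.  This maximizes
    L(k) = prod_closed k e^{-k t_i} * prod_censored e^{-k t_i} for the rate
    k = 1/tau; the profile log-likelihood over a rate grid around the MLE is
    returned for inspection.  With zero observed closures only a lower bound
    on tau exists and an error is raised.
    """
    t = np.asarray(durations, dtype=float)
    cen = np.asarray(censored_flags, dtype=bool)
    if t.shape != cen.shape:
        raise ValueError("durations and censored_flags must align")
    if np.any(t < 0):
        raise ValueError("durations must be non-negative")
    n_events = int(np.sum(~cen))
    if n_events == 0:
        raise ValueError("no observed closures; only a lower bound on tau exists")
    t_sum = float(t.sum())
    tau = t_sum / n_events
    k_hat = 1.0 / tau
    grid = np.linspace(0.2 * k_hat, 5.0 * k_hat, 401)
    ll = n_events * np.log(grid) - grid * t_sum
    fit = LifetimeFit(tau, n_events, len(t), grid, ll)
    fit._t_sum = t_sum
    return fit
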