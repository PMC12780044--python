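"""Synthetic systems with known answers.

Desk-scale surrogates for the molecular-dynamics side of an AI-guided
transition-path-sampling (TPS) study of lipid flip-flop: bistable Langevin
dynamics (optionally with two competing transition channels, the analogues of
"tunneling" and "pore-mediated" flip-flop), enumerable discrete chains that
serve as exact oracles for the TPS target ensemble, membrane-like point
configurations with plantable water pores, beta-binomially dispersed committor
shot outcomes, and randomly censored exponential lifetimes.

Everything downstream (the TPS chain, committor training, diagnostics, pore
geometry) is tested against these generators, so every default here is chosen
to mimic the scale of the real study: lengths in nm, energies in kT, leaflet
separation ~2.6 nm echoing the |z| = 1.3 nm state boundaries of a DMPC
bilayer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Potential",
    "TrajectorySegment",
    "DiscreteChainSpec",
    "MembraneConfig",
    "make_double_well_1d",
    "make_two_channel_2d",
    "simulate_overdamped",
    "shoot_committor_batch",
    "analytic_committor_1d",
    "boltzmann_density_1d",
    "simulate_discrete",
    "discrete_committor",
    "enumerate_tpe_discrete",
    "generate_membrane_config",
    "generate_shot_records",
    "generate_censored_lifetimes",
]


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Potential:
    """Analytic potential-energy surface in kT units.

    ``energy`` and ``gradient`` are vectorized: for ``dim == 1`` they map
    shape ``(...,)`` to ``(...,)``; for ``dim == 2`` shape ``(..., 2)`` to
    ``(...,)`` / ``(..., 2)``.  ``grad_scalar`` is a low-overhead scalar
    evaluation used by the sequential propagator.
    """

    dim: int
    params: dict
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    grad_scalar: Callable


def make_double_well_1d(barrier_kT: float = 5.0, x_min_sep: float = 2.0) -> Potential:
    """Symmetric quartic double well U(x) = h ((x/a)^2 - 1)^2 with a = sep/2.

    Minima at +-a with U = 0; barrier of height ``barrier_kT`` at x = 0.
    """
    if barrier_kT <= 0:
        raise ValueError("barrier_kT must be positive")
    if x_min_sep <= 0:
        raise ValueError("x_min_sep must be positive")
    h = float(barrier_kT)
    a = float(x_min_sep) / 2.0
    inv_a2 = 1.0 / (a * a)

    def energy(x):
        x = np.asarray(x, dtype=float)
        t = x * x * inv_a2 - 1.0
        return h * t * t

    def gradient(x):
        x = np.asarray(x, dtype=float)
        t = x * x * inv_a2 - 1.0
        return 4.0 * h * inv_a2 * x * t

    def grad_scalar(x: float) -> float:
        t = x * x * inv_a2 - 1.0
        return 4.0 * h * inv_a2 * x * t

    return Potential(
        dim=1,
        params={"barrier_kT": h, "x_min_sep": float(x_min_sep), "a": a},
        energy=energy,
        gradient=gradient,
        grad_scalar=grad_scalar,
    )


def make_two_channel_2d(
    barrier_T_kT: float = 7.0,
    barrier_P_kT: float = 10.0,
    intermediate_depth_kT: float = 1.0,
    *,
    x0: float = 1.0,
    y0: float = 1.4,
    sigma_x: float = 0.35,
    sigma_y: float = 0.42,
    eps_conf: float = 1.0,
) -> Potential:
    """Bistable 2D surface with two competing transition channels.

    Two wells at (+-x0, 0) are separated by a Gaussian ridge along x = 0.
    Channel T crosses the ridge directly through a gate at (0, 0) with barrier
    ~``barrier_T_kT``; channel P detours through a metastable intermediate at
    (0, y0) -- the analogue of a transient pore -- reached over a barrier
    ~``barrier_P_kT`` (the harmonic cost of raising y), with the intermediate
    sitting ``intermediate_depth_kT`` below its exit saddles.  The relative
    barrier heights set which channel carries the transition flux.

    The stated barriers are approximate (Gaussian tails overlap at the percent
    level); tests that need exact stationary points locate them numerically.
    """
    for name, v in (
        ("barrier_T_kT", barrier_T_kT),
        ("barrier_P_kT", barrier_P_kT),
        ("intermediate_depth_kT", intermediate_depth_kT),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    kappa = 2.0 * barrier_P_kT / (y0 * y0)
    h_wall = max(barrier_T_kT, barrier_P_kT) + intermediate_depth_kT + 4.0
    g_T = h_wall - barrier_T_kT + eps_conf
    g_P = h_wall + intermediate_depth_kT + eps_conf
    inv_x02 = 1.0 / (x0 * x0)
    isx2 = 1.0 / (2.0 * sigma_x * sigma_x)
    isy2 = 1.0 / (2.0 * sigma_y * sigma_y)

    def energy(xy):
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        t = x * x * inv_x02 - 1.0
        wall = np.exp(-x * x * isx2)
        return (
            eps_conf * t * t
            + 0.5 * kappa * y * y
            + h_wall * wall
            - g_T * wall * np.exp(-y * y * isy2)
            - g_P * wall * np.exp(-((y - y0) ** 2) * isy2)
        )

    def gradient(xy):
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        t = x * x * inv_x02 - 1.0
        wall = np.exp(-x * x * isx2)
        e_T = np.exp(-y * y * isy2)
        e_P = np.exp(-((y - y0) ** 2) * isy2)
        gate = h_wall - g_T * e_T - g_P * e_P
        gx = 4.0 * eps_conf * inv_x02 * x * t + gate * wall * (-2.0 * x * isx2)
        gy = (
            kappa * y
            + g_T * wall * e_T * (2.0 * y * isy2)
            + g_P * wall * e_P * (2.0 * (y - y0) * isy2)
        )
        return np.stack([gx, gy], axis=-1)

    def grad_scalar(x: float, y: float):
        t = x * x * inv_x02 - 1.0
        wall = math.exp(-x * x * isx2)
        e_T = math.exp(-y * y * isy2)
        dy0 = y - y0
        e_P = math.exp(-dy0 * dy0 * isy2)
        gate = h_wall - g_T * e_T - g_P * e_P
        gx = 4.0 * eps_conf * inv_x02 * x * t - gate * wall * 2.0 * x * isx2
        gy = (
            kappa * y
            + g_T * wall * e_T * 2.0 * y * isy2
            + g_P * wall * e_P * 2.0 * dy0 * isy2
        )
        return gx, gy

    return Potential(
        dim=2,
        params={
            "barrier_T_kT": float(barrier_T_kT),
            "barrier_P_kT": float(barrier_P_kT),
            "intermediate_depth_kT": float(intermediate_depth_kT),
            "x0": x0,
            "y0": y0,
            "sigma_x": sigma_x,
            "sigma_y": sigma_y,
            "eps_conf": eps_conf,
            "kappa": kappa,
            "h_wall": h_wall,
        },
        energy=energy,
        gradient=gradient,
        grad_scalar=grad_scalar,
    )


# ---------------------------------------------------------------------------
# overdamped Langevin propagation
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySegment:
    """One propagated segment of overdamped dynamics.

    ``status`` is "ok" when the segment terminated by entering a state (or ran
    its full length with ``stop_on_state=False``) and "unresolved" when
    ``max_steps`` was exhausted before reaching any state.
    """

    frames: np.ndarray  # (n_frames, dim)
    dt: float
    seed: int
    terminal_state: str | None
    status: str = "ok"

    @property
    def duration(self) -> float:
        return (len(self.frames) - 1) * self.dt


def _threshold_states(state_defs) -> list[tuple[str, int, float, float]] | None:
    """Extract (name, axis, lo, hi) interval form if every state is one."""
    out = []
    for s in state_defs:
        axis = getattr(s, "axis", None)
        below = getattr(s, "below", None)
        above = getattr(s, "above", None)
        if getattr(s, "indicator", None) is not None or axis is None:
            return None
        if below is None and above is None:
            return None
        lo = -math.inf if below is None else below
        hi = math.inf if above is None else above
        # in state when coord < below  OR  coord > above
        out.append((s.name, axis, lo, hi))
    return out


def simulate_overdamped(
    potential: Potential,
    x0,
    dt: float,
    beta: float,
    max_steps: int,
    seed: int,
    state_defs: Sequence = (),
    stop_on_state: bool = True,
    noise_scale: float | None = None,
) -> TrajectorySegment:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

    dx = -grad U(x) dt + sqrt(2 dt / beta) * N(0, 1), in kT units with unit
    friction.  ``noise_scale`` overrides the thermal noise amplitude (0 gives
    the deterministic zero-temperature limit).  With ``stop_on_state`` the
    trajectory halts at the first frame inside any state, so that frame is the
    only one inside a state.  Reproducible for a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * dt / beta) if noise_scale is None else float(noise_scale)
    dim = potential.dim
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (dim,):
        raise ValueError(f"x0 must have shape ({dim},)")

    thr = _threshold_states(state_defs) if state_defs else []
    frames = np.empty((max_steps + 1, dim))
    frames[0] = x0
    terminal: str | None = None
    status = "ok"

    def in_state(frame) -> str | None:
        if thr is not None and thr != []:
            for name, axis, lo, hi in thr:
                c = frame[axis]
                if c < lo or c > hi:
                    return name
            return None
        for s in state_defs:
            if s.contains(frame):
                return s.name
        return None

    if state_defs and in_state(x0) is not None and stop_on_state:
        return TrajectorySegment(frames[:1].copy(), dt, seed, in_state(x0))

    n = 1
    block = 4096
    if dim == 1:
        x = float(x0[0])
        gs = potential.grad_scalar
        lo = hi = None
        if thr:
            # single-axis thresholds: precompute for the scalar loop
            bounds = [(name, l, h) for name, _ax, l, h in thr]
        step = 0
        while step < max_steps:
            noise = rng.standard_normal(min(block, max_steps - step))
            for z in noise:
                x = x - gs(x) * dt + sigma * z
                frames[n, 0] = x
                n += 1
                step += 1
                if state_defs:
                    hit = None
                    if thr:
                        for name, l, h in bounds:
                            if x < l or x > h:
                                hit = name
                                break
                    else:
                        hit = in_state(frames[n - 1])
                    if hit is not None and stop_on_state:
                        terminal = hit
                        break
            if terminal is not None:
                break
    elif dim == 2 and thr is not None:
        x, y = float(x0[0]), float(x0[1])
        gs = potential.grad_scalar
        step = 0
        while step < max_steps:
            m = min(block, max_steps - step)
            noise = rng.standard_normal((m, 2))
            for i in range(m):
                gx, gy = gs(x, y)
                x = x - gx * dt + sigma * noise[i, 0]
                y = y - gy * dt + sigma * noise[i, 1]
                frames[n, 0] = x
                frames[n, 1] = y
                n += 1
                step += 1
                if state_defs:
                    hit = None
                    for name, axis, l, h in thr:
                        c = x if axis == 0 else y
                        if c < l or c > h:
                            hit = name
                            break
                    if hit is not None and stop_on_state:
                        terminal = hit
                        break
            if terminal is not None:
                break
    else:
        x = x0.copy()
        for step in range(max_steps):
            x = x - potential.gradient(x) * dt + sigma * rng.standard_normal(dim)
            frames[n] = x
            n += 1
            hit = in_state(x) if state_defs else None
            if hit is not None and stop_on_state:
                terminal = hit
                break

    if state_defs and stop_on_state and terminal is None:
        status = "unresolved"
    return TrajectorySegment(frames[:n].copy(), dt, seed, terminal, status)


def shoot_committor_batch(
    potential: Potential,
    xs: np.ndarray,
    a: float,
    b: float,
    dt: float,
    beta: float,
    max_steps: int,
    seed: int,
) -> np.ndarray:
    """Vectorized first-passage outcomes for a 1D potential.

    Propagates one walker per entry of ``xs`` until it crosses ``a`` (left
    absorbing boundary, outcome 0) or ``b`` (right boundary, outcome 1); all
    walkers share synchronized Euler-Maruyama steps.  Returns an int array of
    outcomes; entries still unresolved after ``max_steps`` are -1.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(xs, dtype=float).copy()
    n = x.size
    out = np.full(n, -1, dtype=int)
    active = np.arange(n)
    sigma = math.sqrt(2.0 * dt / beta)
    for _ in range(max_steps):
        if active.size == 0:
            break
        xa = x[active]
        xa = xa - potential.gradient(xa) * dt + sigma * rng.standard_normal(active.size)
        x[active] = xa
        hit_b = xa >= b
        hit_a = xa <= a
        done = hit_a | hit_b
        if done.any():
            out[active[hit_b]] = 1
            out[active[hit_a]] = 0
            active = active[~done]
    return out


# ---------------------------------------------------------------------------
# 1D oracles
# ---------------------------------------------------------------------------

def analytic_committor_1d(potential: Potential, beta: float, a: float, b: float, x):
    """Closed-form committor for 1D overdamped dynamics.

    phi(x) = int_a^x exp(beta U) ds / int_a^b exp(beta U) ds, evaluated by
    dense trapezoidal quadrature.  Vectorized in ``x``; raises for points
    outside [a, b].
    """
    if not a < b:
        raise ValueError("require a < b")
    x = np.asarray(x, dtype=float)
    if np.any(x < a) or np.any(x > b):
        raise ValueError("x outside [a, b]")
    grid = np.linspace(a, b, 8001)
    u = potential.energy(grid)
    w = np.exp(beta * (u - u.max()))  # shift for overflow safety
    cum = cumulative_trapezoid(w, grid, initial=0.0)
    phi = np.interp(x, grid, cum / cum[-1])
    return phi if phi.shape else float(phi)


def boltzmann_density_1d(potential: Potential, beta: float, lo: float, hi: float, n_grid: int = 4001):
    """Normalized Boltzmann density and CDF on [lo, hi] as (grid, pdf, cdf)."""
    grid = np.linspace(lo, hi, n_grid)
    u = potential.energy(grid)
    w = np.exp(-beta * (u - u.min()))
    cdf = cumulative_trapezoid(w, grid, initial=0.0)
    z = cdf[-1]
    return grid, w / z, cdf / z


# ---------------------------------------------------------------------------
# discrete chains: exact oracle substrate for the TPS Markov chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteChainSpec:
    """Nearest-neighbor (birth-death) chain on sites 0..n_sites-1.

    ``p_left``/``p_stay``/``p_right`` are per-site hop probabilities (each row
    summing to 1); boundary sites must not hop off the chain.  ``state_a`` and
    ``state_b`` are the site sets of the two boundary states.  Birth-death
    chains are reversible, which makes the two-way-shooting acceptance rule
    exact for this substrate.
    """

    n_sites: int
    p_left: tuple
    p_stay: tuple
    p_right: tuple
    state_a: frozenset = field(default_factory=lambda: frozenset({0}))
    state_b: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        n = self.n_sites
        pl, ps, pr = map(np.asarray, (self.p_left, self.p_stay, self.p_right))
        if not (len(pl) == len(ps) == len(pr) == n):
            raise ValueError("hop probability arrays must have length n_sites")
        if not np.allclose(pl + ps + pr, 1.0, atol=1e-12):
            raise ValueError("per-site outgoing probabilities must sum to 1")
        if pl[0] != 0 or pr[n - 1] != 0:
            raise ValueError("boundary sites must not hop off the chain")
        sb = self.state_b if self.state_b else frozenset({n - 1})
        object.__setattr__(self, "state_b", frozenset(sb))
        object.__setattr__(self, "state_a", frozenset(self.state_a))
        if self.state_a & self.state_b:
            raise ValueError("states must be disjoint")

    @classmethod
    def uniform(cls, n_sites: int, p_right: float = 0.5, p_stay: float = 0.0):
        """Homogeneous chain with reflecting stay-probability at the ends."""
        pl = [0.0] + [1.0 - p_right - p_stay] * (n_sites - 2) + [1.0 - p_stay]
        pr = [1.0 - p_stay] + [p_right] * (n_sites - 2) + [0.0]
        ps = [p_stay] * n_sites
        ps[0] = 1.0 - pr[0]
        ps[-1] = 1.0 - pl[-1]
        pl[0] = 0.0
        pr[-1] = 0.0
        return cls(n_sites, tuple(pl), tuple(ps), tuple(pr))

    def transition_matrix(self) -> np.ndarray:
        n = self.n_sites
        T = np.zeros((n, n))
        for i in range(n):
            T[i, i] = self.p_stay[i]
            if i > 0:
                T[i, i - 1] = self.p_left[i]
            if i < n - 1:
                T[i, i + 1] = self.p_right[i]
        return T

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector of the transition matrix)."""
        T = self.transition_matrix()
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def simulate_discrete(spec: DiscreteChainSpec, x0: int, max_steps: int, seed: int,
                      stop_sites: frozenset | None = None) -> list[int]:
    """Propagate the chain from ``x0`` until entering ``stop_sites``."""
    if stop_sites is None:
        stop_sites = spec.state_a | spec.state_b
    rng = np.random.default_rng(seed)
    pl = np.asarray(spec.p_left)
    pr = np.asarray(spec.p_right)
    path = [x0]
    x = x0
    u = rng.random(max_steps)
    for i in range(max_steps):
        if pl[x] > 0 and u[i] < pl[x]:
            x -= 1
        elif u[i] < pl[x] + pr[x]:
            x += 1
        path.append(x)
        if x in stop_sites:
            break
    return path


def discrete_committor(spec: DiscreteChainSpec) -> np.ndarray:
    """Exact committor to state B (linear solve; 1 on B, 0 on A)."""
    n = spec.n_sites
    T = spec.transition_matrix()
    q = np.zeros(n)
    interior = [i for i in range(n) if i not in spec.state_a and i not in spec.state_b]
    if interior:
        A = np.eye(len(interior)) - T[np.ix_(interior, interior)]
        rhs = T[np.ix_(interior, sorted(spec.state_b))].sum(axis=1)
        q[interior] = np.linalg.solve(A, rhs)
    for b in spec.state_b:
        q[b] = 1.0
    return q


def enumerate_tpe_discrete(spec: DiscreteChainSpec, max_len: int):
    """Exact transition-path-ensemble distribution by brute-force enumeration.

    Enumerates every first-entrance path from state A to state B with at most
    ``max_len`` hops.  A path (x_0, ..., x_L) with x_0 in A, x_L in B and all
    interior frames outside both states carries equilibrium weight
    pi(x_0) * prod_i T(x_i, x_i+1); weights are normalized by the exact total
    A->B transition mass (computed from the committor), so the returned
    probabilities sum to 1 minus the reported truncated mass.

    Returns ``(paths, truncated_mass, status)`` where ``paths`` maps each path
    tuple to its probability and ``status`` is "ok" or "truncated" (mass
    beyond ``max_len`` exceeding 1e-6).
    """
    if spec.n_sites > 12:
        raise ValueError("enumeration oracle limited to n_sites <= 12")
    T = spec.transition_matrix()
    pi = spec.stationary()
    if pi[sorted(spec.state_a)].sum() <= 0:
        # state A carries no equilibrium mass (e.g. forced one-way hops):
        # weight starting sites uniformly instead
        pi = np.zeros(spec.n_sites)
        for a in spec.state_a:
            pi[a] = 1.0 / len(spec.state_a)
    q = discrete_committor(spec)
    # exact total weight of all A->B first-entrance paths
    total = 0.0
    for a in spec.state_a:
        for y in range(spec.n_sites):
            if T[a, y] <= 0 or y in spec.state_a:
                continue
            total += pi[a] * T[a, y] * (1.0 if y in spec.state_b else q[y])
    paths: dict[tuple, float] = {}

    def extend(path: tuple, weight: float):
        x = path[-1]
        if x in spec.state_b:
            paths[path] = paths.get(path, 0.0) + weight / total
            return
        if len(path) > max_len:
            return
        for y in range(spec.n_sites):
            p = T[x, y]
            if p <= 0 or y in spec.state_a:
                continue
            extend(path + (y,), weight * p)

    for a in spec.state_a:
        for y in range(spec.n_sites):
            if T[a, y] > 0 and y not in spec.state_a:
                extend((a, y), pi[a] * T[a, y])

    truncated = 1.0 - sum(paths.values())
    status = "ok" if truncated <= 1e-6 else "truncated"
    return paths, truncated, status


# ---------------------------------------------------------------------------
# synthetic membrane configurations
# ---------------------------------------------------------------------------

PARTICLE_TYPES = ("head_P", "head_N", "water_O", "tail_C")
BULK_WATER_DENSITY = 33.4  # molecules / nm^3


@dataclass
class MembraneConfig:
    """Typed point set standing in for a membrane snapshot.

    Geometry only -- no energetics.  Positions in nm, wrapped into the
    periodic box; types are one of ``PARTICLE_TYPES``.
    """

    positions: np.ndarray  # (N, 3)
    types: np.ndarray  # (N,) str
    box: np.ndarray  # (3,) lengths
    midplane_z: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.types = np.asarray(self.types)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.types) != len(self.positions):
            raise ValueError("types and positions length mismatch")
        self.positions = np.mod(self.positions, self.box)

    def select(self, *types: str) -> np.ndarray:
        mask = np.isin(self.types, types)
        return self.positions[mask]

    # -- serialization (CSV schema: x,y,z,type) -----------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.positions[:, 0], "y": self.positions[:, 1],
             "z": self.positions[:, 2], "type": self.types}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, box, midplane_z: float = 0.0) -> "MembraneConfig":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df["type"].to_numpy(),
                   np.asarray(box, dtype=float), midplane_z)

    def to_hdf5(self, group):
        group.create_dataset("positions", data=self.positions)
        group.create_dataset("types", data=np.char.encode(self.types.astype(str)))
        group.attrs["box"] = self.box
        group.attrs["midplane_z"] = self.midplane_z

    @classmethod
    def from_hdf5(cls, group) -> "MembraneConfig":
        return cls(
            group["positions"][...],
            np.char.decode(group["types"][...]),
            np.asarray(group.attrs["box"]),
            float(group.attrs["midplane_z"]),
        )


def generate_membrane_config(
    n_lipids_per_leaflet: int = 60,
    leaflet_sep: float = 2.6,
    box=(6.0, 6.0, 6.0),
    pore_radius: float = 0.0,
    n_pore_waters: int | None = None,
    seed: int = 0,
    head_jitter: float = 0.15,
    n_tail_per_lipid: int = 2,
) -> MembraneConfig:
    """Synthetic bilayer-like point configuration, optionally with a pore.

    Head particles (alternating P/N) are jittered on the planes
    z = midplane +- leaflet_sep/2; tail particles fill the hydrophobic core
    between them.  With ``pore_radius > 0`` a cylindrical water column of that
    radius spans the membrane at bulk density (or with exactly
    ``n_pore_waters`` waters), and heads near the pore axis are displaced
    toward the midplane, mimicking a toroidal pore lining.  The planted
    geometry is recorded in ``metadata``.
    """
    box = np.asarray(box, dtype=float)
    if pore_radius < 0:
        raise ValueError("pore_radius must be >= 0")
    if pore_radius > min(box[0], box[1]) / 2:
        raise ValueError("pore_radius exceeds half the box")
    rng = np.random.default_rng(seed)
    mid = box[2] / 2.0
    center = np.array([box[0] / 2.0, box[1] / 2.0])
    half = leaflet_sep / 2.0

    pos, typ = [], []
    for sign in (-1.0, +1.0):
        xy = rng.uniform(0.0, 1.0, size=(n_lipids_per_leaflet, 2)) * box[:2]
        z = mid + sign * half + rng.normal(0.0, head_jitter, n_lipids_per_leaflet)
        if pore_radius > 0:
            # pull heads near the pore axis toward the midplane (pore lining)
            d = np.linalg.norm(xy - center, axis=1)
            lining = d < pore_radius + 0.6
            z[lining] = mid + sign * rng.uniform(0.1, 0.3, lining.sum())
            # rim lipids crowding the pore mouth (toroidal lining)
            n_rim = max(8, int(2.5 * 2.0 * math.pi * (pore_radius + 0.2)))
            ang = rng.uniform(0.0, 2.0 * math.pi, n_rim)
            rr = pore_radius + 0.2 + rng.normal(0.0, 0.05, n_rim)
            for i in range(n_rim):
                pos.append([center[0] + rr[i] * math.cos(ang[i]),
                            center[1] + rr[i] * math.sin(ang[i]),
                            mid + sign * rng.uniform(0.1, 0.3)])
                typ.append("head_P" if i % 2 == 0 else "head_N")
        for i in range(n_lipids_per_leaflet):
            pos.append([xy[i, 0], xy[i, 1], z[i]])
            typ.append("head_P" if i % 2 == 0 else "head_N")
        # tails between the leaflets
        for j in range(n_tail_per_lipid):
            zt = mid + sign * rng.uniform(0.1, half - 0.2, n_lipids_per_leaflet)
            for i in range(n_lipids_per_leaflet):
                pos.append([xy[i, 0] + rng.normal(0, 0.1),
                            xy[i, 1] + rng.normal(0, 0.1), zt[i]])
                typ.append("tail_C")

    # bulk water slabs outside the leaflets
    water_lo = mid - box[2] / 2.0, mid - half - 2 * head_jitter
    water_hi = mid + half + 2 * head_jitter, mid + box[2] / 2.0
    for zlo, zhi in (water_lo, water_hi):
        vol = box[0] * box[1] * max(zhi - zlo, 0.0)
        n_w = rng.poisson(BULK_WATER_DENSITY * vol)
        w = rng.uniform(0.0, 1.0, size=(n_w, 3))
        w[:, 0] *= box[0]
        w[:, 1] *= box[1]
        w[:, 2] = zlo + w[:, 2] * (zhi - zlo)
        pos.extend(w.tolist())
        typ.extend(["water_O"] * n_w)

    if pore_radius > 0:
        h = leaflet_sep
        if n_pore_waters is None:
            n_pore_waters = rng.poisson(
                BULK_WATER_DENSITY * math.pi * pore_radius**2 * h
            )
        r = pore_radius * np.sqrt(rng.random(n_pore_waters))
        th = rng.uniform(0.0, 2.0 * math.pi, n_pore_waters)
        zc = mid + rng.uniform(-h / 2.0, h / 2.0, n_pore_waters)
        for i in range(n_pore_waters):
            pos.append([center[0] + r[i] * math.cos(th[i]),
                        center[1] + r[i] * math.sin(th[i]), zc[i]])
            typ.append("water_O")

    return MembraneConfig(
        np.asarray(pos), np.asarray(typ), box, midplane_z=mid,
        metadata={
            "seed": seed,
            "planted_pore_radius": float(pore_radius),
            "planted_pore_center": center.tolist(),
            "leaflet_sep": float(leaflet_sep),
        },
    )


# ---------------------------------------------------------------------------
# dispersed shot records and censored lifetimes
# ---------------------------------------------------------------------------

def generate_shot_records(
    N: int,
    n: int,
    alpha_true: float,
    phi_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Beta-binomially dispersed committor shot outcomes.

    For each record: draw the model committor phi from ``phi_sampler``, draw
    the true committor P ~ Beta(a, b) with a = w*phi, b = w*(1-phi) and
    w = alpha/(1-alpha) -- so that <P> = phi and Var[P] = (1-alpha) phi (1-phi)
    -- then draw k ~ Binomial(n, P).  alpha = 1 collapses to P = phi (pure
    binomial outcomes); alpha = 0 is the two-point mixture P in {0, 1} with
    weight phi on 1.  Returns a table with columns (id, phi, n, k).
    """
    if not 0.0 <= alpha_true <= 1.0:
        raise ValueError("alpha_true must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if phi_sampler is None:
        phi = rng.uniform(0.05, 0.95, N)
    else:
        phi = np.asarray(phi_sampler(rng, N), dtype=float)
    if alpha_true >= 1.0:
        P = phi
    elif alpha_true <= 0.0:
        P = (rng.random(N) < phi).astype(float)
    else:
        w = alpha_true / (1.0 - alpha_true)
        P = rng.beta(w * phi, w * (1.0 - phi))
    k = rng.binomial(n, P)
    return pd.DataFrame({"id": np.arange(N), "phi": phi, "n": n, "k": k})


def generate_censored_lifetimes(rate: float, t_censor: float, N: int, seed: int = 0):
    """Exponential lifetimes with deterministic right-censoring at t_censor.

    Returns (durations, censored): draws >= t_censor are reported as t_censor
    with censored = True.
    """
    if rate <= 0 or t_censor <= 0:
        raise ValueError("rate and t_censor must be positive")
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, N)
    censored = t >= t_censor
    t = np.minimum(t, t_censor)
    return t, censored
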