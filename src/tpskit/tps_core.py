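"""Two-way-shooting transition path sampling over a pluggable propagator.

The Markov chain walks in the space of transition paths: from the current
path a shooting point (SP) is selected, two trajectory segments are
propagated from it with independent noise, and -- when their endpoints land
in different metastable states -- the spliced trial path replaces the current
one under a Metropolis-Hastings acceptance that corrects for biased SP
selection.  Every shot, accepted or not, yields a shooting record
(features, n = 2 shots, k hits of the designated final state) that trains the
committor model on the fly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import sp_selection
from .toy_systems import (
    DiscreteChainSpec,
    Potential,
    TrajectorySegment,
    simulate_discrete,
    simulate_overdamped,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StateDefinition",
    "Path",
    "ShootingRecord",
    "ChainLog",
    "ChainResult",
    "LangevinEngine",
    "DiscreteChainEngine",
    "classify_state",
    "two_way_shot",
    "accept_move",
    "run_chain",
    "make_seed_path",
    "time_average_xi",
    "smooth_series",
]


# ---------------------------------------------------------------------------
# states and paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateDefinition:
    """Metastable state as an indicator on frames.

    Either a free-form ``indicator`` or a threshold on one coordinate: the
    frame is inside when ``frame[axis] < below`` or ``frame[axis] > above``
    (whichever bound is set).  Threshold form mirrors the study's state
    definitions -- lower/upper leaflet at z < -1.3 nm / z > +1.3 nm for
    flip-flop, and flat/porous membrane at xi_P < 0.05 / xi_P > 2.0 for
    nucleation -- and enables a fast propagation loop.
    """

    name: str
    indicator: Optional[Callable[[np.ndarray], bool]] = None
    axis: int = 0
    below: Optional[float] = None
    above: Optional[float] = None

    def contains(self, frame) -> bool:
        if self.indicator is not None:
            return bool(self.indicator(frame))
        c = np.asarray(frame).reshape(-1)[self.axis]
        if self.below is not None and c < self.below:
            return True
        if self.above is not None and c > self.above:
            return True
        return False


def flipflop_states(z_star: float = 1.3, axis: int = 0) -> list[StateDefinition]:
    """Lower/upper-leaflet states: L at z < -z*, U at z > +z* (nm)."""
    return [
        StateDefinition("L", axis=axis, below=-z_star),
        StateDefinition("U", axis=axis, above=+z_star),
    ]


def nucleation_states(lo: float = 0.05, hi: float = 2.0, axis: int = 0) -> list[StateDefinition]:
    """Flat-membrane state F at xi_P < lo, expanded-pore state P at xi_P > hi."""
    return [
        StateDefinition("F", axis=axis, below=lo),
        StateDefinition("P", axis=axis, above=hi),
    ]


def classify_state(frame, state_defs: Sequence[StateDefinition]) -> Optional[str]:
    """Unique state label of a frame, or None; two hits violate disjointness."""
    hits = [s.name for s in state_defs if s.contains(frame)]
    if len(hits) > 1:
        raise ValueError(f"frame lies in multiple states: {hits}")
    return hits[0] if hits else None


@dataclass
class Path:
    """Transition path: ordered frames whose endpoints (only) lie in states."""

    frames: np.ndarray  # (n_frames, dim)
    dt: float
    labels: tuple  # (state of frame 0, state of last frame)
    sp_index: Optional[int] = None  # splice point of the generating shot
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.frames) - 1) * self.dt

    def check_first_entrance(self, state_defs: Sequence[StateDefinition]) -> None:
        """Assert endpoints in states and interior frames in none."""
        first = classify_state(self.frames[0], state_defs)
        last = classify_state(self.frames[-1], state_defs)
        if first is None or last is None or first == last:
            raise ValueError("path endpoints must lie in two different states")
        for fr in self.frames[1:-1]:
            if classify_state(fr, state_defs) is not None:
                raise ValueError("interior path frame lies inside a state")


@dataclass
class ShootingRecord:
    """Outcome of one two-way shot: the unit of committor training.

    ``k`` counts how many of the ``n`` = 2 segment endpoints reached the
    designated final state (regardless of trial-path direction); it is None
    for unresolved shots.
    """

    x_sp: np.ndarray  # feature vector at the shooting point
    n: int
    k: Optional[int]
    accepted: bool
    mc_index: int
    phi: Optional[float] = None  # model committor estimate at shot time
    chain_id: int = 0
    sp_index: Optional[int] = None
    status: str = "ok"


@dataclass
class ChainLog:
    """Per-MC-step bookkeeping of a TPS run."""

    accepted: np.ndarray  # bool
    k: np.ndarray  # int, -1 for unresolved
    phi_sp: np.ndarray  # float, nan when no model
    xi_hat: np.ndarray  # float, nan when no xi_fn
    path_id: np.ndarray  # index into the path archive of the current path
    t_tp: np.ndarray  # cumulative time of newly accepted transition paths
    t_all: np.ndarray  # cumulative propagated time incl. rejected shots

    def __post_init__(self):
        if np.any(self.t_tp > self.t_all + 1e-12):
            raise ValueError("T_TP must never exceed T_all")

    @property
    def n_steps(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_fraction(self) -> float:
        return float(np.mean(self.accepted)) if self.n_steps else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "accepted": self.accepted,
                "k": self.k,
                "phi_sp": self.phi_sp,
                "xi_hat": self.xi_hat,
                "path_id": self.path_id,
                "t_tp": self.t_tp,
                "t_all": self.t_all,
            }
        )


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

class LangevinEngine:
    """Overdamped-Langevin propagator on an analytic potential (kT units)."""

    def __init__(self, potential: Potential, dt: float, beta: float,
                 max_steps: int, state_defs: Sequence[StateDefinition]):
        self.potential = potential
        self.dt = dt
        self.beta = beta
        self.max_steps = max_steps
        self.state_defs = list(state_defs)

    def shoot(self, x_sp, seed: int) -> TrajectorySegment:
        return simulate_overdamped(
            self.potential, x_sp, self.dt, self.beta, self.max_steps,
            seed, self.state_defs, stop_on_state=True,
        )


class DiscreteChainEngine:
    """Nearest-neighbor-chain propagator; frames are 1D site coordinates."""

    def __init__(self, spec: DiscreteChainSpec, max_steps: int = 10_000):
        self.spec = spec
        self.dt = 1.0
        self.max_steps = max_steps
        self.state_defs = [
            StateDefinition("A", indicator=lambda fr, s=spec: int(round(float(np.ravel(fr)[0]))) in s.state_a),
            StateDefinition("B", indicator=lambda fr, s=spec: int(round(float(np.ravel(fr)[0]))) in s.state_b),
        ]

    def shoot(self, x_sp, seed: int) -> TrajectorySegment:
        site = int(round(float(np.ravel(x_sp)[0])))
        sites = simulate_discrete(self.spec, site, self.max_steps, seed)
        frames = np.asarray(sites, dtype=float)[:, None]
        terminal = None
        last = sites[-1]
        if last in self.spec.state_a:
            terminal = "A"
        elif last in self.spec.state_b:
            terminal = "B"
        status = "ok" if terminal is not None else "unresolved"
        return TrajectorySegment(frames, self.dt, seed, terminal, status)


# ---------------------------------------------------------------------------
# the two-way shooting move
# ---------------------------------------------------------------------------

def two_way_shot(engine, x_sp, state_defs: Sequence[StateDefinition],
                 final_state: str, seed: int):
    """Two-way shot from ``x_sp``: two independent segments, one time-reversed.

    Returns ``(trial_path_or_None, k, segments)``.  ``k`` counts segment
    endpoints in ``final_state`` (0, 1 or 2); a trial path exists iff the two
    endpoints lie in different states (k = 1), assembled by reversing the
    segment that did *not* reach the final state and splicing at the shooting
    point.  ``k`` is None when a segment is unresolved.
    """
    if classify_state(x_sp, state_defs) is not None:
        raise ValueError("shooting point must lie outside all states")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    s1, s2 = (int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(2))
    seg_fwd = engine.shoot(x_sp, s1)
    seg_bwd = engine.shoot(x_sp, s2)
    segments = (seg_fwd, seg_bwd)
    if seg_fwd.status != "ok" or seg_bwd.status != "ok":
        return None, None, segments

    k = int(seg_fwd.terminal_state == final_state) + int(seg_bwd.terminal_state == final_state)
    if seg_fwd.terminal_state == seg_bwd.terminal_state:
        return None, k, segments

    # orient the trial path so that it ends in final_state
    if seg_fwd.terminal_state == final_state:
        head, tail = seg_bwd, seg_fwd
    else:
        head, tail = seg_fwd, seg_bwd
    frames = np.concatenate([head.frames[::-1], tail.frames[1:]], axis=0)
    sp_index = len(head.frames) - 1
    trial = Path(
        frames,
        engine.dt,
        (head.terminal_state, tail.terminal_state),
        sp_index=sp_index,
        provenance={"seed": int(seed)},
    )
    return trial, k, segments


def accept_move(trial: Path, current: Path, selection_weights_fn,
                sp_index_current: int, rng: np.random.Generator) -> bool:
    """Metropolis-Hastings acceptance for biased SP selection.

    Accept with probability min(1, p_sel(x_SP | trial) / p_sel(x_SP | current)),
    where p_sel is the normalized selection weight of the shooting point
    within each path.  Under uniform selection the ratio is the path-length
    ratio of eligible frames; selection weights of exactly equal form cancel.
    """
    if trial.sp_index is None:
        raise RuntimeError("trial path carries no shooting-point index")
    w_trial = selection_weights_fn(trial)
    w_curr = selection_weights_fn(current)
    p_new = w_trial[trial.sp_index]
    p_old = w_curr[sp_index_current]
    if p_new <= 0.0:
        raise RuntimeError("shooting point has zero selection weight in trial path")
    ratio = p_new / p_old
    return bool(rng.random() < min(1.0, ratio))


# ---------------------------------------------------------------------------
# observables along paths
# ---------------------------------------------------------------------------

def time_average_xi(path: Path, xi_fn: Callable[[np.ndarray], float]) -> float:
    """Path-time average of a frame observable (e.g. the pore coordinate)."""
    if len(path.frames) == 0:
        raise ValueError("empty path")
    vals = np.asarray([xi_fn(fr) for fr in path.frames], dtype=float)
    return float(vals.mean())


def smooth_series(series, window: int = 10) -> np.ndarray:
    """Centered moving average, window truncated at the series ends."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return x.copy()
    out = np.empty_like(x)
    half = window // 2
    n = len(x)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + (window - half))
        out[i] = x[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# the sequential TPS chain
# ---------------------------------------------------------------------------

@dataclass
class ChainResult:
    log: ChainLog
    paths: list  # archived accepted Paths (index 0 = seed path)
    records: list  # all ShootingRecords, unresolved included
    current: Path
    selector: "sp_selection.SPSelector | None"
    model: object | None


def _step_seed(seed: int, mc_index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, mc_index, stream])


def make_seed_path(engine, x_start, state_defs, final_state: str, seed: int,
                   max_tries: int = 200) -> Path:
    """Generate an initial transition path by repeated two-way shooting."""
    for t in range(max_tries):
        s = int(_step_seed(seed, t, 9).generate_state(1)[0] & 0x7FFFFFFF)
        trial, k, _ = two_way_shot(engine, x_start, state_defs, final_state, s)
        if trial is not None:
            trial.check_first_entrance(state_defs)
            return trial
    raise RuntimeError(f"no transition path found in {max_tries} shots from {x_start}")


def run_chain(
    engine,
    seed_path: Path,
    n_steps: int,
    committor_model=None,
    sp_scheduler: "sp_selection.SPSelector | None" = None,
    state_defs: Sequence[StateDefinition] | None = None,
    seed: int = 0,
    *,
    final_state: str | None = None,
    featurize: Callable[[np.ndarray], np.ndarray] | None = None,
    xi_fn: Callable[[np.ndarray], float] | None = None,
    trainer: Callable | None = None,
    train_schedule: Callable[[int], bool] | None = None,
    extra_records: Sequence[ShootingRecord] = (),
    chain_id: int = 0,
    start_index: int = 0,
) -> ChainResult:
    """Sequential two-way-shooting TPS with on-the-fly committor guidance.

    Per MC step: select an SP from the current path (uniformly, or from the
    Cauchy-reweighted committor-logit distribution once the selector has a
    histogram), two-way shoot, Metropolis accept/reject, log, and retrain the
    committor model on the accumulated shooting records per ``train_schedule``.
    On rejection the current path is retained and the step still counts.

    All randomness derives from per-step seed sequences of ``seed``, so a run
    restarted from a checkpoint (same current path, selector state, model and
    ``start_index``) reproduces the remaining log bit-identically.

    ``extra_records`` (e.g. shots from initial restraint runs) are prepended
    to the training set but not logged.
    """
    if state_defs is None:
        state_defs = engine.state_defs
    if final_state is None:
        final_state = seed_path.labels[1]
    if featurize is None:
        featurize = lambda frames: np.atleast_2d(np.asarray(frames, dtype=float))
    if sp_scheduler is None:
        sp_scheduler = sp_selection.SPSelector(model=committor_model, featurize=featurize)
    seed_path.check_first_entrance(state_defs)

    current = seed_path
    sel_weights = sp_scheduler.weights_for  # path -> normalized per-frame weights
    records: list[ShootingRecord] = list(extra_records)
    n_extra = len(records)
    paths: list[Path] = [current]
    acc = np.zeros(n_steps, dtype=bool)
    ks = np.full(n_steps, -1, dtype=int)
    phis = np.full(n_steps, np.nan)
    xis = np.full(n_steps, np.nan)
    pids = np.zeros(n_steps, dtype=int)
    t_tp = np.zeros(n_steps)
    t_all = np.zeros(n_steps)
    cum_tp = 0.0
    cum_all = 0.0
    cur_pid = 0
    cur_xi = time_average_xi(current, xi_fn) if xi_fn is not None else np.nan

    if start_index == 0:
        sp_scheduler.observe_path(current)  # seed path counts as the first accepted TP

    for i in range(n_steps):
        mc = start_index + i
        sp_scheduler.maybe_update(mc)
        rng = np.random.default_rng(_step_seed(seed, mc, 0))

        weights = sel_weights(current)
        j = sp_selection.select_sp(weights, rng)
        x_sp = current.frames[j]
        feats = featurize(x_sp[None, :])[0]
        phi_sp = float(committor_model.predict(feats[None, :])[0]) if committor_model is not None else np.nan

        shot_seed = int(_step_seed(seed, mc, 1).generate_state(1)[0] & 0x7FFFFFFF)
        try:
            trial, k, segments = two_way_shot(engine, x_sp, state_defs, final_state, shot_seed)
        except ValueError:
            # SP inside a state should be impossible for valid paths
            raise
        cum_all += sum(seg.duration for seg in segments)

        accepted = False
        status = "ok"
        if k is None:
            status = "unresolved"
            logger.debug("MC %d: unresolved shot", mc)
        elif trial is not None:
            if accept_move(trial, current, sel_weights, j, rng):
                accepted = True
                current = trial
                cur_pid = len(paths)
                paths.append(current)
                cum_tp += current.duration
                cur_xi = time_average_xi(current, xi_fn) if xi_fn is not None else np.nan
                sp_scheduler.observe_path(current)

        records.append(
            ShootingRecord(
                x_sp=feats, n=2, k=k, accepted=accepted, mc_index=mc,
                phi=phi_sp if committor_model is not None else None,
                chain_id=chain_id, sp_index=j, status=status,
            )
        )
        acc[i] = accepted
        ks[i] = -1 if k is None else k
        phis[i] = phi_sp
        xis[i] = cur_xi
        pids[i] = cur_pid
        t_tp[i] = cum_tp
        t_all[i] = cum_all

        if trainer is not None and train_schedule is not None and train_schedule(mc):
            usable = [r for r in records if r.k is not None]
            if usable:
                trainer(committor_model, usable, mc)

    log = ChainLog(acc, ks, phis, xis, pids, t_tp, t_all)
    return ChainResult(log, paths, records[n_extra:], current, sp_scheduler, committor_model)
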