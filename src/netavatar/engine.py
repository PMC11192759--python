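"""Discrete-time, continuous-valued dynamics on a cell-line avatar.

Update rule
-----------
Each node ``j`` carries an activity ``a_j(t)`` bounded by its
``[activity_min, activity_max]`` interval and a concentration ``c_j``
that is fixed during a run.  One synchronous step computes

    input_j  = bias_j + sum_i sign_ij * w_ij * a_i(t) * chat_i
    a_j(t+1) = clamp(sigmoid(input_j), activity_min_j, activity_max_j)

with ``chat_i = c_i / (1 + c_i)`` (a saturating transform so expression
fold-changes modulate edge influence boundedly) and
``bias_j = logit(base_activity_j)`` so an input-free node sits exactly at
its base activity.  The rule is continuous-valued, honours sign/weight
semantics and saturates inside [0, 1]; it is isolated behind
:func:`_step_batch` so alternative gate functions can be swapped in.

Heterogeneity enters only through the initial condition: activities and
concentrations start at their base values times ``exp(N(0, noise_sd))``,
clamped to bounds.  A replicate reaches a *fixed point* when the largest
activity change falls below ``attractor_tol``; a *limit cycle* when a
state rounded to 6 decimals recurs within ``cycle_detection_window``
steps.  Phenotype readouts (mean activity of the cell_cycle and apoptosis
readout nodes, averaged over one period for cycles) are taken at the
attractor, and a replicate is alive iff its cell-cycle score reaches 0.60
while apoptosis stays at or below 0.20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .conditioning import CellLineAvatar
from .errors import InputError

#: verdict thresholds: alive iff cell_cycle >= ALIVE_CC and apoptosis <= ALIVE_APOP
ALIVE_CELL_CYCLE_MIN = 0.60
ALIVE_APOPTOSIS_MAX = 0.20

_LOGIT_EPS = 1e-9
_ROUND_DECIMALS = 6


@dataclass
class SimulationConfig:
    max_steps: int = 300
    n_replicates: int = 100
    noise_sd: float = 0.05
    attractor_tol: float = 1e-6
    cycle_detection_window: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise InputError("max_steps must be >= 1")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not self.attractor_tol > 0:
            raise InputError("attractor_tol must be > 0")


@dataclass
class CompiledSystem:
    """Avatar flattened to arrays; node order = network insertion order."""

    node_ids: list[str]
    weights: np.ndarray  # (n, n) signed weights, [i, j] = effect of i on j
    bias: np.ndarray
    base_activity: np.ndarray
    base_concentration: np.ndarray
    activity_min: np.ndarray
    activity_max: np.ndarray
    cc_idx: np.ndarray
    apop_idx: np.ndarray


def compile_avatar(avatar: CellLineAvatar) -> CompiledSystem:
    net = avatar.network
    ids = net.node_ids
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    for e in net.edges:
        w[index[e.source], index[e.target]] += e.sign * e.weight
    base_a = np.array([net.nodes[i].base_activity for i in ids])
    amin = np.array([net.nodes[i].activity_min for i in ids])
    amax = np.array([net.nodes[i].activity_max for i in ids])
    conc = np.array([net.nodes[i].base_concentration for i in ids])
    bias = logit(np.clip(base_a, _LOGIT_EPS, 1 - _LOGIT_EPS))
    cc = np.array([index[i] for i in net.readout_ids("cell_cycle")], dtype=int)
    ap = np.array([index[i] for i in net.readout_ids("apoptosis")], dtype=int)
    return CompiledSystem(ids, w, bias, base_a, conc, amin, amax, cc, ap)


def _step_batch(a: np.ndarray, chat: np.ndarray, sys: CompiledSystem) -> np.ndarray:
    z = (a * chat) @ sys.weights + sys.bias
    return np.clip(expit(z), sys.activity_min, sys.activity_max)


def step(state_activities: np.ndarray, avatar: CellLineAvatar,
         concentrations: np.ndarray | None = None) -> np.ndarray:
    """Advance a single activity vector one time step.

    ``concentrations`` defaults to the avatar's effective concentrations.
    """
    sys = compile_avatar(avatar)
    a = np.asarray(state_activities, dtype=float)
    if a.shape != (len(sys.node_ids),):
        raise InputError(
            f"state has {a.shape} entries for {len(sys.node_ids)} nodes"
        )
    if not np.all(np.isfinite(a)):
        raise InputError("non-finite state")
    c = sys.base_concentration if concentrations is None else np.asarray(concentrations)
    chat = c / (1.0 + c)
    return _step_batch(a[None, :], chat[None, :], sys)[0]


@dataclass
class Trajectory:
    states: np.ndarray  # (steps+1, n)
    attractor: bool
    attractor_type: str  # fixed_point | limit_cycle | none
    period: int
    cell_cycle_score: float
    apoptosis_score: float
    verdict: str


@dataclass
class EnsembleResult:
    """Replicate-level readouts plus ensemble summaries."""

    cell_line: str
    cell_cycle_scores: np.ndarray
    apoptosis_scores: np.ndarray
    verdicts: np.ndarray  # bool, True = alive
    attractor_types: np.ndarray  # int codes 0 none / 1 fixed_point / 2 limit_cycle
    steps_to_attractor: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_replicates(self) -> int:
        return len(self.verdicts)

    @property
    def survival_fraction(self) -> float:
        return float(np.mean(self.verdicts))

    @property
    def attractor_fraction(self) -> float:
        return float(np.mean(self.attractor_types > 0))

    def to_frame(self):
        import pandas as pd

        names = np.array(["none", "fixed_point", "limit_cycle"])
        return pd.DataFrame(
            {
                "replicate": np.arange(self.n_replicates),
                "cell_cycle_score": self.cell_cycle_scores,
                "apoptosis_score": self.apoptosis_scores,
                "verdict": np.where(self.verdicts, "alive", "dead"),
                "attractor_type": names[self.attractor_types],
                "steps_to_attractor": self.steps_to_attractor,
            }
        )


def compute_verdict(cell_cycle_score: float, apoptosis_score: float) -> str:
    """'alive' iff cell cycle >= 0.60 and apoptosis <= 0.20 (both inclusive)."""
    for name, v in (("cell_cycle_score", cell_cycle_score), ("apoptosis_score", apoptosis_score)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name}={v} outside [0, 1]")
    alive = cell_cycle_score >= ALIVE_CELL_CYCLE_MIN and apoptosis_score <= ALIVE_APOPTOSIS_MAX
    return "alive" if alive else "dead"


def _initial_conditions(
    sys: CompiledSystem, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate noisy initial activities and concentrations.

    Each replicate draws from its own child of the config seed, so the
    r-th replicate's trajectory is invariant to n_replicates.
    """
    n = len(sys.node_ids)
    reps = config.n_replicates
    a0 = np.empty((reps, n))
    c0 = np.empty((reps, n))
    children = np.random.SeedSequence(config.rng_seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        if config.noise_sd > 0:
            a0[r] = sys.base_activity * np.exp(rng.normal(0.0, config.noise_sd, n))
            c0[r] = sys.base_concentration * np.exp(rng.normal(0.0, config.noise_sd, n))
        else:
            a0[r] = sys.base_activity
            c0[r] = sys.base_concentration
    np.clip(a0, sys.activity_min, sys.activity_max, out=a0)
    return a0, c0


def _readout_means(states: np.ndarray, idx: np.ndarray) -> np.ndarray:
    if len(idx) == 0:
        return np.zeros(states.shape[0])
    return states[:, idx].mean(axis=1)


def run_ensemble(
    avatar: CellLineAvatar,
    treatment: Sequence = (),
    config: SimulationConfig | None = None,
) -> EnsembleResult:
    """Run ``n_replicates`` noisy trajectories to their attractors.

    ``treatment`` is a sequence of (TargetProfile, dose_nM) pairs whose
    activity caps are applied before stepping.  Fully reproducible for a
    given seed: replicate r uses the r-th child stream of ``rng_seed``.
    """
    from .pharmacology import apply_treatment

    config = config or SimulationConfig()
    if treatment:
        avatar = apply_treatment(avatar, treatment)
    sys = compile_avatar(avatar)
    reps = config.n_replicates
    n = len(sys.node_ids)

    a, c0 = _initial_conditions(sys, config)
    chat = c0 / (1.0 + c0)

    att_type = np.zeros(reps, dtype=int)
    att_step = np.full(reps, -1, dtype=int)
    cc = np.empty(reps)
    ap = np.empty(reps)
    done = np.zeros(reps, dtype=bool)

    window = max(1, config.cycle_detection_window)
    # ring buffer of recent states per replicate, for cycle detection and
    # period-mean readouts
    hist = np.empty((window, reps, n))
    hist[0] = a
    hist_len = 1

    for t in range(1, config.max_steps + 1):
        a_next = _step_batch(a, chat, sys)
        if not np.all(np.isfinite(a_next)):
            raise InputError("non-finite state during simulation")
        delta = np.max(np.abs(a_next - a), axis=1)

        newly_fixed = (~done) & (delta < config.attractor_tol)
        if np.any(newly_fixed):
            att_type[newly_fixed] = 1
            att_step[newly_fixed] = t
            cc[newly_fixed] = _readout_means(a_next[newly_fixed], sys.cc_idx)
            ap[newly_fixed] = _readout_means(a_next[newly_fixed], sys.apop_idx)
            done |= newly_fixed

        # limit-cycle detection on rounded states against the ring buffer
        open_mask = ~done
        if np.any(open_mask):
            rounded = np.round(a_next, _ROUND_DECIMALS)
            for back in range(1, hist_len + 1):
                prev = np.round(hist[(t - back) % window], _ROUND_DECIMALS)
                match = open_mask & np.all(rounded == prev, axis=1)
                if np.any(match):
                    idx = np.where(match)[0]
                    # mean readout over the `back` states of one period
                    period_states = np.stack(
                        [hist[(t - b) % window][idx] for b in range(back)]
                    )  # uses a_next implicitly via hist update below; include a_next
                    period_states[0] = a_next[idx]
                    cc[idx] = _readout_means(
                        period_states.reshape(-1, n), sys.cc_idx
                    ).reshape(back, -1).mean(axis=0)
                    ap[idx] = _readout_means(
                        period_states.reshape(-1, n), sys.apop_idx
                    ).reshape(back, -1).mean(axis=0)
                    att_type[idx] = 2
                    att_step[idx] = t
                    done[idx] = True
                    open_mask = ~done
                    if not np.any(open_mask):
                        break

        a = a_next
        hist[t % window] = a
        hist_len = min(hist_len + 1, window)
        if np.all(done):
            break

    if not np.all(done):
        rest = ~done
        cc[rest] = _readout_means(a[rest], sys.cc_idx)
        ap[rest] = _readout_means(a[rest], sys.apop_idx)

    verdicts = (cc >= ALIVE_CELL_CYCLE_MIN) & (ap <= ALIVE_APOPTOSIS_MAX)
    return EnsembleResult(
        cell_line=avatar.cell_line,
        cell_cycle_scores=cc,
        apoptosis_scores=ap,
        verdicts=verdicts,
        attractor_types=att_type,
        steps_to_attractor=att_step,
        config=config,
    )


def run_trajectory(
    avatar: CellLineAvatar,
    config: SimulationConfig | None = None,
    replicate: int = 0,
) -> Trajectory:
    """Run one replicate, recording the full state history.

    ``replicate`` selects which child stream of the config seed supplies
    the initial noise, matching the corresponding ensemble member.
    """
    config = config or SimulationConfig()
    sys = compile_avatar(avatar)
    n = len(sys.node_ids)
    children = np.random.SeedSequence(config.rng_seed).spawn(replicate + 1)
    rng = np.random.default_rng(children[replicate])
    if config.noise_sd > 0:
        a = sys.base_activity * np.exp(rng.normal(0.0, config.noise_sd, n))
        c = sys.base_concentration * np.exp(rng.normal(0.0, config.noise_sd, n))
    else:
        a = sys.base_activity.copy()
        c = sys.base_concentration.copy()
    a = np.clip(a, sys.activity_min, sys.activity_max)
    chat = (c / (1.0 + c))[None, :]

    states = [a.copy()]
    att_type = "none"
    period = 0
    window = max(1, config.cycle_detection_window)
    for t in range(1, config.max_steps + 1):
        a_next = _step_batch(a[None, :], chat, sys)[0]
        states.append(a_next.copy())
        if np.max(np.abs(a_next - a)) < config.attractor_tol:
            att_type = "fixed_point"
            a = a_next
            break
        rounded = np.round(a_next, _ROUND_DECIMALS)
        found = False
        for back in range(1, min(window, len(states) - 1) + 1):
            if np.all(rounded == np.round(states[-1 - back], _ROUND_DECIMALS)):
                att_type = "limit_cycle"
                period = back
                found = True
                break
        a = a_next
        if found:
            break

    arr = np.asarray(states)
    if att_type == "limit_cycle":
        tail = arr[-period:]
    else:
        tail = arr[-1:]
    cc = float(_readout_means(tail, sys.cc_idx).mean())
    ap = float(_readout_means(tail, sys.apop_idx).mean())
    return Trajectory(
        states=arr,
        attractor=att_type != "none",
        attractor_type=att_type,
        period=period,
        cell_cycle_score=cc,
        apoptosis_score=ap,
        verdict=compute_verdict(cc, ap),
    )
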