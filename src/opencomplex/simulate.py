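"""Synthetic-data generator: Gillespie trajectories of the promoter cycle
rendered as noisy magnetic-tweezers extension traces.

The generator emulates the assay: a two-level telegraph extension signal
(open/closed tether levels) driven by the continuous-time kinetic scheme
R+P <-> RP_C -> RP_I <-> RP_O with dissociation from RP_I (and optionally
RP_O), sampled at 58 Hz with additive Gaussian tracking noise, optional slow
linear drift, and optional 10-point block averaging, mirroring the
acquisition and preprocessing of the experiment.  Ground-truth state
trajectories and dwell records are kept alongside each trace for
benchmarking the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dwells import DwellSet
from .schemes import KineticScheme, RateConstants

__all__ = [
    "STATES",
    "OPEN_STATES",
    "TraceConfig",
    "StateTrajectory",
    "Trace",
    "simulate_trajectory",
    "render_trace",
    "true_dwells",
    "sample_first_passage",
]

STATES = ("R+P", "RP_C", "RP_I", "RP_O")
OPEN_STATES = frozenset({"RP_I", "RP_O"})
_OPEN_IDX = np.array([False, False, True, True])


@dataclass
class TraceConfig:
    """Rendering parameters of a synthetic extension trace.

    Defaults follow the assay: 58 Hz acquisition, 10-point averaging, and a
    raw-sample noise SD of 25 nm so the 73 nm opening jump has SNR ~ 9 after
    decimation.  ``jump_pos``/``jump_neg`` are the OS->CS extension jumps for
    positively/negatively supercoiled tethers.
    """

    rates: RateConstants = field(default_factory=RateConstants)
    z_CS: float = 300.0          # closed-state extension level (nm)
    jump_pos: float = 73.0       # nm
    jump_neg: float = 42.0       # nm
    supercoiling_sign: str = "+"
    noise_sd: float = 25.0       # per raw sample (nm)
    f_s: float = 58.0            # Hz
    duration: float = 600.0      # s
    decimate: int = 10
    drift_rate: float = 0.0      # nm/s
    seed: int = 0
    labels: dict = field(default_factory=dict)  # free-text condition labels

    def __post_init__(self) -> None:
        if self.f_s <= 0 or self.duration <= 0:
            raise ValueError("f_s and duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if int(self.decimate) != self.decimate or self.decimate < 1:
            raise ValueError("decimate must be an integer >= 1")
        if self.supercoiling_sign not in ("+", "-"):
            raise ValueError("supercoiling_sign must be '+' or '-'")
        self.decimate = int(self.decimate)

    @property
    def jump(self) -> float:
        return self.jump_pos if self.supercoiling_sign == "+" else self.jump_neg

    @property
    def f_s_eff(self) -> float:
        return self.f_s / self.decimate

    def meta_dict(self) -> dict:
        d = {"z_CS": self.z_CS, "jump_pos": self.jump_pos,
             "jump_neg": self.jump_neg,
             "supercoiling_sign": self.supercoiling_sign,
             "noise_sd": self.noise_sd, "f_s": self.f_s,
             "duration": self.duration, "decimate": self.decimate,
             "drift_rate": self.drift_rate, "seed": self.seed}
        d.update({f"rates.{k}": v for k, v in self.rates.to_dict().items()})
        d.update(self.labels)
        return d


@dataclass
class StateTrajectory:
    """Exact event record of one promoter: state after each event time."""

    event_times: np.ndarray   # strictly increasing, starts at 0.0
    states: np.ndarray        # state name after each event; first is "R+P"
    duration: float           # observation window (s)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if len(self.event_times) != len(self.states):
            raise ValueError("event_times and states must have equal length")
        if len(self.states) == 0 or self.states[0] != "R+P":
            raise ValueError("trajectory must start in R+P")
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")

    def state_at(self, t) -> np.ndarray:
        """State occupied at each query time."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right") - 1
        return self.states[np.clip(idx, 0, None)]


@dataclass
class Trace:
    """Uniformly sampled extension signal with acquisition metadata."""

    t: np.ndarray      # s
    z: np.ndarray      # nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.t) != len(self.z):
            raise ValueError("t and z must have equal length")

    @property
    def f_s_eff(self) -> float:
        if "f_s" in self.meta:
            return float(self.meta["f_s"]) / int(self.meta.get("decimate", 1))
        return 1.0 / float(np.median(np.diff(self.t)))


def _transition_table(rates: RateConstants):
    """targets[i], rates_out[i] for each source state index."""
    r = rates
    return [
        ([1], [r.k1 * r.R_conc]),                      # R+P -> RP_C
        ([0, 2], [r.k_neg1, r.k2]),                    # RP_C -> R+P | RP_I
        ([1, 3, 0], [r.k_neg2, r.k3, r.k5]),           # RP_I -> RP_C | RP_O | R+P
        ([2, 0], [r.k_neg3, r.k4]),                    # RP_O -> RP_I | R+P
    ]


def simulate_trajectory(rates: RateConstants, duration: float,
                        seed=None) -> StateTrajectory:
    """Exact stochastic simulation of the promoter cycle for ``duration`` s.

    Waiting times are exponential at the total exit rate of the current
    state; the branch is chosen proportionally to the competing rates.
    Binding is pseudo-first-order at ``k1 * [R]``; every dissociation event
    returns the promoter to R+P.  Identical seeds give identical
    trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    table = _transition_table(rates)
    totals = [float(np.sum(rts)) for _, rts in table]

    times = [0.0]
    states = [0]
    t, s = 0.0, 0
    while True:
        total = totals[s]
        if total <= 0.0:
            raise RuntimeError(
                f"absorbing configuration: state {STATES[s]} has no exit rate")
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        targets, rts = table[s]
        if len(targets) == 1:
            s = targets[0]
        else:
            u = rng.random() * total
            c = 0.0
            for tgt, rate in zip(targets, rts):
                c += rate
                if u < c:
                    s = tgt
                    break
            else:
                s = targets[-1]
        times.append(t)
        states.append(s)
    return StateTrajectory(np.array(times),
                           np.array([STATES[i] for i in states], dtype=object),
                           duration=duration)


def render_trace(traj: StateTrajectory, config: TraceConfig) -> Trace:
    """Render a trajectory as a noisy two-level extension trace.

    States R+P and RP_C map to the closed-state level ``z_CS``; RP_I and
    RP_O map to ``z_CS - jump`` (sign-appropriate) -- the intermediate and
    final open complexes render at the same level, as no difference in
    transcription-bubble size is observable in the assay.  Each raw sample
    takes the state occupied at its timestamp; linear drift and i.i.d.
    Gaussian noise are added before block-averaging by ``decimate``.
    """
    n_raw = int(np.floor(config.duration * config.f_s))
    t_raw = np.arange(n_raw) / config.f_s
    idx = np.searchsorted(traj.event_times, t_raw, side="right") - 1
    state_codes = np.array([STATES.index(s) for s in traj.states])
    is_open = _OPEN_IDX[state_codes[np.clip(idx, 0, None)]]
    z = np.where(is_open, config.z_CS - config.jump, config.z_CS).astype(float)
    if config.drift_rate != 0.0:
        z += config.drift_rate * t_raw
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        z += rng.normal(0.0, config.noise_sd, size=n_raw)
    d = config.decimate
    if d > 1:
        n_dec = n_raw // d
        z = z[: n_dec * d].reshape(n_dec, d).mean(axis=1)
        t = t_raw[: n_dec * d].reshape(n_dec, d).mean(axis=1)
    else:
        t = t_raw
    return Trace(t=t, z=z, meta=config.meta_dict())


def true_dwells(traj: StateTrajectory) -> DwellSet:
    """Ground-truth OS/CS dwell record of a trajectory.

    R+P and RP_C are lumped into CS, RP_I and RP_O into OS.  Alternating
    dwell durations are returned with the first and last dwell flagged as
    censored (truncated by the observation window).
    """
    codes = np.array([STATES.index(s) for s in traj.states])
    is_open = _OPEN_IDX[codes].astype(int)
    change = np.flatnonzero(np.diff(is_open) != 0) + 1
    bounds = np.concatenate(([0.0], traj.event_times[change], [traj.duration]))
    durations = np.diff(bounds)
    labels = []
    lvl = is_open[0]
    for _ in range(len(durations)):
        labels.append("OS" if lvl else "CS")
        lvl = 1 - lvl
    censored = np.zeros(len(durations), dtype=bool)
    censored[0] = True
    censored[-1] = True
    keep = durations > 0
    return DwellSet(labels=np.array(labels, dtype=object)[keep],
                    durations=durations[keep], censored=censored[keep],
                    starts=bounds[:-1][keep])


def sample_first_passage(scheme: KineticScheme, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` first-passage (dwell) times from a transient scheme by
    exact jump-chain simulation, vectorized over walkers.

    This is a stochastic route to the phase-type density that shares no code
    with :func:`opencomplex.schemes.phase_type_pdf`.
    """
    if np.all(scheme.a == 0):
        raise ValueError("non-absorbing scheme: no first passage exists")
    rng = np.random.default_rng(seed)
    m = scheme.n_states
    Q = scheme.Q
    exit_total = -np.diag(Q)            # total exit rate per state
    # branching: columns = target transient states, last column = absorption
    probs = np.zeros((m, m + 1))
    for i in range(m):
        if exit_total[i] <= 0:
            raise RuntimeError(f"transient state {scheme.state_names[i]} is absorbing "
                               "within the transient set")
        probs[i, :m] = Q[i] / exit_total[i]
        probs[i, i] = 0.0
        probs[i, m] = scheme.a[i] / exit_total[i]
    cum = np.cumsum(probs, axis=1)

    state = rng.choice(m, size=n, p=scheme.pi0)
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    while np.any(alive):
        s = state[alive]
        t[alive] += rng.exponential(1.0, size=s.size) / exit_total[s]
        u = rng.random(s.size)
        nxt = (u[:, None] > cum[s]).sum(axis=1)
        absorbed = nxt == m
        idx = np.flatnonzero(alive)
        state[idx[~absorbed]] = nxt[~absorbed]
        alive[idx[absorbed]] = False
    return t
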