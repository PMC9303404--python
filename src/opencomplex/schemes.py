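"""Kinetic schemes for bacterial RNA polymerase open-complex dynamics.

The promoter cycle is modelled as a continuous-time Markov chain over the
species

    R + P  <=[k1[R] / k-1]=>  RP_C  --[k2]-->  RP_I  <=[k3 / k-3]=>  RP_O

with holoenzyme dissociation from RP_I (rate ``k5``) and, in the general
model, from RP_O (rate ``k4``).  The magnetic-tweezers assay observes only
two extension levels: the closed state CS (R+P and RP_C) and the open state
OS (RP_I and RP_O).  A dwell in either observable state is therefore a
first-passage time of the chain restricted to the states of that level, and
its distribution is phase-type: ``f(t) = pi0' exp(Q t) a`` where ``Q`` is the
generator restricted to the transient states, ``a`` the vector of absorption
rates and ``pi0`` the entry distribution.

For the accepted model (dissociation from RP_I only, ``k4 = 0``) the OS
dwell density is a two-exponential mixture ``p+ k+ exp(-k+ t) +
p- k- exp(-k- t)`` and the mapping between the mixture parameters
``(k+, k-, p-)`` and the microscopic rates ``(k5, k3, k-3)`` is exact in
both directions:

    k5  = p+ k+ + (1 - p+) k-
    k3  = p+ (1 - p+) (k+ - k-)^2 / k5
    k-3 = k+ k- / k5

This module defines the model ladder used to discriminate dissociation
pathways, the phase-type machinery, and those conversion relations with
first-order error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateConstants",
    "KineticScheme",
    "ExpMixParams",
    "DerivedRates",
    "MODEL_IDS",
    "build_scheme",
    "phase_type_pdf",
    "phase_type_cdf",
    "phase_type_mean",
    "pdf_shape",
    "fit_to_micro",
    "micro_to_fit",
    "propagate_errors",
]


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the promoter cycle.

    Units are s^-1 except ``k1`` (nM^-1 s^-1) and ``R_conc`` (nM).  ``k_neg2``
    (RP_I -> RP_C back-isomerization) defaults to 0: the forward isomerization
    is treated as effectively irreversible, and only the reversed-pathway
    model (M1) uses a nonzero value.  ``k4`` (dissociation from RP_O) is 0 in
    the accepted model.
    """

    k1: float = 0.0
    k_neg1: float = 0.0
    k2: float = 0.0
    k_neg2: float = 0.0
    k3: float = 0.0
    k_neg3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    R_conc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_neg1", "k2", "k_neg2", "k3", "k_neg3",
                     "k4", "k5", "R_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    def replace(self, **kwargs) -> "RateConstants":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "k1": self.k1, "k_neg1": self.k_neg1, "k2": self.k2,
            "k_neg2": self.k_neg2, "k3": self.k3, "k_neg3": self.k_neg3,
            "k4": self.k4, "k5": self.k5, "R_conc": self.R_conc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: float(v) for k, v in d.items() if k in known})


@dataclass(frozen=True)
class KineticScheme:
    """Transient-state generator of a first-passage (dwell-time) problem.

    ``Q`` holds the transition rates among the transient states (s^-1,
    off-diagonal >= 0, row sums <= 0), ``a`` the per-state absorption rates
    (the negated row sums), and ``pi0`` the entry distribution.
    """

    state_names: tuple
    Q: np.ndarray
    pi0: np.ndarray
    a: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        pi0 = np.asarray(self.pi0, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        n = Q.shape[0]
        if len(self.state_names) != n or pi0.shape != (n,):
            raise ValueError("state_names, Q and pi0 sizes disagree")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be >= 0")
        a = -Q.sum(axis=1)
        if np.any(a < -1e-9 * max(1.0, np.abs(Q).max())):
            raise ValueError("row sums of Q must be <= 0")
        a = np.clip(a, 0.0, None)
        if np.any(pi0 < 0) or np.any(pi0 > 1) or abs(pi0.sum() - 1.0) > 1e-9:
            raise ValueError("pi0 must be a probability distribution")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "pi0", pi0)
        object.__setattr__(self, "a", a)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class ExpMixParams:
    """Two-exponential mixture parameters (k+ >= k- > 0, p+ + p- = 1)."""

    k_plus: float
    k_minus: float
    p_minus: float

    def __post_init__(self) -> None:
        if not (self.k_minus > 0 and self.k_plus >= self.k_minus):
            raise ValueError(
                f"require k_plus >= k_minus > 0, got ({self.k_plus}, {self.k_minus})")
        if not (-1e-12 <= self.p_minus <= 1 + 1e-12):
            raise ValueError(f"p_minus must lie in [0, 1], got {self.p_minus}")
        object.__setattr__(self, "p_minus", float(min(max(self.p_minus, 0.0), 1.0)))

    @property
    def p_plus(self) -> float:
        return 1.0 - self.p_minus

    def pdf(self, t, t_min: float = 0.0):
        """Mixture density, renormalized on [t_min, inf) when t_min > 0."""
        t = np.asarray(t, dtype=float)
        f = (self.p_plus * self.k_plus * np.exp(-self.k_plus * t)
             + self.p_minus * self.k_minus * np.exp(-self.k_minus * t))
        if t_min > 0:
            f = f / self.sf(t_min)
        return f

    def sf(self, t):
        t = np.asarray(t, dtype=float)
        return (self.p_plus * np.exp(-self.k_plus * t)
                + self.p_minus * np.exp(-self.k_minus * t))

    def cdf(self, t):
        return 1.0 - self.sf(t)

    @property
    def mean(self) -> float:
        return self.p_plus / self.k_plus + self.p_minus / self.k_minus


@dataclass(frozen=True)
class DerivedRates:
    """Microscopic rates derived from a mixture fit, with propagated 1-SD errors."""

    k5: float
    k3: float
    k_neg3: float
    sd_k5: float = 0.0
    sd_k3: float = 0.0
    sd_k_neg3: float = 0.0

    def to_dict(self) -> dict:
        return {"k5": self.k5, "k3": self.k3, "k_neg3": self.k_neg3,
                "sd_k5": self.sd_k5, "sd_k3": self.sd_k3,
                "sd_k_neg3": self.sd_k_neg3}


MODEL_IDS = ("M1", "M2", "M3c1", "M3c2", "M4_full", "M4_A1", "M4_A2",
             "M4_A3", "CS_chain")


def _require(rates: RateConstants, names: tuple, model_id: str) -> None:
    for n in names:
        if getattr(rates, n) <= 0:
            raise ValueError(f"model {model_id} requires {n} > 0, got {getattr(rates, n)}")


def build_scheme(model_id: str, rates: RateConstants,
                 mix_weight: float = 0.5) -> KineticScheme:
    """Assemble the transient generator for one model of the OS (or CS) dwell.

    The OS model ladder:

    * ``M1`` -- reversed pathway: start RP_I, walk back through RP_C (k_neg2,
      k2) and dissociate from RP_C (k_neg1).
    * ``M2`` -- two parallel dissociation pathways: probabilistic start over
      two independent single-exit intermediates with exit rates k5 and k4;
      ``mix_weight`` is the probability of the k5 pathway.
    * ``M3c1`` / ``M3c2`` -- dissociation only from RP_O (rate k4), starting
      from RP_O (case 1) or RP_I (case 2).
    * ``M4_full`` -- dissociation from both RP_I (k5) and RP_O (k4).
    * ``M4_A1`` -- same wiring as M4_full (the rapid RP_I<->RP_O equilibrium
      of Assumption 1 is a parameter regime, not a different generator).
    * ``M4_A2`` -- Assumption 2, k_neg3 = 0 (RP_O irreversible).
    * ``M4_A3`` -- Assumption 3, k4 = 0 (dissociation only via RP_I); the
      accepted model.
    * ``CS_chain`` -- the closed-state dwell: R+P <-> RP_C with absorption
      into RP_I at rate k2; binding is pseudo-first-order at k1*[R].
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    if model_id == "M1":
        _require(rates, ("k_neg2", "k2", "k_neg1"), model_id)
        Q = np.array([
            [-rates.k_neg2, rates.k_neg2],
            [rates.k2, -(rates.k2 + rates.k_neg1)],
        ])
        return KineticScheme(("RP_I", "RP_C"), Q, np.array([1.0, 0.0]))

    if model_id == "M2":
        _require(rates, ("k5", "k4"), model_id)
        if not 0.0 <= mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        Q = np.diag([-rates.k5, -rates.k4])
        return KineticScheme(("RP_I_a", "RP_I_b"), Q,
                             np.array([mix_weight, 1.0 - mix_weight]))

    if model_id in ("M3c1", "M3c2"):
        _require(rates, ("k3", "k_neg3", "k4"), model_id)
        Q = np.array([
            [-rates.k3, rates.k3],
            [rates.k_neg3, -(rates.k_neg3 + rates.k4)],
        ])
        pi0 = np.array([0.0, 1.0]) if model_id == "M3c1" else np.array([1.0, 0.0])
        return KineticScheme(("RP_I", "RP_O"), Q, pi0)

    if model_id in ("M4_full", "M4_A1", "M4_A2", "M4_A3"):
        k4 = 0.0 if model_id == "M4_A3" else rates.k4
        k_neg3 = 0.0 if model_id == "M4_A2" else rates.k_neg3
        req = ["k3", "k5"]
        if model_id in ("M4_full", "M4_A1"):
            req += ["k4", "k_neg3"]
        elif model_id == "M4_A2":
            req += ["k4"]
        else:
            req += ["k_neg3"]
        _require(rates, tuple(req), model_id)
        Q = np.array([
            [-(rates.k3 + rates.k5), rates.k3],
            [k_neg3, -(k_neg3 + k4)],
        ])
        return KineticScheme(("RP_I", "RP_O"), Q, np.array([1.0, 0.0]))

    # CS_chain
    _require(rates, ("k1", "R_conc", "k2"), model_id)
    kon = rates.k1 * rates.R_conc
    Q = np.array([
        [-kon, kon],
        [rates.k_neg1, -(rates.k_neg1 + rates.k2)],
    ])
    return KineticScheme(("R+P", "RP_C"), Q, np.array([1.0, 0.0]))


def _spectral(scheme: KineticScheme):
    """Spectral form of f(t): weights w_i and eigenvalues lam_i such that
    f(t) = sum_i w_i exp(lam_i t).  Returns None if Q is too ill-conditioned
    to diagonalize reliably."""
    lam, V = np.linalg.eig(scheme.Q)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(V) > 1e10:
        return None
    w = (scheme.pi0 @ V) * (Vinv @ scheme.a)
    return w, lam


def phase_type_pdf(scheme: KineticScheme, t) -> np.ndarray:
    """First-passage density ``f(t) = pi0' exp(Q t) a`` on a grid ``t >= 0``.

    Two-state (and generically diagonalizable) generators are evaluated by
    eigendecomposition; defective cases fall back to scaling-and-squaring
    ``expm`` per time point.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.all(scheme.a == 0):
        raise ValueError("non-absorbing scheme: no first passage exists")
    spec = _spectral(scheme)
    if spec is not None:
        w, lam = spec
        f = np.real(np.exp(np.outer(t, lam)) @ w)
    else:
        f = np.array([scheme.pi0 @ expm(scheme.Q * ti) @ scheme.a for ti in t])
    return np.clip(f, 0.0, None)


def phase_type_cdf(scheme: KineticScheme, t) -> np.ndarray:
    """First-passage CDF ``F(t) = 1 - pi0' exp(Q t) 1``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.all(scheme.a == 0):
        raise ValueError("non-absorbing scheme: no first passage exists")
    spec = _spectral(scheme)
    ones = np.ones(scheme.n_states)
    if spec is not None:
        lam, V = np.linalg.eig(scheme.Q)
        w = (scheme.pi0 @ V) * (np.linalg.inv(V) @ ones)
        surv = np.real(np.exp(np.outer(t, lam)) @ w)
    else:
        surv = np.array([scheme.pi0 @ expm(scheme.Q * ti) @ ones for ti in t])
    return np.clip(1.0 - surv, 0.0, 1.0)


def phase_type_mean(scheme: KineticScheme) -> float:
    """Mean first-passage time ``-pi0' Q^-1 1``."""
    if np.all(scheme.a == 0):
        raise ValueError("non-absorbing scheme: no first passage exists")
    m = np.linalg.solve(scheme.Q, -np.ones(scheme.n_states))
    return float(scheme.pi0 @ m)


def pdf_shape(scheme: KineticScheme) -> str:
    """Classify the dwell density at the origin.

    Returns ``"peaked_at_zero"`` iff ``f(0+) = pi0' a = 0`` (the dwell must
    traverse at least one transition before absorbing, so the density rises
    from zero like a gamma-type peak), else ``"positive_mixture"``.  This is
    the discard/keep criterion of the model ladder: the measured OS dwell
    histograms decay from t = 0.
    """
    f0 = float(scheme.pi0 @ scheme.a)
    scale = max(scheme.a.max(initial=0.0), 1e-300)
    return "peaked_at_zero" if f0 <= 1e-12 * scale else "positive_mixture"


def fit_to_micro(fit: ExpMixParams) -> DerivedRates:
    """Convert mixture parameters to the microscopic rates of the accepted model.

    Exact relations (dissociation from RP_I only):
    ``k5 = p+ k+ + p- k-``, ``k3 = p+ p- (k+ - k-)^2 / k5``,
    ``k-3 = k+ k- / k5``.  All outputs are positive whenever the input
    satisfies its invariants.
    """
    kp, km, pp = fit.k_plus, fit.k_minus, fit.p_plus
    k5 = pp * kp + (1.0 - pp) * km
    if k5 <= 0:
        raise ValueError("degenerate mixture: k5 = 0")
    k3 = pp * (1.0 - pp) * (kp - km) ** 2 / k5
    k_neg3 = kp * km / k5
    return DerivedRates(k5=k5, k3=k3, k_neg3=k_neg3)


def micro_to_fit(k5: float, k3: float, k_neg3: float) -> ExpMixParams:
    """Invert the conversion: mixture parameters from (k5, k3, k-3).

    ``k+``/``k-`` are the negated eigenvalues of the 2-state generator of the
    accepted model, i.e. the roots of ``x^2 - (k5+k3+k-3) x + k5 k-3 = 0``,
    and ``p+`` solves ``k5 = p+ k+ + p- k-``.
    """
    if k5 <= 0 or k3 < 0 or k_neg3 < 0:
        raise ValueError("require k5 > 0 and k3, k_neg3 >= 0")
    if k3 == 0.0:
        # no RP_O entry: pure exponential at k5 (degenerate weight on k_neg3)
        if k5 >= k_neg3:
            return ExpMixParams(k_plus=k5, k_minus=k_neg3 if k_neg3 > 0 else k5,
                                p_minus=0.0)
        return ExpMixParams(k_plus=k_neg3, k_minus=k5, p_minus=1.0)
    s = k5 + k3 + k_neg3
    # discriminant rewritten as u^2 + 4 k3 k-3 (u = k5 + k3 - k-3): always
    # positive for k3 > 0 and free of cancellation
    u = k5 + k3 - k_neg3
    disc = u * u + 4.0 * k3 * k_neg3
    if disc <= 0:
        # repeated eigenvalue (measure-zero Erlang boundary): single-exp limit
        half = 0.5 * s
        return ExpMixParams(k_plus=half, k_minus=half, p_minus=0.0)
    root = math.sqrt(disc)
    kp = 0.5 * (s + root)
    km = (k5 * k_neg3) / kp          # product of roots
    # p+ = (k5 - km)/(kp - km) with kp - km = root and
    # k5 - km = k5 (kp - k-3)/kp, the last factor evaluated stably
    if u >= 0:
        kp_minus_kn3 = 0.5 * (u + root)
    else:
        kp_minus_kn3 = (2.0 * k3 * k_neg3) / (root - u)
    pp = k5 * kp_minus_kn3 / (kp * root)
    pp = min(max(pp, 0.0), 1.0)
    return ExpMixParams(k_plus=kp, k_minus=km, p_minus=1.0 - pp)


def _micro_vec(x: np.ndarray) -> np.ndarray:
    kp, km, pm = x
    d = fit_to_micro(ExpMixParams(k_plus=kp, k_minus=km, p_minus=pm))
    return np.array([d.k5, d.k3, d.k_neg3])


def propagate_errors(fit: ExpMixParams, sds) -> DerivedRates:
    """First-order error propagation from (k+, k-, p-) to (k5, k3, k-3).

    ``sds`` are the one-SD errors of (k+, k-, p-), e.g. from the bootstrap.
    Partials are evaluated by central finite differences with a relative step
    of 1e-6: Delta k_mic_j = sqrt(sum_i (d k_mic_j / d x_i * Delta x_i)^2).
    """
    sds = np.asarray(sds, dtype=float)
    if sds.shape != (3,) or np.any(sds < 0):
        raise ValueError("sds must be three non-negative values for (k+, k-, p-)")
    x0 = np.array([fit.k_plus, fit.k_minus, fit.p_minus])
    jac = np.zeros((3, 3))
    for i in range(3):
        h = 1e-6 * max(abs(x0[i]), 1e-6)
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        # keep the perturbed points inside the valid domain
        xp[2] = min(max(xp[2], 0.0), 1.0)
        xm[2] = min(max(xm[2], 0.0), 1.0)
        denom = xp[i] - xm[i]
        jac[:, i] = (_micro_vec(xp) - _micro_vec(xm)) / denom
    var = (jac ** 2) @ (sds ** 2)
    sd = np.sqrt(var)
    base = fit_to_micro(fit)
    return DerivedRates(k5=base.k5, k3=base.k3, k_neg3=base.k_neg3,
                        sd_k5=sd[0], sd_k3=sd[1], sd_k_neg3=sd[2])
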