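"""Maximum-likelihood fitting of dwell-time distributions.

Dwell times are fitted by one- or two-exponential densities,

    f(t) = k exp(-k t)
    f(t) = p+ k+ exp(-k+ t) + p- k- exp(-k- t),    p+ + p- = 1,

with left truncation at the minimum-dwell cutoff ``t_min`` (the density is
renormalized on ``[t_min, inf)``, since dwells below the assay's temporal
resolution are discarded during extraction).  The single-exponential MLE is
closed-form, ``k = 1 / (mean(tau) - t_min)``; the mixture is maximized by
bounded L-BFGS-B over ``(ln k+, ln k-, logit p-)`` from multiple stratified
starts.  Model order is chosen by the Bayesian (Schwarz) information
criterion ``BIC = m ln N - 2 ln L``, and parameter errors are one-SD spreads
over bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .dwells import DwellSet
from .schemes import ExpMixParams

__all__ = [
    "ExpMixFit",
    "fit_single_exp",
    "fit_double_exp",
    "select_model",
    "bootstrap_errors",
]


@dataclass
class ExpMixFit:
    """Result of a dwell-time MLE fit.

    ``params`` holds ``{"k"}`` for the single-exponential model or
    ``{"k_plus", "k_minus", "p_minus"}`` for the mixture; ``sds`` holds the
    matching one-SD bootstrap errors when computed.
    """

    model: str                 # "single" | "double"
    params: dict
    logL: float
    n: int
    bic: float
    t_min: float = 0.0
    sds: dict = field(default_factory=dict)
    n_boot: int = 0
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        m = 1 if self.model == "single" else 3
        expected = m * np.log(self.n) - 2.0 * self.logL
        if not np.isclose(self.bic, expected, rtol=1e-9, atol=1e-6):
            raise ValueError("bic inconsistent with logL and n")

    def mixture(self) -> ExpMixParams:
        """The fit as mixture parameters (single-exp maps to p- = 0)."""
        if self.model == "single":
            k = self.params["k"]
            return ExpMixParams(k_plus=k, k_minus=k, p_minus=0.0)
        return ExpMixParams(**self.params)

    def to_dict(self) -> dict:
        return {"model": self.model, "params": dict(self.params),
                "logL": self.logL, "n": self.n, "bic": self.bic,
                "t_min": self.t_min, "sds": dict(self.sds),
                "n_boot": self.n_boot, "n_failed": self.n_failed}


def _durations(dwells, label: str | None) -> np.ndarray:
    if isinstance(dwells, DwellSet):
        if label is None:
            raise ValueError("label required when fitting a DwellSet")
        return dwells.uncensored(label)
    return np.asarray(dwells, dtype=float)


def fit_single_exp(dwells, label: str | None = None,
                   t_min: float | None = None) -> ExpMixFit:
    """Closed-form single-exponential MLE with left truncation.

    Under the truncated density ``k exp(-k (tau - t_min))`` the MLE is
    ``k = 1 / (mean(tau) - t_min)``.
    """
    tau = _durations(dwells, label)
    if t_min is None:
        t_min = dwells.t_min if isinstance(dwells, DwellSet) else 0.0
    n = tau.size
    if n < 1:
        raise ValueError("need at least one uncensored dwell")
    if np.any(tau < t_min):
        raise ValueError("dwells shorter than t_min present")
    excess = float(np.mean(tau)) - t_min
    if excess <= 0:
        raise ValueError("degenerate data: mean dwell <= t_min")
    k = 1.0 / excess
    logL = n * np.log(k) - k * float(np.sum(tau - t_min))
    return ExpMixFit(model="single", params={"k": k}, logL=logL, n=n,
                     bic=float(np.log(n) - 2.0 * logL), t_min=t_min)


def _nll_double(theta: np.ndarray, tau: np.ndarray, t_min: float) -> float:
    lkp, lkm, lgt = theta
    kp, km = np.exp(lkp), np.exp(lkm)
    pm = 1.0 / (1.0 + np.exp(-lgt))
    pp = 1.0 - pm
    f = pp * kp * np.exp(-kp * tau) + pm * km * np.exp(-km * tau)
    if t_min > 0:
        norm = pp * np.exp(-kp * t_min) + pm * np.exp(-km * t_min)
    else:
        norm = 1.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore",
                     under="ignore"):
        ll = np.sum(np.log(f)) - tau.size * np.log(norm)
    return -ll if np.isfinite(ll) else 1e300


def _double_inits(tau: np.ndarray, restarts: int, rng: np.random.Generator):
    """Stratified initializations: rate scales from quantile means, mixture
    weights spread over (0, 1), plus random log-perturbations."""
    med = np.median(tau)
    lo = tau[tau <= med]
    hi = tau[tau > med]
    k_fast = 1.0 / max(np.mean(lo), 1e-12) if lo.size else 2.0 / np.mean(tau)
    k_slow = 1.0 / max(np.mean(hi), 1e-12) if hi.size else 0.5 / np.mean(tau)
    base = []
    for pm in (0.2, 0.5, 0.8):
        base.append((np.log(k_fast), np.log(k_slow), np.log(pm / (1 - pm))))
    inits = list(base)
    while len(inits) < restarts:
        b = base[len(inits) % len(base)]
        jit = rng.normal(0.0, (0.7, 0.7, 0.8))
        inits.append((b[0] + jit[0], b[1] + jit[1], b[2] + jit[2]))
    return inits[:restarts]


def fit_double_exp(dwells, label: str | None = None, t_min: float | None = None,
                   restarts: int = 8, seed: int = 0,
                   init: ExpMixParams | None = None) -> ExpMixFit:
    """Two-exponential mixture MLE (truncation-renormalized when t_min > 0).

    Minimizes the negative log-likelihood by L-BFGS-B in the unconstrained
    coordinates ``(ln k+, ln k-, logit p-)``; the best of ``restarts``
    stratified initializations is returned, with ``k+ >= k-`` enforced by
    post-hoc relabeling.  ``init`` warm-starts the search (used by the
    bootstrap).
    """
    tau = _durations(dwells, label)
    if t_min is None:
        t_min = dwells.t_min if isinstance(dwells, DwellSet) else 0.0
    n = tau.size
    if n < 4:
        raise ValueError("need at least 4 uncensored dwells")
    if float(np.mean(tau)) - t_min <= 0:
        raise ValueError("degenerate data: mean dwell <= t_min")
    rng = np.random.default_rng(seed)
    inits = []
    if init is not None:
        pm = min(max(init.p_minus, 1e-4), 1 - 1e-4)
        inits.append((np.log(init.k_plus), np.log(init.k_minus),
                      np.log(pm / (1 - pm))))
    inits.extend(_double_inits(tau, max(restarts - len(inits), 1), rng))

    bounds = [(-35.0, 35.0)] * 2 + [(-16.0, 16.0)]
    best = None
    for x0 in inits:
        res = minimize(_nll_double, np.asarray(x0), args=(tau, t_min),
                       method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("mixture fit failed to converge from all restarts")

    lkp, lkm, lgt = best.x
    kp, km = float(np.exp(lkp)), float(np.exp(lkm))
    pm = float(1.0 / (1.0 + np.exp(-lgt)))
    if kp < km:  # relabel: the fast component is k+
        kp, km = km, kp
        pm = 1.0 - pm
    logL = -float(best.fun)
    return ExpMixFit(model="double",
                     params={"k_plus": kp, "k_minus": km, "p_minus": pm},
                     logL=logL, n=n,
                     bic=float(3.0 * np.log(n) - 2.0 * logL), t_min=t_min)


def select_model(fit1: ExpMixFit, fit2: ExpMixFit) -> str:
    """Choose between the single- and double-exponential fits by BIC.

    Returns ``"single"`` or ``"double"``; ties go to the model with fewer
    parameters.
    """
    if fit1.n != fit2.n:
        raise ValueError("fits must be on the same dwell set")
    single = fit1 if fit1.model == "single" else fit2
    double = fit2 if fit1.model == "single" else fit1
    if single.model != "single" or double.model != "double":
        raise ValueError("need one single- and one double-exponential fit")
    return "double" if double.bic < single.bic else "single"


def bootstrap_errors(dwells, fitter, n_boot: int = 1000, seed: int = 0,
                     label: str | None = None, max_fail_frac: float = 0.2):
    """One-SD parameter errors from bootstrap resampling.

    Resamples the dwell set with replacement ``n_boot`` times, refits with
    ``fitter(durations)`` and returns ``(sds, n_failed)`` where ``sds`` maps
    each parameter name to the SD of its value across converged replicates.
    Replicates that fail to converge are dropped and counted; more than
    ``max_fail_frac`` failures raises (the fit is unstable).
    """
    tau = _durations(dwells, label)
    n = tau.size
    if n < 1:
        raise ValueError("need at least one dwell")
    rng = np.random.default_rng(seed)
    values: dict[str, list] = {}
    n_failed = 0
    for _ in range(n_boot):
        sample = tau[rng.integers(0, n, size=n)]
        try:
            fit = fitter(sample)
            if not np.all(np.isfinite(list(fit.params.values()))):
                raise RuntimeError("non-finite fit")
        except Exception:
            n_failed += 1
            continue
        for k, v in fit.params.items():
            values.setdefault(k, []).append(v)
    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{n_boot} replicates failed")
    sds = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
           for k, v in values.items()}
    return sds, n_failed
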