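"""Dependence of the extracted rate constants on experimental conditions.

Three empirical laws are fitted:

* Holoenzyme concentration -- rapid pre-equilibration of binding followed by
  rate-limiting isomerization gives the observed opening rate

      k_open([R]) = k2 * [R] / (K_D + [R]),          K_D = k-1 / k1.

* Temperature -- each microscopic rate follows the Arrhenius law
  ``k = k0 exp(-dE / (R_gas T))`` with a sign-carrying activation energy
  (negative values flag a hidden stable intermediate).  Substituting the
  Arrhenius forms of k2 and K_D into the binding law gives

      k_open(T) = k2^0 e^{-dE2/RT} [R] / (K_D^0 e^{-(dE-1 - dE1)/RT} + [R]),

  which is non-monotonic in T when the binding-energy difference
  ``dE_diff = dE-1 - dE1`` exceeds ``dE2``: isomerization limits the rate at
  low temperature, holoenzyme dissociation at high temperature.

* Salt -- the sensitivity ``S = d ln k / d ln [salt]``, the log-log slope of
  a rate against monovalent-salt concentration.

Temperatures are accepted in degrees Celsius and converted to kelvin
internally; energies are reported in kcal/mol with a kJ/mol echo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.stats import linregress

__all__ = [
    "R_GAS_KCAL",
    "KCAL_TO_KJ",
    "BindingFit",
    "ArrheniusFit",
    "TempBindingFit",
    "SaltSensitivity",
    "fit_binding",
    "fit_arrhenius",
    "fit_kopen_temperature",
    "kopen_temperature_model",
    "salt_sensitivity",
]

R_GAS_KCAL = 1.98720425e-3   # kcal mol^-1 K^-1
KCAL_TO_KJ = 4.184
_T0_K = 273.15


@dataclass
class BindingFit:
    """Hyperbolic binding fit: K_D (nM), k2 (s^-1), 1-SD errors, residual norm."""

    K_D: float
    k2: float
    sd_K_D: float
    sd_k2: float
    residual_norm: float
    flat_data: bool = False
    """True when K_D is effectively unidentifiable: relative SD above 1, or
    K_D collapsed far below the smallest probed concentration."""

    def predict(self, R_conc):
        R = np.asarray(R_conc, dtype=float)
        return self.k2 * R / (self.K_D + R)

    def to_dict(self) -> dict:
        return {"K_D": self.K_D, "k2": self.k2, "sd_K_D": self.sd_K_D,
                "sd_k2": self.sd_k2, "residual_norm": self.residual_norm,
                "flat_data": self.flat_data}


@dataclass
class ArrheniusFit:
    """Arrhenius fit: attempt rate k0 (s^-1) and activation energy dE (kcal/mol)."""

    k0: float
    dE: float            # sign-carrying, kcal/mol
    sd_k0: float
    sd_dE: float

    @property
    def dE_kJ(self) -> float:
        return self.dE * KCAL_TO_KJ

    def predict(self, T_C):
        T = np.asarray(T_C, dtype=float) + _T0_K
        return self.k0 * np.exp(-self.dE / (R_GAS_KCAL * T))

    def to_dict(self) -> dict:
        return {"k0": self.k0, "dE_kcal_mol": self.dE,
                "dE_kJ_mol": self.dE_kJ, "sd_k0": self.sd_k0,
                "sd_dE_kcal_mol": self.sd_dE}


@dataclass
class TempBindingFit:
    """Temperature-dependent binding fit of k_open(T).

    ``dE2`` is the isomerization activation energy and ``dE_diff`` the
    difference of the dissociation and association activation energies
    (both kcal/mol); ``k2_0`` and ``KD_0`` are the corresponding attempt
    prefactors.  ``k2_ref``/``KD_ref`` are the same quantities evaluated at
    the reference temperature ``T_ref_K`` (numerically better conditioned).
    """

    k2_0: float
    dE2: float
    KD_0: float
    dE_diff: float
    T_ref_K: float
    k2_ref: float
    KD_ref: float
    sds: dict = field(default_factory=dict)

    def predict(self, T_C, R_conc):
        return kopen_temperature_model(T_C, R_conc, self.k2_ref, self.dE2,
                                       self.KD_ref, self.dE_diff, self.T_ref_K)

    def to_dict(self) -> dict:
        return {"k2_0": self.k2_0, "dE2_kcal_mol": self.dE2,
                "KD_0": self.KD_0, "dE_diff_kcal_mol": self.dE_diff,
                "dE2_kJ_mol": self.dE2 * KCAL_TO_KJ,
                "dE_diff_kJ_mol": self.dE_diff * KCAL_TO_KJ,
                "T_ref_K": self.T_ref_K, "k2_ref": self.k2_ref,
                "KD_ref": self.KD_ref, "sds": dict(self.sds)}


@dataclass
class SaltSensitivity:
    """Log-log salt sensitivity S = d ln k / d ln [salt] (dimensionless)."""

    S: float
    sd: float

    def to_dict(self) -> dict:
        return {"S": self.S, "sd": self.sd}


def _as_arrays(*cols):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("input columns must have equal length")
    return arrs


def fit_binding(k_open, R_conc, sd=None) -> BindingFit:
    """Weighted least squares of ``k_open = k2 [R] / (K_D + [R])``.

    ``sd`` supplies per-point one-SD errors for 1/sigma^2 weighting; without
    it the fit is unweighted.  Requires >= 3 concentrations and positive
    rates.  Flat (unidentifiable) data is flagged via ``flat_data`` rather
    than raised.
    """
    k_open, R = _as_arrays(k_open, R_conc)
    if k_open.size < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(k_open <= 0) or np.any(R < 0):
        raise ValueError("rates must be > 0 and concentrations >= 0")

    def model(R, k2, K_D):
        return k2 * R / (K_D + R)

    kmax = float(k_open.max())
    half = 0.5 * kmax
    KD0 = float(np.interp(half, k_open[np.argsort(R)], np.sort(R)))
    p0 = (1.5 * kmax, max(KD0, 1e-3))
    sigma = np.asarray(sd, dtype=float) if sd is not None else None
    popt, pcov = curve_fit(model, R, k_open, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None,
                           bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = k_open - model(R, *popt)
    K_D = float(popt[1])
    flat = (not np.isfinite(perr[1]) or perr[1] > K_D
            or K_D < 0.05 * float(np.min(R[R > 0], initial=np.inf)))
    return BindingFit(K_D=K_D, k2=float(popt[0]),
                      sd_K_D=float(perr[1]), sd_k2=float(perr[0]),
                      residual_norm=float(np.linalg.norm(resid)),
                      flat_data=flat)


def fit_arrhenius(k, T_C, sd=None) -> ArrheniusFit:
    """Linear least squares of ``ln k`` against ``1/T`` (T in kelvin).

    The slope is ``-dE / R_gas`` with the gas constant in kcal/(mol K);
    negative activation energies are permitted.  With exactly two
    temperatures the line is exactly determined and the SDs are NaN.
    """
    k, T_C = _as_arrays(k, T_C)
    if k.size < 2:
        raise ValueError("need at least 2 temperatures")
    if np.any(k <= 0):
        raise ValueError("rates must be > 0")
    T = T_C + _T0_K
    if np.unique(T).size < 2:
        raise ValueError("duplicate temperatures only")
    x = 1.0 / T
    y = np.log(k)
    w = None
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        w = k / sd            # weights on ln k: sigma_lnk = sd/k
    A = np.vstack([x, np.ones_like(x)]).T
    if w is not None:
        Aw, yw = A * w[:, None], y * w
    else:
        Aw, yw = A, y
    coef, res, _, _ = np.linalg.lstsq(Aw, yw, rcond=None)
    slope, intercept = coef
    dof = k.size - 2
    if dof > 0:
        resid = yw - Aw @ coef
        s2 = float(resid @ resid) / dof if sd is None else 1.0
        cov = s2 * np.linalg.inv(Aw.T @ Aw)
        if sd is not None:
            cov = np.linalg.inv(Aw.T @ Aw)
        sd_slope = np.sqrt(cov[0, 0])
        sd_int = np.sqrt(cov[1, 1])
    else:
        sd_slope = sd_int = float("nan")
    dE = -slope * R_GAS_KCAL
    k0 = float(np.exp(intercept))
    return ArrheniusFit(k0=k0, dE=float(dE),
                        sd_k0=float(k0 * sd_int),
                        sd_dE=float(R_GAS_KCAL * sd_slope))


def kopen_temperature_model(T_C, R_conc, k2_ref, dE2, KD_ref, dE_diff,
                            T_ref_K) -> np.ndarray:
    """k_open(T) from Arrhenius-form k2 and K_D, referenced at ``T_ref_K``:

    ``k2(T) = k2_ref exp(-dE2/R (1/T - 1/T_ref))`` and likewise for K_D with
    ``dE_diff``; identical to the attempt-prefactor form but conditioned for
    fitting."""
    T = np.asarray(T_C, dtype=float) + _T0_K
    dinv = 1.0 / T - 1.0 / T_ref_K
    k2 = k2_ref * np.exp(-dE2 / R_GAS_KCAL * dinv)
    KD = KD_ref * np.exp(-dE_diff / R_GAS_KCAL * dinv)
    return k2 * R_conc / (KD + R_conc)


def fit_kopen_temperature(k_open, T_C, R_conc: float, sd=None,
                          n_starts: int = 12, seed: int = 0) -> TempBindingFit:
    """Nonlinear least squares of the temperature-dependent binding law.

    Fits ``(ln k2_ref, dE2, ln KD_ref, dE_diff)`` at the median data
    temperature by multi-start trust-region least squares on log-rate
    residuals; reproduces a non-monotonic ``k_open(T)`` whenever
    ``dE_diff > dE2``.  Requires >= 4 temperatures spanning the turnover.
    """
    k_open, T_C = _as_arrays(k_open, T_C)
    if k_open.size < 4:
        raise ValueError("need at least 4 temperatures")
    if np.any(k_open <= 0):
        raise ValueError("rates must be > 0")
    T_ref = float(np.median(T_C)) + _T0_K
    y = np.log(k_open)
    w = np.ones_like(y)
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        w = k_open / sd

    def resid(theta):
        lk2, dE2, lKD, dEd = theta
        model = kopen_temperature_model(T_C, R_conc, np.exp(lk2), dE2,
                                        np.exp(lKD), dEd, T_ref)
        return w * (np.log(model) - y)

    rng = np.random.default_rng(seed)
    lk2_0 = float(np.log(k_open.max() * 2.0))
    starts = []
    for dE2_0 in (5.0, 20.0, 40.0):
        for dEd_0 in (20.0, 80.0, 150.0):
            starts.append((lk2_0, dE2_0, np.log(max(R_conc, 1e-2)), dEd_0))
    while len(starts) < n_starts:
        starts.append((lk2_0 + rng.normal(0, 1), rng.uniform(0, 60),
                       np.log(max(R_conc, 1e-2)) + rng.normal(0, 2),
                       rng.uniform(0, 250)))
    best = None
    for x0 in starts[:max(n_starts, 9)]:
        try:
            res = least_squares(resid, np.asarray(x0), method="lm",
                                max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("temperature fit failed to converge from all starts")

    lk2, dE2, lKD, dEd = best.x
    k2_ref, KD_ref = float(np.exp(lk2)), float(np.exp(lKD))
    # 1-SD errors from the Jacobian at the optimum
    dof = k_open.size - 4
    sds = {}
    try:
        J = best.jac
        cov = np.linalg.inv(J.T @ J)
        s2 = 2.0 * best.cost / dof if (dof > 0 and sd is None) else 1.0
        perr = np.sqrt(np.clip(np.diag(cov) * s2, 0.0, None))
        sds = {"ln_k2_ref": float(perr[0]), "dE2": float(perr[1]),
               "ln_KD_ref": float(perr[2]), "dE_diff": float(perr[3])}
    except np.linalg.LinAlgError:
        pass
    k2_0 = k2_ref * float(np.exp(dE2 / (R_GAS_KCAL * T_ref)))
    KD_0 = KD_ref * float(np.exp(dEd / (R_GAS_KCAL * T_ref)))
    return TempBindingFit(k2_0=k2_0, dE2=float(dE2), KD_0=KD_0,
                          dE_diff=float(dEd), T_ref_K=T_ref,
                          k2_ref=k2_ref, KD_ref=KD_ref, sds=sds)


def salt_sensitivity(k, salt_conc) -> SaltSensitivity:
    """Log-log slope ``S = d ln k / d ln [salt]`` by least squares."""
    k, salt = _as_arrays(k, salt_conc)
    if k.size < 2:
        raise ValueError("need at least 2 concentrations")
    if np.any(k <= 0) or np.any(salt <= 0):
        raise ValueError("rates and concentrations must be > 0")
    if k.size == 2:
        S = float(np.diff(np.log(k))[0] / np.diff(np.log(salt))[0])
        return SaltSensitivity(S=S, sd=float("nan"))
    res = linregress(np.log(salt), np.log(k))
    return SaltSensitivity(S=float(res.slope), sd=float(res.stderr))
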