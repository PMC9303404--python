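"""End-to-end orchestration: simulate -> segment -> fit -> derive.

A run is driven by a flat key-value configuration (dotted keys group stage
parameters) and a single global seed; all randomness is derived from that
seed, one child stream per trace, so a rerun with the same configuration is
bit-reproducible.  Every run writes a manifest linking each artifact to its
stage, parameters and seed.

The canonical fixture condition mimics the reference buffer condition of
the assay (150 mM potassium acetate-like kinetics, K_D = 17 nM): the OS
dwell mixture is (k+ = 0.3 s^-1, k- = 0.03 s^-1, p- = 0.5), i.e.
k5 = 0.165, k3 ~ 0.110, k-3 ~ 0.055 s^-1, with k2 = 0.45 s^-1 and 5 nM
holoenzyme giving an observable closed-state exit rate near 0.096 s^-1 --
dwell scales that are long against the 172 ms effective sampling period but
short enough to collect thousands of events in a tractable simulated
ensemble, with the two mixture rates separated enough (10x) for the
mixture parameters to be well identified at a few thousand dwells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ocio
from .depfit import kopen_temperature_model
from .dwellfit import bootstrap_errors, fit_double_exp, fit_single_exp, select_model
from .dwells import DwellSet
from .schemes import (ExpMixParams, RateConstants, build_scheme, fit_to_micro,
                      phase_type_mean, propagate_errors)
from .segment import segment_trace
from .simulate import TraceConfig, render_trace, simulate_trajectory, true_dwells

__all__ = [
    "TRUE_MIXTURE",
    "canonical_rates",
    "default_config",
    "trace_config_from",
    "run_pipeline",
    "make_fixtures",
]

# OS dwell mixture of the canonical fixture condition
TRUE_MIXTURE = ExpMixParams(k_plus=0.3, k_minus=0.03, p_minus=0.5)


def canonical_rates(R_conc: float = 5.0) -> RateConstants:
    """Fixture rate constants (see module docstring)."""
    micro = fit_to_micro(TRUE_MIXTURE)
    return RateConstants(k1=0.3, k_neg1=5.1, k2=0.45,
                         k3=micro.k3, k_neg3=micro.k_neg3,
                         k5=micro.k5, R_conc=R_conc)


def default_config() -> dict:
    """Flat configuration with documented defaults for every stage."""
    cfg = {
        # kinetic scheme (s^-1; k1 in nM^-1 s^-1, R_conc in nM)
        **ocio.rates_to_config(canonical_rates()),
        # trace rendering (nm, Hz)
        "trace.z_CS": 300.0,
        "trace.jump_pos": 73.0,
        "trace.jump_neg": 42.0,
        "trace.supercoiling_sign": "+",
        "trace.noise_sd": 25.0,
        "trace.f_s": 58.0,
        "trace.decimate": 10,
        "trace.drift_rate": 0.0,
        # ensemble
        "simulate.n_traces": 4,
        "simulate.duration": 600.0,
        # segmentation: min_size 1 so that short closed-state gaps are
        # representable wherever they fall (a 2-sample event aligns with an
        # n/2 initial partition only half the time); all detected dwells are
        # kept at extraction (t_min 0) -- a detected short dwell is a real
        # 9-sigma level excursion that correctly terminates its neighbors
        "segment.penalty": 1.0,
        "segment.min_size": 1,
        "segment.t_min": 0.0,
        "segment.max_drift": 0.5,
        # fitting: likelihood truncation sits above the dwell-extraction
        # cutoff, at ~4.5 effective samples, where change-point detection is
        # complete -- shorter dwells are only partially detected and would
        # bias the truncated MLE of the fast rate
        "fit.t_min": 0.776,
        "fit.restarts": 8,
        "fit.n_boot": 1000,
        # bookkeeping
        "seed": 0,
        "output.write_traces": False,
    }
    return cfg


def trace_config_from(cfg: dict, rates: RateConstants, duration: float,
                      seed: int) -> TraceConfig:
    return TraceConfig(
        rates=rates,
        z_CS=float(cfg.get("trace.z_CS", 300.0)),
        jump_pos=float(cfg.get("trace.jump_pos", 73.0)),
        jump_neg=float(cfg.get("trace.jump_neg", 42.0)),
        supercoiling_sign=str(cfg.get("trace.supercoiling_sign", "+")),
        noise_sd=float(cfg.get("trace.noise_sd", 25.0)),
        f_s=float(cfg.get("trace.f_s", 58.0)),
        decimate=int(cfg.get("trace.decimate", 10)),
        drift_rate=float(cfg.get("trace.drift_rate", 0.0)),
        duration=duration, seed=seed)


def _truth(rates: RateConstants) -> dict:
    """Generator truth: microscopic OS rates and the observable CS exit rate
    (reciprocal mean first passage of the binding chain)."""
    cs = build_scheme("CS_chain", rates)
    return {
        "k5": rates.k5, "k3": rates.k3, "k_neg3": rates.k_neg3,
        "k_open": 1.0 / phase_type_mean(cs),
    }


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis on a simulated (or ingested) ensemble.

    Stages: simulate (or read ``input.traces``), segment, fit-dwells,
    derive-rates, report.  Any stage failure aborts with the stage name;
    artifacts of completed stages are preserved.  Returns a results dict
    with generator truth, estimates and artifact paths.
    """
    cfg = dict(default_config())
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"seed": seed, "config": {k: cfg[k] for k in sorted(cfg)},
                "stages": []}
    results = {"seed": seed}
    stage = "simulate"
    try:
        rates = ocio.rates_from_config(cfg)
        results["truth"] = _truth(rates)

        # -- simulate (or ingest) ------------------------------------------
        traces = []
        if cfg.get("input.traces"):
            paths = cfg["input.traces"]
            if isinstance(paths, str):
                paths = [p for p in paths.split(",") if p]
            traces = [ocio.read_trace(p) for p in paths]
            manifest["stages"].append({"name": "simulate", "seed": seed,
                                       "ingested": list(map(str, paths))})
        else:
            n_traces = int(cfg["simulate.n_traces"])
            duration = float(cfg["simulate.duration"])
            master = np.random.default_rng(seed)
            trace_seeds = master.integers(0, 2 ** 31 - 1, size=(n_traces, 2))
            for i in range(n_traces):
                traj = simulate_trajectory(rates, duration,
                                           seed=int(trace_seeds[i, 0]))
                tc = trace_config_from(cfg, rates, duration,
                                       seed=int(trace_seeds[i, 1]))
                traces.append((render_trace(traj, tc), true_dwells(traj)))
            if cfg.get("output.write_traces"):
                for i, (tr, td) in enumerate(traces):
                    ocio.write_trace(tr, out / f"trace_{i:03d}.tsv")
                    ocio.write_dwells(td, out / f"dwells_true_{i:03d}.tsv")
            traces = [tr for tr, _ in traces]
            manifest["stages"].append({
                "name": "simulate", "seed": seed, "n_traces": n_traces,
                "duration_s": duration})

        # -- segment -------------------------------------------------------
        stage = "segment"
        t_min = float(cfg["segment.t_min"])
        dwell_sets = []
        for tr in traces:
            _, dw = segment_trace(tr, penalty=float(cfg["segment.penalty"]),
                                  min_size=int(cfg["segment.min_size"]),
                                  t_min=t_min,
                                  max_drift=float(cfg["segment.max_drift"]))
            dwell_sets.append(dw)
        dwells = DwellSet.concatenate(dwell_sets)
        ocio.write_dwells(dwells, out / "dwells.tsv")
        manifest["stages"].append({"name": "segment", "seed": seed,
                                   "t_min_s": t_min,
                                   "penalty": cfg["segment.penalty"],
                                   "outputs": ["dwells.tsv"]})

        # -- fit dwell distributions ---------------------------------------
        stage = "fit-dwells"
        restarts = int(cfg["fit.restarts"])
        n_boot = int(cfg["fit.n_boot"])
        t_fit = max(t_min, float(cfg["fit.t_min"]))
        cs_tau = dwells.uncensored("CS")
        os_tau = dwells.uncensored("OS")
        results["n_dwells"] = {"CS": int(cs_tau.size), "OS": int(os_tau.size)}
        # likelihood truncation at t_fit: dwells below it were detected (and
        # correctly bound their neighbors) but are incompletely sampled
        cs_tau = cs_tau[cs_tau >= t_fit]
        os_tau = os_tau[os_tau >= t_fit]

        cs_fit = fit_single_exp(cs_tau, t_min=t_fit)
        cs_sds, _ = bootstrap_errors(
            cs_tau, lambda s: fit_single_exp(s, t_min=t_fit),
            n_boot=n_boot, seed=seed + 1)
        cs_fit.sds, cs_fit.n_boot = cs_sds, n_boot

        os_single = fit_single_exp(os_tau, t_min=t_fit)
        os_double = fit_double_exp(os_tau, t_min=t_fit, restarts=restarts,
                                   seed=seed + 2)
        os_model = select_model(os_single, os_double)
        warm = os_double.mixture()
        os_sds, os_failed = bootstrap_errors(
            os_tau,
            lambda s: fit_double_exp(s, t_min=t_fit, restarts=3,
                                     seed=seed + 3, init=warm),
            n_boot=n_boot, seed=seed + 4)
        os_double.sds, os_double.n_boot = os_sds, n_boot
        os_double.n_failed = os_failed

        fits = {"CS": cs_fit.to_dict(),
                "OS_single": os_single.to_dict(),
                "OS_double": os_double.to_dict(),
                "OS_selected": os_model}
        ocio.write_json(fits, out / "fits.json")
        manifest["stages"].append({"name": "fit-dwells", "seed": seed,
                                   "n_boot": n_boot, "restarts": restarts,
                                   "outputs": ["fits.json"]})

        # -- derive microscopic rates --------------------------------------
        stage = "derive-rates"
        mix = os_double.mixture()
        sds = (os_sds.get("k_plus", 0.0), os_sds.get("k_minus", 0.0),
               os_sds.get("p_minus", 0.0))
        derived = propagate_errors(mix, sds)
        est = derived.to_dict()
        est["k_open"] = cs_fit.params["k"]
        est["sd_k_open"] = cs_sds.get("k", 0.0)
        results["estimates"] = est
        ocio.write_json(est, out / "derived_rates.json")
        manifest["stages"].append({"name": "derive-rates", "seed": seed,
                                   "outputs": ["derived_rates.json"]})

        # -- report --------------------------------------------------------
        stage = "report"
        rel = {k: est[k] / results["truth"][k] - 1.0
               for k in ("k5", "k3", "k_neg3", "k_open")}
        results["relative_error"] = rel
        ocio.write_json(results, out / "results.json")
        manifest["stages"].append({"name": "report", "seed": seed,
                                   "outputs": ["results.json"]})
    except Exception as exc:
        manifest["failed_stage"] = stage
        ocio.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    ocio.write_json(manifest, out / "manifest.json")
    return results


# ---------------------------------------------------------------------------
# canonical synthetic fixtures
# ---------------------------------------------------------------------------

def _rotation_curve(turns: np.ndarray, apex: float, z0: float = 5500.0,
                    cap_width: float = 20.0, slope: float = 60.0,
                    noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """Synthetic rotation-extension hat curve: quadratic cap matched to
    linear plectonemic wings of the given slope (nm/turn).  The default cap
    is wide enough that the apex-fit window (within 90% of the maximal
    extension) stays inside the parabolic region."""
    x = np.abs(turns - apex)
    alpha = slope / (2.0 * cap_width)
    z = np.where(x <= cap_width,
                 z0 - alpha * x ** 2,
                 z0 - alpha * cap_width ** 2 - slope * (x - cap_width))
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    return z


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the canonical synthetic fixture set and its ground truth.

    (a) a single-condition trace bundle (trace TSV + true dwell TSV);
    (b) a holoenzyme-concentration series 0.2-10 nM of k_open estimates
        (exponential closed-state dwell samples at the hyperbolic-binding
        rate, 500 dwells per concentration, K_D = 17 nM, k2 = 0.16 s^-1);
    (c) a temperature series 25-45 C: a noiseless non-monotonic k_open(T)
        (dE2 = 22, dE_diff = 107 kcal/mol at 5 nM holoenzyme) and a 5%-noisy
        Arrhenius series for the RP_I dissociation rate (dE = -17.1);
    (d) a salt series with power-law k_open (S = -2.3);
    (e) a rotation-curve pair with a programmed +7.7-turn twist shift on a
        20.6 kb tether.

    All outputs are synthetic stand-ins for the non-deposited experimental
    data; the programmed parameters are written to ``synthetic_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"seed": seed}

    # (a) trace bundle
    rates = canonical_rates()
    cfg = default_config()
    for i in range(2):
        s_traj, s_rend = rng.integers(0, 2 ** 31 - 1, size=2)
        traj = simulate_trajectory(rates, 300.0, seed=int(s_traj))
        tc = trace_config_from(cfg, rates, 300.0, seed=int(s_rend))
        ocio.write_trace(render_trace(traj, tc), out / f"trace_{i}.tsv")
        ocio.write_dwells(true_dwells(traj), out / f"trace_{i}_dwells_true.tsv")
    truth["trace"] = {**rates.to_dict(), "mixture": {
        "k_plus": TRUE_MIXTURE.k_plus, "k_minus": TRUE_MIXTURE.k_minus,
        "p_minus": TRUE_MIXTURE.p_minus}}

    # (b) concentration series
    K_D, k2 = 17.0, 0.16
    R_vals = np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
    n_dwell = 500
    rows = []
    for R in R_vals:
        k_open = k2 * R / (K_D + R)
        tau = rng.exponential(1.0 / k_open, size=n_dwell)
        fit = fit_single_exp(tau, t_min=0.0)
        rows.append({"R_nM": R, "k_open": fit.params["k"],
                     "sd": fit.params["k"] / np.sqrt(n_dwell)})
    ocio.write_table(pd.DataFrame(rows), out / "concentration_series.tsv",
                     meta={"K_D_true_nM": K_D, "k2_true": k2,
                           "n_dwells": n_dwell})
    truth["concentration"] = {"K_D": K_D, "k2": k2, "n_dwells": n_dwell}

    # (c) temperature series
    T_C = np.array([25.0, 30.0, 34.0, 37.0, 41.0, 45.0])
    k2_ref, dE2, KD_ref, dE_diff, T_ref, R_conc = 0.23, 22.0, 1.3, 107.0, 310.15, 5.0
    k_open_T = kopen_temperature_model(T_C, R_conc, k2_ref, dE2, KD_ref,
                                       dE_diff, T_ref)
    ocio.write_table(pd.DataFrame({"T_C": T_C, "k_open": k_open_T}),
                     out / "temperature_kopen.tsv",
                     meta={"R_nM": R_conc, "dE2_true": dE2,
                           "dE_diff_true": dE_diff})
    dE5, k5_34 = -17.1, 0.0385
    from .depfit import R_GAS_KCAL
    k5_T = k5_34 * np.exp(-dE5 / R_GAS_KCAL * (1 / (T_C + 273.15) - 1 / 307.15))
    k5_noisy = k5_T * np.exp(rng.normal(0.0, 0.05, size=T_C.size))
    ocio.write_table(pd.DataFrame({"T_C": T_C, "k5": k5_noisy,
                                   "sd": 0.05 * k5_noisy}),
                     out / "temperature_k5.tsv", meta={"dE5_true": dE5})
    truth["temperature"] = {"dE2": dE2, "dE_diff": dE_diff, "k2_ref": k2_ref,
                            "KD_ref": KD_ref, "T_ref_K": T_ref,
                            "R_nM": R_conc, "dE5": dE5}

    # (d) salt series
    salt = np.array([50.0, 75.0, 100.0, 125.0, 150.0])
    S_true, k150 = -2.3, 0.1
    k_salt = k150 * (salt / 150.0) ** S_true
    ocio.write_table(pd.DataFrame({"salt_mM": salt, "k_open": k_salt}),
                     out / "salt_series.tsv", meta={"S_true": S_true})
    truth["salt"] = {"S": S_true}

    # (e) rotation-curve pair
    turns = np.arange(-40.0, 40.5, 1.0)
    shift, length_kb = 7.7, 20.6
    z_ref = _rotation_curve(turns, 0.0, noise_sd=5.0, rng=rng)
    z_test = _rotation_curve(turns, shift, noise_sd=5.0, rng=rng)
    ocio.write_table(pd.DataFrame({"turns": turns, "extension_nm": z_ref}),
                     out / "rotation_ref.tsv", meta={"length_kb": length_kb})
    ocio.write_table(pd.DataFrame({"turns": turns, "extension_nm": z_test}),
                     out / "rotation_test.tsv",
                     meta={"length_kb": length_kb, "shift_true": shift})
    truth["rotation"] = {"delta_turns": shift, "length_kb": length_kb}

    ocio.write_json(truth, out / "synthetic_truth.json")
    return truth
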