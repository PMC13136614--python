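"""The integrated cell-process digital twin.

Couples the three modeling layers into one fully predictive forward
simulator: the growth network supplies the net specific growth rate from
metabolic features, the kinetic ODE layer supplies death/lysis rates (hence
the effective growth rate) and the five FLEX metabolite rates, and PC-dFBA
supplies every remaining exchange flux, including product titer.  All layers
are advanced together on a 0.1-day grid through the bioreactor mass balance

    dE/dt = r_E X_V - (F/V) E + (F/V) E_in

with bolus feeds applied as instantaneous mixing events.  After
initialization nothing measured is read: the twin sees only the initial
state and the feed schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pcdfba
from .growth import GrowthModel, assemble_features
from .kinetics import (
    KineticParameters,
    PopulationState,
    death_lysis_rates,
    effective_growth,
    flex_specific_rates,
)
from .network import MetabolicNetwork
from .records import FLEX_ANALYTES, GROWTH_RATE_NAME, ProcessRecord


@dataclass
class TwinConfig:
    dt: float = 0.1                       # days
    horizon: float = 14.0
    rf: float = 1.5
    flux_per_rate: float = 1.0            # specific rate -> model flux units
    continuity_mode: str = "qp"
    concentration_floor: float = 0.0
    seed: int = 0


@dataclass
class TwinResult:
    times: np.ndarray
    concentrations: pd.DataFrame          # time x analytes (g/l)
    vcd: np.ndarray
    dead: np.ndarray
    lysed: np.ndarray
    biomaterial: np.ndarray
    mu: np.ndarray                        # net growth (1/d)
    mu_eff: np.ndarray
    volume: np.ndarray
    fluxes: pd.DataFrame
    scores: np.ndarray
    relaxed_steps: list[int] = field(default_factory=list)
    floored_events: list[tuple[float, str]] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)


def mass_balance_step(E, rE, Xv, F, V, E_in, dt):
    """One explicit-Euler step of the bioreactor mass balance.

    ``rE`` is the signed specific rate (production positive).  With ``F = 0``
    only the cellular term acts; with continuous feeding the dilution and
    feed-source terms apply.
    """
    E = np.asarray(E, dtype=float)
    rE = np.asarray(rE, dtype=float)
    dEdt = rE * Xv - (F / V) * (E - np.asarray(E_in, dtype=float))
    return E + dEdt * dt


def run_twin(initial: dict, feed_schedule, growth_model: GrowthModel,
             kinetic_params: KineticParameters, network: MetabolicNetwork,
             loading_model: pcdfba.LoadingModel, band_stats: pcdfba.BandStats,
             config: TwinConfig | None = None, score_bounds=None,
             rate_percentiles=None) -> TwinResult:
    """Fully predictive twin simulation from initial state and feeds alone.

    ``initial`` must provide ``vcd`` (1e6 cells/ml), ``volume_ml`` and
    initial concentrations for the analyte panel.  Per step the layers run
    in sequence: growth network (mu), kinetic layer (mu_d, mu_l -> mu_eff,
    FLEX rates), PC-dFBA (free exchanges + titer), then the mass balance and
    the population/biomaterial recurrences advance the state.  Exchange-rate
    features for the growth network come from the previous PC-dFBA step
    (one-step lag), which breaks the simultaneity of the layer coupling.
    """
    cfg = config or TwinConfig()
    times = np.arange(0.0, cfg.horizon + cfg.dt / 2, cfg.dt)
    analytes = [a for a in band_stats.analytes if a != GROWTH_RATE_NAME]
    conc = {a: max(float(initial.get(a, 0.0)), 0.0) for a in analytes}
    xv = float(initial["vcd"])
    xd = float(initial.get("dead", 0.0))
    xl = float(initial.get("lysed", 0.0))
    gamma = float(initial.get("biomaterial", 0.0))
    volume = float(initial.get("volume_ml", 1.0))

    prev_mu = float(growth_model.baseline(times[:1])[0])
    # before the first PC-dFBA step, rate features fall back to the training
    # median at t=0 (prior knowledge, not a measurement of this batch)
    med0, _ = band_stats.at(0.0)
    prev_rates: dict[str, float] = {
        a: float(m) for a, m in zip(band_stats.analytes, med0)}
    prev_flux = None

    rows_c, rows_f, rows_s, diags = [], [], [], []
    xv_t, xd_t, xl_t, g_t, mu_t, mueff_t, vol_t = [], [], [], [], [], [], []
    relaxed, floored = [], []

    for k, t in enumerate(times):
        # (1) growth network: mu from lagged rates/concentrations
        growth_feats = growth_model.feature_analytes
        feat_rates = np.array([prev_rates.get(a, 0.0) for a in growth_feats])
        feat_conc = np.array([conc.get(a, 0.0) for a in growth_feats])
        x = assemble_features(feat_rates, feat_conc, prev_mu, gamma, cfg.dt)
        dev = growth_model.network.predict(growth_model.standardize(x))[0]
        mu = float(growth_model.baseline(np.array([t]))[0]) + dev

        # (2) kinetic layer: death/lysis, mu_eff, FLEX rates
        pop = PopulationState(xv, xd, xl, gamma)
        mu_d, mu_l = death_lysis_rates(pop, kinetic_params)
        mu_eff = float(effective_growth(mu, mu_d, mu_l))
        flex_conc = np.array([conc[a] for a in FLEX_ANALYTES])
        flex_rates = flex_specific_rates(flex_conc, mu_eff, kinetic_params)
        hb = {GROWTH_RATE_NAME: mu_eff}
        hb.update({a: r for a, r in zip(FLEX_ANALYTES, flex_rates)})

        # (3) PC-dFBA: free exchange fluxes under hybrid constraints
        rate_vec = []
        for a in loading_model.feature_analytes:
            rate_vec.append(hb.get(a, prev_rates.get(a, 0.0)))
        loadings = loading_model.predict_loadings(np.asarray(rate_vec))
        hard = {a: (v if a == GROWTH_RATE_NAME else v * cfg.flux_per_rate)
                for a, v in hb.items()}
        problem = pcdfba.build_step_problem(
            network, loadings, band_stats.analytes, hard, band_stats.at(t),
            cfg.rf, score_bounds, prev_flux)
        perc = rate_percentiles(t) if rate_percentiles else {
            a: (v - 0.3 * abs(v) - 1e-3, v + 0.3 * abs(v) + 1e-3)
            for a, v in hard.items()}
        try:
            sol = pcdfba.solve_with_fallback(problem, cfg.continuity_mode, perc)
        except pcdfba.StepInfeasibleError as err:
            raise RuntimeError(
                f"twin layer pc_dfba failed at t={t:.2f} d: "
                "irreducibly infeasible") from err
        if sol.relaxed:
            relaxed.append(k)
        flux = {a: sol.fluxes[i] for a, i in
                zip(problem.measured_analytes, problem.measured_rows)}

        rows_c.append(dict(conc))
        rows_f.append(flux)
        rows_s.append(sol.scores)
        xv_t.append(xv); xd_t.append(xd); xl_t.append(xl); g_t.append(gamma)
        mu_t.append(mu); mueff_t.append(mu_eff); vol_t.append(volume)
        diags.append({"t": float(t), "objective": sol.objective,
                      "relaxed": sol.relaxed,
                      "band_violation": sol.band_violation,
                      "continuity_penalty": sol.continuity_penalty})
        if k == len(times) - 1:
            break

        # (4) dynamic update: mass balance, population, feeds
        rates_all = {a: flux[a] / cfg.flux_per_rate for a in analytes}
        for a in FLEX_ANALYTES:          # kinetic layer owns the FLEX rates
            rates_all[a] = float(hb[a])
        xv_mid = xv * float(np.exp(0.5 * mu * cfg.dt))   # second-order update
        for a in analytes:
            new = float(mass_balance_step(conc[a], rates_all[a], xv_mid, 0.0,
                                          volume, 0.0, cfg.dt))
            if new < cfg.concentration_floor:
                floored.append((float(t), a))
                new = cfg.concentration_floor
            conc[a] = new
        xv_new = xv * float(np.exp(mu * cfg.dt))
        xd = xd + mu_d * xv_mid * cfg.dt
        xl = xl + mu_l * xv_mid * cfg.dt
        gamma = gamma + xv_mid * cfg.dt
        xv = xv_new
        for vol, comp in (feed_schedule(t, t + cfg.dt) if feed_schedule else []):
            if comp is None:
                volume = max(volume - vol, 1e-6)
                continue
            d = volume / (volume + vol)
            for a in analytes:
                conc[a] = conc[a] * d + comp.get(a, 0.0) * (1 - d)
            xv *= d; xd *= d; xl *= d; gamma *= d
            volume += vol
        prev_mu = mu
        prev_rates = rates_all
        prev_rates[GROWTH_RATE_NAME] = mu
        prev_flux = sol.fluxes

    n = len(rows_c)
    return TwinResult(
        times=times[:n],
        concentrations=pd.DataFrame(rows_c, index=times[:n]),
        vcd=np.asarray(xv_t), dead=np.asarray(xd_t), lysed=np.asarray(xl_t),
        biomaterial=np.asarray(g_t), mu=np.asarray(mu_t),
        mu_eff=np.asarray(mueff_t), volume=np.asarray(vol_t),
        fluxes=pd.DataFrame(rows_f, index=times[:n]),
        scores=np.asarray(rows_s), relaxed_steps=relaxed,
        floored_events=floored, diagnostics=diags)


def evaluate(result: TwinResult, observed: ProcessRecord,
             variables=None) -> pd.DataFrame:
    """Per-variable fit quality of a twin run against an observed record.

    Simulated values are interpolated to the observation times; for each
    variable the table reports SSE, ln(SSE) and ``R^2 = 1 - SSE/SStot``.
    Zero-variance observation series yield an undefined (NaN) R^2.
    """
    t_obs = observed.times_d
    if t_obs.max() > result.times.max() + 1e-9:
        raise ValueError("observations extend beyond the simulated horizon")
    variables = list(variables) if variables is not None else (
        ["vcd"] + [a for a in observed.analytes
                   if a in result.concentrations.columns])
    rows = []
    for var in variables:
        obs = observed.vcd if var == "vcd" else observed.series(var)
        sim_series = result.vcd if var == "vcd" \
            else result.concentrations[var].values
        sim = np.interp(t_obs, result.times, sim_series)
        sse = float(np.sum((sim - obs) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        rows.append({"variable": var, "sse": sse,
                     "log_sse": float(np.log(sse)) if sse > 0 else -np.inf,
                     "r2": 1.0 - sse / sst if sst > 0 else np.nan})
    return pd.DataFrame(rows).set_index("variable")
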