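"""Kinetic ODE models for the cell population and the five FLEX metabolites.

Two coupled mechanistic layers:

* a **biomass population model** with viable (``Xv``), dead (``Xd``) and lysed
  (``Xl``) cell pools plus the cumulative "biomaterial" variable ``gammaX``
  (the time integral of VCD, a catch-all proxy for accumulated inhibitory
  by-products).  Death and lysis rates are base rates modulated linearly by
  biomaterial and lysed-cell toxicity.
* a **FLEX metabolite model** for glucose, lactate, glutamine, glutamate and
  ammonium, with substrate saturation (``tanh`` of squared reduced
  concentration), cubic lactate inhibition of glucose uptake, overflow
  metabolism (lactate produced only when glucose uptake exceeds the oxidative
  capacity), and maintenance terms.

Unit conventions
----------------
Time is in **days** throughout this module.  Specific rates are in
g per 1e9 cells per day, VCD in 1e6 cells/ml and concentrations in g/l, so a
concentration derivative is numerically ``rate * vcd`` in g/l/day.  Rate-law
formulas return *magnitudes* (consumption rates are positive numbers); the
mass-balance right-hand sides apply the sign convention (consumption enters
with a minus, production with a plus), matching the global exchange-flux
convention used by the flux-balance layer (production positive).

Fed-batch feeding is represented as discrete bolus events: between events the
feed rate ``F`` is zero and dilution acts only through the instantaneous
mixing jumps applied by the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.optimize import minimize

#: Floor applied to the effective growth rate, in 1/day.
MU_EFF_FLOOR = 1e-6

FLEX_STATE_NAMES = ("glucose", "lactate", "glutamine", "glutamate", "ammonium")


@dataclass(frozen=True)
class KineticParameters:
    """Identified parameter set of the population + FLEX models.

    Defaults are the canonical identified values; units follow the module
    convention (per-day rates, g/l concentrations, 1e6 cells/ml cell pools).
    """

    # population model
    kd: float = 0.01794129          # base death rate, 1/d
    kTd: float = 0.00033013         # biomaterial toxicity on death
    kl: float = 0.02962941          # base lysis rate, 1/d
    kTl: float = 0.01359236         # lysed-cell toxicity on lysis
    # glucose
    YG: float = 13.2705431          # growth-linked glucose yield
    KG: float = 25.4521167          # glucose half-saturation, g/l
    KI: float = 8.18034685          # lactate inhibition constant, g/l
    mGlc: float = 0.882132146       # glucose maintenance, g/1e9 cells/d
    # lactate / overflow
    vOx_max: float = 1.64619067     # maximum oxidative capacity, g/1e9 cells/d
    KLac: float = 53.1522878        # lactate reuptake half-saturation, g/l
    YLac_Prod: float = 2.56537542
    YLac_Cons: float = 1.17984249
    # glutamate
    YGlu: float = 2.99191279e-07
    KGlu: float = 0.00151171924     # g/l
    mGlu: float = 0.00926153436     # g/1e9 cells/d
    # glutamine
    vGln_max: float = 2.68030547    # g/1e9 cells/d
    KGln: float = 2.69282272        # g/l
    # ammonium
    YN_Glu: float = 20.8763687
    YN_Gln: float = 0.722160623

    POPULATION_NAMES = ("kd", "kTd", "kl", "kTl")
    FLEX_NAMES = (
        "YG", "KG", "KI", "mGlc", "vOx_max", "KLac", "YLac_Prod", "YLac_Cons",
        "YGlu", "KGlu", "mGlu", "vGln_max", "KGln", "YN_Glu", "YN_Gln",
    )

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_values(self, **kw: float) -> "KineticParameters":
        return replace(self, **kw)


@dataclass
class PopulationState:
    Xv: float       # viable cells, 1e6/ml
    Xd: float       # dead cells
    Xl: float       # lysed cells
    gammaX: float   # biomaterial, 1e6 cells*d/ml

    def as_array(self) -> np.ndarray:
        return np.array([self.Xv, self.Xd, self.Xl, self.gammaX], dtype=float)


@dataclass(frozen=True)
class FeedInput:
    """Continuous feeding descriptor (zero between bolus events)."""

    F: float = 0.0          # feed rate, ml/d
    V: float = 1.0          # reactor volume, ml
    Glc_in: float = 0.0     # g/l
    Gln_in: float = 0.0
    Glu_in: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0 or self.V <= 0:
            raise ValueError("feed rate must be >= 0 and volume > 0")


# --------------------------------------------------------------------------
# rate laws
# --------------------------------------------------------------------------

def death_lysis_rates(state: PopulationState, params: KineticParameters) -> tuple[float, float]:
    """Death and lysis rates: base rates plus linear toxicity terms."""
    mu_d = params.kd + params.kTd * state.gammaX
    mu_l = params.kl + params.kTl * state.Xl
    return mu_d, mu_l


def effective_growth(mu_net, mu_d, mu_l):
    """Effective biomass synthesis rate ``mu_eff = mu + mu_d + mu_l``.

    The net growth rate observed in VCD data already includes losses to death
    and lysis; adding them back gives the synthesis rate that constrains the
    metabolic model.  Values below the floor are truncated to ``1e-6 /d``.
    """
    return np.maximum(np.asarray(mu_net) + mu_d + mu_l, MU_EFF_FLOOR)


def rate_glc(Glc: float, Lac: float, mu_eff: float, p: KineticParameters) -> float:
    """Specific glucose consumption (magnitude, g/1e9 cells/d).

    Growth-linked uptake saturates in glucose (tanh of the squared reduced
    concentration), is inhibited by lactate with a cubic denominator, and a
    constant maintenance demand is always present.
    """
    sat = np.tanh((Glc / p.KG) ** 2)
    inhib = 1.0 / ((Lac / p.KI) ** 3 + 1.0)
    return p.YG * mu_eff * sat * inhib + p.mGlc


def rate_lac(vGlc: float, Lac: float, p: KineticParameters) -> float:
    """Net specific lactate rate (production positive, g/1e9 cells/d).

    Overflow metabolism: lactate is produced only when glucose uptake exceeds
    the oxidative capacity, and consumed (if present) when capacity is spare.
    The two branches are mutually exclusive by construction.
    """
    prod = max(0.0, vGlc - p.vOx_max)
    cons = max(0.0, p.vOx_max - vGlc) * np.tanh((Lac / p.KLac) ** 2)
    return p.YLac_Prod * prod - p.YLac_Cons * cons


def rate_glu(Glu: float, mu_eff: float, p: KineticParameters) -> float:
    """Specific glutamate consumption (magnitude)."""
    return p.YGlu * mu_eff * np.tanh((Glu / p.KGlu) ** 2) + p.mGlu


def rate_gln(Gln: float, p: KineticParameters) -> float:
    """Specific glutamine consumption (magnitude), saturating in glutamine."""
    return p.vGln_max * np.tanh((Gln / p.KGln) ** 2)


def rate_nh4(vGlu: float, vGln: float, p: KineticParameters) -> float:
    """Ammonium production as a by-product of glutamate/glutamine catabolism."""
    return p.YN_Glu * vGlu + p.YN_Gln * vGln


def flex_specific_rates(conc: np.ndarray, mu_eff: float, p: KineticParameters) -> np.ndarray:
    """Signed specific rates for the five FLEX metabolites (production > 0).

    ``conc`` is ordered as :data:`FLEX_STATE_NAMES`.
    """
    Glc, Lac, Gln, Glu, _ = np.maximum(conc, 0.0)
    vGlc = rate_glc(Glc, Lac, mu_eff, p)
    vLac = rate_lac(vGlc, Lac, p)
    vGlu = rate_glu(Glu, mu_eff, p)
    vGln = rate_gln(Gln, p)
    vNH4 = rate_nh4(vGlu, vGln, p)
    return np.array([-vGlc, vLac, -vGln, -vGlu, vNH4])


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------

def population_rhs(
    state: PopulationState,
    params: KineticParameters,
    mu_eff: float,
    F_over_V: float = 0.0,
) -> np.ndarray:
    """Population balances.  Dilution removes cells: ``-(F/V) * X``.

    Returns d/dt of ``(Xv, Xd, Xl, gammaX)``.
    """
    mu_d, mu_l = death_lysis_rates(state, params)
    dXv = (mu_eff - mu_d - mu_l) * state.Xv - F_over_V * state.Xv
    dXd = mu_d * state.Xv - F_over_V * state.Xd
    dXl = mu_l * state.Xv - F_over_V * state.Xl
    dG = state.Xv - F_over_V * state.gammaX
    return np.array([dXv, dXd, dXl, dG])


def flex_rhs(
    conc: np.ndarray,
    params: KineticParameters,
    mu_eff: float,
    Xv: float,
    feed: FeedInput | None = None,
) -> np.ndarray:
    """FLEX metabolite balances: cellular exchange plus dilution.

    Fed species (glucose, glutamine, glutamate) carry a feed source term;
    lactate and ammonium only wash out.
    """
    rates = flex_specific_rates(conc, mu_eff, params)
    d = rates * Xv
    if feed is not None and feed.F > 0:
        fv = feed.F / feed.V
        feed_conc = np.array([feed.Glc_in, 0.0, feed.Gln_in, feed.Glu_in, 0.0])
        d = d + fv * (feed_conc - conc)
    return d


# --------------------------------------------------------------------------
# event-driven fixed-step integration
# --------------------------------------------------------------------------

def _build_mesh(t_out: np.ndarray, event_times: list[float], dt_max: float) -> np.ndarray:
    knots = np.unique(np.concatenate([t_out, np.asarray(event_times, dtype=float)]))
    mesh = [knots[0]]
    for a, b in zip(knots[:-1], knots[1:]):
        n = max(1, int(np.ceil((b - a) / dt_max)))
        mesh.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(mesh)


def integrate_events(rhs, y0, t_out, events=None, dt_max=0.02):
    """RK4 integration with instantaneous state jumps at event times.

    Parameters
    ----------
    rhs : callable ``(t, y) -> dy/dt``
    events : list of ``(time, apply)`` where ``apply(y) -> y`` is the jump
        map; the state recorded at an event time is the post-event state.
    t_out : output grid (must contain ``t0``).

    Returns array of shape ``(len(t_out), len(y0))``.  Raises ``FloatingPointError``
    naming the first non-finite state component.
    """
    t_out = np.asarray(t_out, dtype=float)
    events = sorted(events or [], key=lambda e: e[0])
    mesh = _build_mesh(t_out, [e[0] for e in events], dt_max)
    ev_idx = 0
    y = np.asarray(y0, dtype=float).copy()
    out = np.empty((len(t_out), len(y)))
    out_idx = 0

    def record(t, y):
        nonlocal out_idx
        while out_idx < len(t_out) and np.isclose(t, t_out[out_idx], atol=1e-12, rtol=0):
            out[out_idx] = y
            out_idx += 1

    # events exactly at t0 apply before the first record
    while ev_idx < len(events) and events[ev_idx][0] <= mesh[0] + 1e-12:
        y = events[ev_idx][1](y)
        ev_idx += 1
    record(mesh[0], y)
    for a, b in zip(mesh[:-1], mesh[1:]):
        h = b - a
        k1 = rhs(a, y)
        k2 = rhs(a + h / 2, y + h / 2 * k1)
        k3 = rhs(a + h / 2, y + h / 2 * k2)
        k4 = rhs(b, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        while ev_idx < len(events) and events[ev_idx][0] <= b + 1e-12:
            y = events[ev_idx][1](y)
            ev_idx += 1
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y)))
            raise FloatingPointError(f"non-finite state component {bad} at t={b:.3f} d")
        record(b, y)
    return out


# --------------------------------------------------------------------------
# compiled FLEX simulator for parameter identification
# --------------------------------------------------------------------------
# Identification evaluates the FLEX ODEs thousands of times inside
# Nelder--Mead; the generic event-driven integrator is far too slow for
# that, so the fitting path precomputes the time mesh, the imposed
# mu_eff/Xv profiles and the (affine) bolus maps once per batch and runs a
# JIT-compiled fixed-step RK4.  Equivalence with the generic integrator is
# asserted in the test suite.

from numba import njit


@njit(cache=True)
def _flex_rates_nb(c, mu_eff, p):
    Glc = max(c[0], 0.0)
    Lac = max(c[1], 0.0)
    Gln = max(c[2], 0.0)
    Glu = max(c[3], 0.0)
    # p: YG KG KI mGlc vOx KLac YLP YLC YGlu KGlu mGlu vGlnmax KGln YNGlu YNGln
    vGlc = p[0] * mu_eff * np.tanh((Glc / p[1]) ** 2) \
        / ((Lac / p[2]) ** 3 + 1.0) + p[3]
    prod = max(0.0, vGlc - p[4])
    cons = max(0.0, p[4] - vGlc) * np.tanh((Lac / p[5]) ** 2)
    vLac = p[6] * prod - p[7] * cons
    vGlu = p[8] * mu_eff * np.tanh((Glu / p[9]) ** 2) + p[10]
    vGln = p[11] * np.tanh((Gln / p[12]) ** 2)
    vNH4 = p[13] * vGlu + p[14] * vGln
    out = np.empty(5)
    out[0] = -vGlc
    out[1] = vLac
    out[2] = -vGln
    out[3] = -vGlu
    out[4] = vNH4
    return out


@njit(cache=True)
def _flex_rk4_nb(p, c0, h, mu3, xv3, dil, feedc, out_mask):
    """RK4 over a fixed mesh with affine bolus maps applied at nodes.

    mu3/xv3: (n_steps, 3) values at (t, t+h/2, t+h); dil/feedc: per-node
    affine event maps (c -> dil*c + feedc) applied after reaching the node.
    """
    n_steps = h.shape[0]
    n_out = 0
    for k in range(out_mask.shape[0]):
        if out_mask[k]:
            n_out += 1
    traj = np.empty((n_out, 5))
    c = c0.copy()
    io = 0
    if out_mask[0]:
        traj[0] = c
        io = 1
    for k in range(n_steps):
        hk = h[k]
        k1 = _flex_rates_nb(c, mu3[k, 0], p) * xv3[k, 0]
        k2 = _flex_rates_nb(c + 0.5 * hk * k1, mu3[k, 1], p) * xv3[k, 1]
        k3 = _flex_rates_nb(c + 0.5 * hk * k2, mu3[k, 1], p) * xv3[k, 1]
        k4 = _flex_rates_nb(c + hk * k3, mu3[k, 2], p) * xv3[k, 2]
        c = c + hk / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        c = c * dil[k + 1] + feedc[k + 1]
        if out_mask[k + 1]:
            traj[io] = c
            io += 1
    return traj


def _prepare_flex_batch(b, dt_max=0.05):
    """Precompute mesh, imposed profiles and event maps for one batch."""
    times = np.asarray(b["times"], dtype=float)
    events = b.get("events") or []
    mesh = _build_mesh(times, [e[0] for e in events], dt_max)
    n_steps = len(mesh) - 1
    h = np.diff(mesh)
    mu3 = np.empty((n_steps, 3))
    xv3 = np.empty((n_steps, 3))
    for j, frac in enumerate((0.0, 0.5, 1.0)):
        tt = mesh[:-1] + frac * h
        mu3[:, j] = [float(b["mu_eff"](t)) for t in tt]
        xv3[:, j] = [float(b["xv"](t)) for t in tt]
    dil = np.ones(len(mesh))
    feedc = np.zeros((len(mesh), 5))
    for t_ev, apply in sorted(events, key=lambda e: e[0]):
        k = int(np.argmin(np.abs(mesh - t_ev)))
        zero = np.zeros(5)
        f = apply(zero)
        d = apply(np.ones(5)) - f
        # compose with any earlier event at the same node
        feedc[k] = feedc[k] * d[0] + f
        dil[k] = dil[k] * d[0]
    out_mask = np.zeros(len(mesh), dtype=np.bool_)
    for t in times:
        out_mask[int(np.argmin(np.abs(mesh - t)))] = True
    return {"c0": np.asarray(b["c0"], dtype=float), "h": h, "mu3": mu3,
            "xv3": xv3, "dil": dil, "feedc": feedc, "out_mask": out_mask}


def simulate_flex_fast(params: KineticParameters, prepared) -> np.ndarray:
    p = np.array([getattr(params, n) for n in KineticParameters.FLEX_NAMES])
    return _flex_rk4_nb(p, prepared["c0"], prepared["h"], prepared["mu3"],
                        prepared["xv3"], prepared["dil"], prepared["feedc"],
                        prepared["out_mask"])


@njit(cache=True)
def _pop_rk4_nb(p, y0, h, mu3, dil, out_mask):
    """Population-model RK4 with imposed net growth and bolus dilutions.

    ``p = (kd, kTd, kl, kTl)``; state ``y = (Xv, Xd, Xl, gammaX)``.
    """
    def rhs(y, mu_net):
        mu_d = p[0] + p[1] * y[3]
        mu_l = p[2] + p[3] * y[2]
        mu_eff = max(mu_net + mu_d + mu_l, MU_EFF_FLOOR)
        out = np.empty(4)
        out[0] = (mu_eff - mu_d - mu_l) * y[0]
        out[1] = mu_d * y[0]
        out[2] = mu_l * y[0]
        out[3] = y[0]
        return out

    n_steps = h.shape[0]
    n_out = 0
    for k in range(out_mask.shape[0]):
        if out_mask[k]:
            n_out += 1
    traj = np.empty((n_out, 4))
    y = y0.copy()
    io = 0
    if out_mask[0]:
        traj[0] = y
        io = 1
    for k in range(n_steps):
        hk = h[k]
        k1 = rhs(y, mu3[k, 0])
        k2 = rhs(y + 0.5 * hk * k1, mu3[k, 1])
        k3 = rhs(y + 0.5 * hk * k2, mu3[k, 1])
        k4 = rhs(y + hk * k3, mu3[k, 2])
        y = (y + hk / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)) * dil[k + 1]
        if out_mask[k + 1]:
            traj[io] = y
            io += 1
    return traj


def _prepare_pop_batch(b, dt_max=0.05):
    times = np.asarray(b["times"], dtype=float)
    events = b.get("events") or []
    mesh = _build_mesh(times, [e[0] for e in events], dt_max)
    h = np.diff(mesh)
    mu3 = np.empty((len(h), 3))
    for j, frac in enumerate((0.0, 0.5, 1.0)):
        mu3[:, j] = [float(b["mu"](t)) for t in mesh[:-1] + frac * h]
    dil = np.ones(len(mesh))
    for t_ev, apply in events:
        k = int(np.argmin(np.abs(mesh - t_ev)))
        dil[k] *= float(apply(np.ones(4))[0])
    out_mask = np.zeros(len(mesh), dtype=np.bool_)
    for t in times:
        out_mask[int(np.argmin(np.abs(mesh - t)))] = True
    return {"y0": b["x0"].as_array(), "h": h, "mu3": mu3, "dil": dil,
            "out_mask": out_mask}


# --------------------------------------------------------------------------
# parameter identification (Nelder--Mead, log-parameterized, multi-start)
# --------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    n_starts: int = 5
    maxiter: int = 4000
    n_restarts: int = 3          # NM restarts from the incumbent best point
    ftol: float = 1e-10
    perturbation: float = 0.3    # multiplicative spread of extra starts
    seed: int = 0
    penalty_lambda: float = 10.0  # dead/lysed comparability soft penalty


@dataclass
class IdentificationResult:
    params: KineticParameters
    sse: float
    n_evals: int
    per_metabolite_sse: dict[str, float] = field(default_factory=dict)
    per_metabolite_r2: dict[str, float] = field(default_factory=dict)


def _nelder_mead(objective, x0_list, cfg: OptimizerConfig):
    best_x, best_f, n_evals = None, np.inf, 0
    for x0 in x0_list:
        x = np.asarray(x0, dtype=float)
        for _ in range(max(1, cfg.n_restarts)):
            res = minimize(
                objective, x, method="Nelder-Mead",
                options={"maxiter": cfg.maxiter, "fatol": cfg.ftol,
                         "xatol": 1e-10, "adaptive": True},
            )
            n_evals += res.nfev
            x = res.x
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x.copy()
    return best_x, best_f, n_evals


def identify_population(batches, config: OptimizerConfig | None = None,
                        init: KineticParameters | None = None) -> IdentificationResult:
    """Fit ``(kd, kTd, kl, kTl)`` to viable and dead biomass profiles.

    ``batches`` is a list of dicts with keys ``times`` (days), ``xv_obs``,
    ``xd_obs`` (1e6 cells/ml), ``mu`` (callable, net growth 1/d), ``x0``
    (initial ``PopulationState``) and optional ``events``.  The net growth
    rate is imposed, so the viable pool is parameter-free and the dead pool
    identifies the death-rate parameters; the unobservable lysed pool is kept
    in a biologically sensible range by a soft penalty on ``|log(Xl/Xd)|``
    exceeding ``log 3``.
    """
    cfg = config or OptimizerConfig()
    p0 = init or KineticParameters()
    names = KineticParameters.POPULATION_NAMES
    log3 = np.log(3.0)
    prepared = [_prepare_pop_batch(b) for b in batches]

    def objective(logx):
        p = np.exp(np.clip(logx, -40.0, 40.0))
        total = 0.0
        for prep, b in zip(prepared, batches):
            traj = _pop_rk4_nb(p, prep["y0"], prep["h"], prep["mu3"],
                               prep["dil"], prep["out_mask"])
            if not np.all(np.isfinite(traj)):
                return 1e12
            xv, xd, xl = traj[:, 0], traj[:, 1], traj[:, 2]
            sxv = max(np.std(b["xv_obs"]), 1e-9)
            sxd = max(np.std(b["xd_obs"]), 1e-9)
            total += np.sum(((xv - b["xv_obs"]) / sxv) ** 2)
            total += np.sum(((xd - b["xd_obs"]) / sxd) ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.abs(np.log(np.maximum(xl, 1e-12) / np.maximum(xd, 1e-12)))
            total += cfg.penalty_lambda * np.sum(np.maximum(0.0, ratio - log3) ** 2)
        return total

    x0 = np.log([getattr(p0, n) for n in names])
    rng = np.random.default_rng(cfg.seed)
    starts = [x0] + [x0 + np.log(1 + cfg.perturbation * rng.uniform(-1, 1, len(x0)))
                     for _ in range(cfg.n_starts - 1)]
    if cfg.maxiter == 0:
        return IdentificationResult(p0, objective(x0), 1)
    best_x, best_f, n_evals = _nelder_mead(objective, starts, cfg)
    fitted = p0.with_values(**dict(zip(
        names, np.exp(np.clip(best_x, -40.0, 40.0)))))
    return IdentificationResult(fitted, best_f, n_evals)


def identify_flex(batches, config: OptimizerConfig | None = None,
                  init: KineticParameters | None = None,
                  fit_names: tuple[str, ...] | None = None,
                  include: tuple[str, ...] = FLEX_STATE_NAMES) -> IdentificationResult:
    """Fit the 15 FLEX parameters to measured metabolite concentrations.

    ``batches`` entries need ``times``, ``conc_obs`` (n_times x 5, ordered as
    :data:`FLEX_STATE_NAMES`), ``mu_eff`` (callable, 1/d), ``xv`` (callable),
    ``c0`` (initial 5-vector) and optional ``events`` (bolus jump maps acting
    on the 5-vector).  Viable-cell dynamics are imposed, not fitted.  The SSE
    is standardized per metabolite so that differently scaled analytes
    contribute comparably; ``include`` restricts which metabolites enter the
    objective (ablation support).
    """
    cfg = config or OptimizerConfig()
    p0 = init or KineticParameters()
    names = tuple(fit_names or KineticParameters.FLEX_NAMES)
    mask = np.array([m in include for m in FLEX_STATE_NAMES])

    prepared = [_prepare_flex_batch(b) for b in batches]

    scales = []
    for b in batches:
        s = np.std(b["conc_obs"], axis=0)
        scales.append(np.maximum(s, 1e-6))

    base = np.array([getattr(p0, n) for n in KineticParameters.FLEX_NAMES])
    pos = [KineticParameters.FLEX_NAMES.index(n) for n in names]

    def objective(logx):
        p = base.copy()
        p[pos] = np.exp(np.clip(logx, -40.0, 40.0))
        total = 0.0
        for prep, b, s in zip(prepared, batches, scales):
            traj = _flex_rk4_nb(p, prep["c0"], prep["h"], prep["mu3"],
                                prep["xv3"], prep["dil"], prep["feedc"],
                                prep["out_mask"])
            if not np.all(np.isfinite(traj)):
                return 1e12
            resid = (traj - b["conc_obs"]) / s
            total += np.sum(resid[:, mask] ** 2)
        return total

    x0 = np.log([getattr(p0, n) for n in names])
    rng = np.random.default_rng(cfg.seed)
    starts = [x0] + [x0 + np.log(1 + cfg.perturbation * rng.uniform(-1, 1, len(x0)))
                     for _ in range(cfg.n_starts - 1)]
    if cfg.maxiter == 0:
        return IdentificationResult(p0, objective(x0), 1)
    best_x, best_f, n_evals = _nelder_mead(objective, starts, cfg)
    fitted = p0.with_values(**dict(zip(
        names, np.exp(np.clip(best_x, -40.0, 40.0)))))

    per_sse, per_r2 = {}, {}
    for j, m in enumerate(FLEX_STATE_NAMES):
        sse = sst = 0.0
        for prep, b in zip(prepared, batches):
            traj = simulate_flex_fast(fitted, prep)
            obs = b["conc_obs"][:, j]
            sse += float(np.sum((traj[:, j] - obs) ** 2))
            sst += float(np.sum((obs - obs.mean()) ** 2))
        per_sse[m] = sse
        per_r2[m] = 1.0 - sse / sst if sst > 0 else np.nan
    return IdentificationResult(fitted, best_f, n_evals, per_sse, per_r2)


def bolus_jump(feed_volume_ml: float, reactor_volume_ml: float, feed_conc: np.ndarray):
    """Jump map for an instantaneous bolus: perfect mixing of two volumes."""
    d = reactor_volume_ml / (reactor_volume_ml + feed_volume_ml)

    def apply(y):
        return y * d + np.asarray(feed_conc) * (1.0 - d)

    return apply
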