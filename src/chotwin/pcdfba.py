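"""PC-dFBA: dynamic flux balance analysis under PCA-derived empirical constraints.

The hybrid linear program couples mechanistic constraints (stoichiometric
mass balance ``S v = 0``, reaction bounds, hard bounds pinning the measured
growth + FLEX exchanges) with empirical constraints that tie the measured
exchange fluxes to a low-dimensional PCA representation learned from
historical batches:

    min_{v, s}  c_v' v + 1' |s|
    s.t.        S v = 0
                lb <= v <= ub          (hard-bounded subset pinned)
                med - RF*iqr <= Se v - Load s <= med + RF*iqr
                LB_s <= s <= UB_s

where ``Load`` holds per-PC loading vectors predicted at run time by small
neural regressors from the current exchange-rate vector, ``med``/``iqr`` are
robust location/spread statistics of the training exchange rates over a
culture-phase interval (day 0-3 vs day 3-end), and ``RF`` is a relaxation
factor.  Scores ``s`` are free per-step variables; their L1 norm is
penalized so the empirical correction is used sparingly.

A sequential simulation advances extracellular concentrations with the
optimized fluxes at 0.1-day steps; temporal continuity between consecutive
flux distributions is enforced lexicographically with a MOMA-style penalty
(stage two minimizes ``sum (v_t - v_{t-1})^2`` at the fixed stage-one
optimum).  Infeasible hard bounds are relaxed to the 5th-95th percentile
band of the rate posterior.  A PC-dFVA diagnostic reports per-exchange flux
ranges at the fixed optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .network import MetabolicNetwork
from .records import FLEX_ANALYTES, GROWTH_RATE_NAME, RATE_PANEL

logger = logging.getLogger(__name__)

#: Default culture-phase split (days): higher rate uncertainty before day 3.
DELTA_C_BOUNDARY = 3.0
MAX_PCS = 5


class StepInfeasibleError(RuntimeError):
    """Stage-one LP infeasible (caller may relax hard bounds)."""


# --------------------------------------------------------------------------
# window PCA
# --------------------------------------------------------------------------

@dataclass
class WindowLoadings:
    group: int
    window_start: float
    loadings: np.ndarray          # (n_metabolites, n_pcs), orthonormal columns
    explained: np.ndarray         # explained-variance fractions
    n_samples: int
    zero_variance: bool = False


@dataclass
class LoadingTargetSet:
    analytes: tuple[str, ...]
    window: float
    var_threshold: float
    windows: list[WindowLoadings] = field(default_factory=list)

    def max_pcs(self) -> int:
        return max((w.loadings.shape[1] for w in self.windows), default=0)


def window_pca(rate_tables: dict[str, tuple[int, pd.DataFrame]],
               window: float = 0.5, var_threshold: float = 0.90,
               analytes: tuple[str, ...] = RATE_PANEL) -> LoadingTargetSet:
    """Windowed, media-group-matched PCA of exchange-rate trajectories.

    ``rate_tables`` maps batch id to ``(media_group, table)`` where the table
    holds mean exchange rates indexed by time (days), one column per analyte.
    For every (group, 0.5-day window) with at least two samples, a PCA is
    computed on the centered rate matrix and the smallest number of PCs
    reaching ``var_threshold`` cumulative explained variance (capped at 5)
    is retained.
    """
    out = LoadingTargetSet(tuple(analytes), window, var_threshold)
    groups = sorted({g for g, _ in rate_tables.values()})
    t_max = max(t.index.max() for _, t in rate_tables.values())
    edges = np.arange(0.0, t_max + window, window)
    for g in groups:
        tables = [t for gg, t in rate_tables.values() if gg == g]
        for w0 in edges:
            rows = []
            for t in tables:
                m = (t.index.values >= w0) & (t.index.values < w0 + window)
                if m.any():
                    rows.append(t.loc[m, list(analytes)].to_numpy(dtype=float))
            if not rows:
                continue
            X = np.vstack(rows)
            if len(X) < 2:
                continue
            Xc = X - X.mean(axis=0)
            total = float(np.sum(Xc ** 2))
            if total < 1e-30:
                load = np.zeros((len(analytes), 1))
                load[0, 0] = 1.0
                logger.warning("zero-variance window g=%s t=%s", g, w0)
                out.windows.append(WindowLoadings(g, float(w0), load,
                                                  np.array([1.0]), len(X), True))
                continue
            _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
            var = sv ** 2 / np.sum(sv ** 2)
            cum = np.cumsum(var)
            n_pc = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
            n_pc = min(max(n_pc, 1), MAX_PCS, len(var))
            out.windows.append(WindowLoadings(
                g, float(w0), vt[:n_pc].T.copy(), var[:n_pc].copy(), len(X)))
    return out


# --------------------------------------------------------------------------
# loading regressors
# --------------------------------------------------------------------------

FEATURE_SETS = {
    "ALL": RATE_PANEL,
    "FLEX": (GROWTH_RATE_NAME,) + FLEX_ANALYTES,
}


@dataclass
class LoadingModel:
    """One regressor per PC index mapping exchange rates to loading vectors."""

    feature_set: str
    feature_analytes: tuple[str, ...]
    target_analytes: tuple[str, ...]
    n_pcs: int
    regressors: list[MLPRegressor]
    x_scaler: StandardScaler
    y_scalers: list[StandardScaler]

    def predict_loadings(self, rate_vector: np.ndarray) -> np.ndarray:
        """Loading matrix (n_target_analytes, n_pcs) for one feature vector."""
        x = self.x_scaler.transform(np.atleast_2d(rate_vector))
        cols = []
        for reg, ys in zip(self.regressors, self.y_scalers):
            y = reg.predict(x)
            cols.append(ys.inverse_transform(np.atleast_2d(y))[0])
        return np.column_stack(cols)


def _training_pairs(targets: LoadingTargetSet,
                    rate_tables: dict[str, tuple[int, pd.DataFrame]],
                    feature_analytes: tuple[str, ...]):
    """Feature rows (per batch/time sample) paired with window loading targets.

    Missing PCs beyond a window's count are zero-filled so the output
    dimensionality is fixed across windows.
    """
    n_pc = max(targets.max_pcs(), 1)
    n_met = len(targets.analytes)
    by_key = {(w.group, w.window_start): w for w in targets.windows}
    X, Y = [], []
    for _, (g, table) in rate_tables.items():
        for t, row in table.iterrows():
            w0 = np.floor(t / targets.window) * targets.window
            w = by_key.get((g, float(w0)))
            if w is None:
                continue
            load = np.zeros((n_met, n_pc))
            load[:, :w.loadings.shape[1]] = w.loadings
            X.append(row[list(feature_analytes)].to_numpy(dtype=float))
            Y.append(load)
    return np.asarray(X), np.asarray(Y)


@dataclass
class LoadingHPConfig:
    hidden_options: tuple = ((32,), (64, 32))
    alpha_options: tuple = (1e-4,)
    max_iter: int = 2000
    seed: int = 0
    budget: int = 2          # configurations tried per PC


def train_loading_model(rate_tables, targets: LoadingTargetSet,
                        feature_set: str = "ALL",
                        hp_config: LoadingHPConfig | None = None) -> LoadingModel:
    """Fit per-PC neural regressors from exchange rates to PCA loadings.

    Inputs and outputs are standardized with scalers fitted on the training
    data only; a small hyperparameter search (hidden sizes, L2) selects the
    configuration with the lowest validation RMSE per PC.
    """
    hp = hp_config or LoadingHPConfig()
    feats = FEATURE_SETS[feature_set] if feature_set in FEATURE_SETS \
        else tuple(feature_set)
    X, Y = _training_pairs(targets, rate_tables, feats)
    if len(X) == 0:
        raise ValueError("no training samples; check rate tables and windows")
    xs = StandardScaler().fit(X)
    Xs = xs.transform(X)
    rng = np.random.default_rng(hp.seed)
    n_val = max(1, len(Xs) // 5)
    perm = rng.permutation(len(Xs))
    vi, ti = perm[:n_val], perm[n_val:]
    if len(ti) == 0:
        ti = vi
    regs, yss = [], []
    n_pc = Y.shape[2]
    for p in range(n_pc):
        yp = Y[:, :, p]
        ys = StandardScaler().fit(yp)
        yt = ys.transform(yp)
        best, best_rmse = None, np.inf
        combos = [(h, a) for h in hp.hidden_options for a in hp.alpha_options]
        for h, a in combos[:hp.budget]:
            reg = MLPRegressor(hidden_layer_sizes=h, alpha=a,
                               max_iter=hp.max_iter, random_state=hp.seed,
                               early_stopping=False)
            reg.fit(Xs[ti], yt[ti])
            rmse = float(np.sqrt(np.mean((reg.predict(Xs[vi]) - yt[vi]) ** 2)))
            if rmse < best_rmse:
                best, best_rmse = reg, rmse
        logger.info("PC%d loading regressor val RMSE %.4f", p + 1, best_rmse)
        regs.append(best)
        yss.append(ys)
    return LoadingModel(feature_set, feats, targets.analytes, n_pc,
                        regs, xs, yss)


def cross_validate(strategy: str, rate_tables, window: float = 0.5,
                   var_threshold: float = 0.90, feature_set: str = "ALL",
                   hp_config: LoadingHPConfig | None = None,
                   seed: int = 0, analytes=None) -> pd.DataFrame:
    """Loading-prediction generalization under direct / LOMO / LOBO schemes.

    Returns a tidy frame with per-fold, per-metabolite R^2 and SSE of the
    predicted loading coordinates on held-out batches.  The analyte panel
    defaults to the columns shared by all rate tables.
    """
    ids = list(rate_tables)
    if analytes is None:
        cols = None
        for _, t in rate_tables.values():
            cols = set(t.columns) if cols is None else cols & set(t.columns)
        analytes = tuple(a for a in RATE_PANEL if a in cols) or tuple(sorted(cols))
    groups = {b: g for b, (g, _) in rate_tables.items()}
    rng = np.random.default_rng(seed)
    if strategy == "direct":
        perm = rng.permutation(ids)
        n = len(ids)
        n_test = max(1, int(round(0.15 * n)))
        n_valid = max(1, int(round(0.15 * n)))
        folds = [(perm[n_test + n_valid:].tolist(), perm[:n_test].tolist())]
    elif strategy == "LOMO":
        gs = sorted(set(groups.values()))
        if len(gs) < 2:
            raise ValueError("LOMO needs at least two media groups")
        folds = [([b for b in ids if groups[b] != g],
                  [b for b in ids if groups[b] == g]) for g in gs]
    elif strategy == "LOBO":
        folds = [([b for b in ids if b != held], [held]) for held in ids]
    else:
        raise ValueError(f"unknown validation strategy {strategy!r}")

    rows = []
    for k, (train_ids, test_ids) in enumerate(folds):
        train_tables = {b: rate_tables[b] for b in train_ids}
        test_tables = {b: rate_tables[b] for b in test_ids}
        targets = window_pca(train_tables, window, var_threshold, analytes)
        model = train_loading_model(train_tables, targets, feature_set,
                                    hp_config)
        full_targets = window_pca(rate_tables, window, var_threshold, analytes)
        Xt, Yt = _training_pairs(
            replace(full_targets,
                    windows=[w for w in full_targets.windows]),
            test_tables, model.feature_analytes)
        if len(Xt) == 0:
            continue
        n_pc_eval = min(model.n_pcs, Yt.shape[2])
        pred = np.stack([model.predict_loadings(x) for x in Xt])
        for j, analyte in enumerate(full_targets.analytes):
            y_true = Yt[:, j, :n_pc_eval].ravel()
            y_pred = pred[:, j, :n_pc_eval].ravel()
            sse = float(np.sum((y_pred - y_true) ** 2))
            sst = float(np.sum((y_true - y_true.mean()) ** 2))
            rows.append({"fold": k, "analyte": analyte, "sse": sse,
                         "r2": 1 - sse / sst if sst > 0 else np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# hybrid LP
# --------------------------------------------------------------------------

@dataclass
class BandStats:
    """Robust per-exchange statistics of measured rates per culture phase."""

    analytes: tuple[str, ...]
    med: dict[str, np.ndarray]    # interval label -> vector over analytes
    iqr: dict[str, np.ndarray]
    boundary: float = DELTA_C_BOUNDARY

    def at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        key = "early" if t < self.boundary else "late"
        return self.med[key], self.iqr[key]


def compute_band_stats(rate_tables, analytes: tuple[str, ...] = RATE_PANEL,
                       boundary: float = DELTA_C_BOUNDARY,
                       iqr_floor_rel: float = 0.05,
                       iqr_floor_abs: float = 1e-6) -> BandStats:
    """Median / IQR of the pooled training rates per phase interval.

    The boundary time itself belongs to the second (late) interval.  The IQR
    is floored at a small fraction of the median magnitude: a rate that is
    near-identical across training batches would otherwise produce a
    zero-width (equality) band that no pinned measurement can satisfy.
    """
    frames = [t for _, t in rate_tables.values()]
    allr = pd.concat(frames)
    med, iqr = {}, {}
    for key, mask in (("early", allr.index.values < boundary),
                      ("late", allr.index.values >= boundary)):
        sub = allr.loc[mask, list(analytes)]
        if len(sub) == 0:
            sub = allr[list(analytes)]
        med[key] = sub.median().to_numpy(dtype=float)
        q75, q25 = sub.quantile(0.75), sub.quantile(0.25)
        width = (q75 - q25).to_numpy(dtype=float)
        iqr[key] = np.maximum(width,
                              iqr_floor_rel * np.abs(med[key]) + iqr_floor_abs)
    return BandStats(tuple(analytes), med, iqr, boundary)


@dataclass
class HybridLPProblem:
    network: MetabolicNetwork
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c_v: np.ndarray                       # objective on fluxes (min direction)
    measured_rows: list[int]              # reaction indices of measured exchanges
    measured_analytes: tuple[str, ...]
    loadings: np.ndarray                  # (n_measured, n_pc)
    band_lo: np.ndarray
    band_hi: np.ndarray
    score_lb: np.ndarray
    score_ub: np.ndarray
    hard_bound_idx: dict[str, int]        # analyte/biomass name -> reaction index
    prev_flux: np.ndarray | None = None
    score_weight: float = 1.0

    @property
    def n_rxn(self) -> int:
        return self.S.shape[1]

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


@dataclass
class StepSolution:
    fluxes: np.ndarray
    scores: np.ndarray
    objective: float
    status: str
    relaxed: bool = False
    continuity_penalty: float | None = None
    band_violation: float = 0.0   # total elastic band slack (0 when strict)


def build_step_problem(network: MetabolicNetwork, loadings: np.ndarray,
                       measured_analytes, hard_bounds: dict[str, float] | None,
                       band_stats_at: tuple[np.ndarray, np.ndarray],
                       rf: float = 1.5, score_bounds=None,
                       prev_flux: np.ndarray | None = None,
                       maximize_biomass: bool = True) -> HybridLPProblem:
    """Assemble the hybrid LP for one time step.

    ``measured_analytes`` are the names behind the rows of ``loadings`` and
    the band statistics; each maps to an exchange reaction (or the biomass
    reaction for the growth entry).  ``hard_bounds`` pins a subset of those
    reactions to given flux values (equality by bounds).
    """
    model = network.model
    S = network.S
    lb, ub = network.bounds
    lb, ub = lb.astype(float).copy(), ub.astype(float).copy()
    rxn_index = {r.id: i for i, r in enumerate(model.reactions)}
    biomass = network.biomass_id

    def reaction_for(analyte: str) -> int:
        if analyte == GROWTH_RATE_NAME:
            return rxn_index[biomass]
        return rxn_index[network.exchange_for_analyte(analyte)]

    rows = [reaction_for(a) for a in measured_analytes]
    med, iqr = band_stats_at
    med = np.asarray(med, dtype=float)
    iqr = np.asarray(iqr, dtype=float)
    if loadings.shape[0] != len(rows):
        raise ValueError("loading matrix rows must match measured analytes")
    if len(med) != len(rows):
        raise ValueError("band statistics must match measured analytes")

    hb_idx = {}
    if hard_bounds:
        for analyte, value in hard_bounds.items():
            i = reaction_for(analyte)
            lb[i] = ub[i] = float(value)
            hb_idx[analyte] = i

    n_pc = loadings.shape[1]
    if score_bounds is None:
        score_lb = np.full(n_pc, -np.inf)
        score_ub = np.full(n_pc, np.inf)
    else:
        score_lb = np.asarray(score_bounds[0], dtype=float)
        score_ub = np.asarray(score_bounds[1], dtype=float)

    c_v = -network.objective_vector if maximize_biomass \
        else network.objective_vector
    return HybridLPProblem(
        network=network, S=S, lb=lb, ub=ub, c_v=c_v,
        measured_rows=rows, measured_analytes=tuple(measured_analytes),
        loadings=np.asarray(loadings, dtype=float),
        band_lo=med - rf * iqr, band_hi=med + rf * iqr,
        score_lb=score_lb, score_ub=score_ub,
        hard_bound_idx=hb_idx, prev_flux=prev_flux)


def _assemble_lp(problem: HybridLPProblem, elastic_penalty: float | None = None):
    """Matrices for ``x = [v, s, a(, e)]`` with ``a >= |s|``.

    With ``elastic_penalty`` set, a nonnegative slack ``e`` per band side is
    added with that objective weight (an exact-penalty relaxation: when the
    strict problem is feasible and the penalty large, slacks stay zero)."""
    n, p = problem.n_rxn, problem.n_pc
    n_meas = len(problem.measured_rows)
    Se = np.zeros((n_meas, n))
    for r, i in enumerate(problem.measured_rows):
        Se[r, i] = 1.0
    finite = np.isfinite(problem.band_lo) & np.isfinite(problem.band_hi)
    n_band = int(finite.sum())
    n_e = 2 * n_band if elastic_penalty is not None else 0
    nx = n + 2 * p + n_e
    A_eq = np.zeros((problem.S.shape[0], nx))
    A_eq[:, :n] = problem.S
    b_eq = np.zeros(problem.S.shape[0])
    rows_ub, rhs_ub = [], []
    # band: lo <= Se v - Load s <= hi (optionally elastic)
    band = np.zeros((n_meas, nx))
    band[:, :n] = Se
    band[:, n:n + p] = -problem.loadings
    hi_rows = band[finite].copy()
    lo_rows = -band[finite]
    if n_e:
        hi_rows[:, n + 2 * p:n + 2 * p + n_band] = -np.eye(n_band)
        lo_rows = lo_rows.copy()
        lo_rows[:, n + 2 * p + n_band:] = -np.eye(n_band)
    rows_ub.append(hi_rows)
    rhs_ub.append(problem.band_hi[finite])
    rows_ub.append(lo_rows)
    rhs_ub.append(-problem.band_lo[finite])
    # |s| <= a
    for j in range(p):
        row = np.zeros(nx)
        row[n + j] = 1.0
        row[n + p + j] = -1.0
        rows_ub.append(row[None, :])
        rhs_ub.append([0.0])
        row2 = np.zeros(nx)
        row2[n + j] = -1.0
        row2[n + p + j] = -1.0
        rows_ub.append(row2[None, :])
        rhs_ub.append([0.0])
    A_ub = np.vstack(rows_ub)
    b_ub = np.concatenate([np.atleast_1d(r) for r in rhs_ub])
    bounds = [(problem.lb[i], problem.ub[i]) for i in range(n)]
    bounds += [(problem.score_lb[j], problem.score_ub[j]) for j in range(p)]
    bounds += [(0.0, None)] * (p + n_e)
    c = np.concatenate([problem.c_v, np.zeros(p),
                        problem.score_weight * np.ones(p),
                        np.full(n_e, elastic_penalty or 0.0)])
    return c, A_eq, b_eq, A_ub, b_ub, bounds


def solve_step(problem: HybridLPProblem, continuity_mode: str = "qp",
               objective_tol: float = 1e-6,
               elastic_penalty: float | None = None) -> StepSolution:
    """Two-stage solve: hybrid LP, then MOMA continuity at the fixed optimum.

    Stage one minimizes ``c_v'v + 1'|s|``; when a previous flux vector is
    present, stage two fixes the stage-one objective (within a relative
    tolerance) and minimizes the squared (``qp``) or absolute (``l1``) flux
    change from the previous step, making the choice among alternate optima
    deterministic and temporally smooth.
    """
    c, A_eq, b_eq, A_ub, b_ub, bounds = _assemble_lp(problem, elastic_penalty)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise StepInfeasibleError("stage-1 hybrid LP infeasible")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    n, p = problem.n_rxn, problem.n_pc
    x = res.x

    def violation(xx):
        return float(np.sum(xx[n + 2 * p:])) if elastic_penalty else 0.0

    if problem.prev_flux is None:
        return StepSolution(x[:n], x[n:n + p], float(res.fun), "optimal",
                            continuity_penalty=None,
                            band_violation=violation(x))

    z_star = float(res.fun)
    tol = objective_tol * max(abs(z_star), 1.0)
    prev = np.asarray(problem.prev_flux, dtype=float)

    if continuity_mode == "l1":
        # extra variables t >= |v - prev|
        nx = len(c)
        c2 = np.concatenate([np.zeros(nx), np.ones(n)])
        A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
        blocks = [np.hstack([A_ub, np.zeros((A_ub.shape[0], n))])]
        rhs = [b_ub]
        blocks.append(np.hstack([c[None, :], np.zeros((1, n))]))
        rhs.append([z_star + tol])
        I = np.zeros((n, nx))
        I[:, :n] = np.eye(n)
        T = np.eye(n)
        blocks.append(np.hstack([I, -T]))
        rhs.append(prev)
        blocks.append(np.hstack([-I, -T]))
        rhs.append(-prev)
        res2 = linprog(c2, A_ub=np.vstack(blocks),
                       b_ub=np.concatenate([np.atleast_1d(r) for r in rhs]),
                       A_eq=A_eq2, b_eq=b_eq,
                       bounds=bounds + [(0.0, None)] * n, method="highs")
        if not res2.success:
            logger.warning("continuity LP failed (%s); stage-1 kept",
                           res2.message)
            return StepSolution(x[:n], x[n:n + p], z_star, "optimal",
                                continuity_penalty=None,
                                band_violation=violation(x))
        x2 = res2.x[:len(c)]
        pen = float(np.sum((x2[:n] - prev) ** 2))
        return StepSolution(x2[:n], x2[n:n + p], z_star, "optimal",
                            continuity_penalty=pen,
                            band_violation=violation(x2))

    if continuity_mode != "qp":
        raise ValueError(f"unknown continuity mode {continuity_mode!r}")

    def fun(xx):
        d = xx[:n] - prev
        return float(d @ d)

    def jac(xx):
        g = np.zeros_like(xx)
        g[:n] = 2.0 * (xx[:n] - prev)
        return g

    cons = [
        {"type": "eq", "fun": lambda xx: A_eq @ xx - b_eq,
         "jac": lambda xx: A_eq},
        {"type": "ineq", "fun": lambda xx: b_ub - A_ub @ xx,
         "jac": lambda xx: -A_ub},
        {"type": "ineq", "fun": lambda xx: (z_star + tol) - c @ xx,
         "jac": lambda xx: -c},
    ]
    slsqp_bounds = [
        (None if l is None or not np.isfinite(l) else l,
         None if u is None or not np.isfinite(u) else u) for l, u in bounds]
    res2 = minimize(fun, x, jac=jac, method="SLSQP", bounds=slsqp_bounds,
                    constraints=cons,
                    options={"maxiter": 300, "ftol": 1e-12})
    if not res2.success or np.max(np.abs(A_eq @ res2.x - b_eq)) > 1e-6:
        logger.warning("continuity QP failed (%s); stage-1 kept", res2.message)
        return StepSolution(x[:n], x[n:n + p], z_star, "optimal",
                            continuity_penalty=None,
                            band_violation=violation(x))
    x2 = res2.x
    return StepSolution(x2[:n], x2[n:n + p], z_star, "optimal",
                        continuity_penalty=float(res2.fun),
                        band_violation=violation(x2))


def relax_hard_bounds(problem: HybridLPProblem,
                      rate_percentiles: dict[str, tuple[float, float]]
                      ) -> HybridLPProblem:
    """Widen hard bounds from pinned means to the [p5, p95] posterior band."""
    lb, ub = problem.lb.copy(), problem.ub.copy()
    for analyte, i in problem.hard_bound_idx.items():
        if analyte in rate_percentiles:
            p5, p95 = rate_percentiles[analyte]
            lb[i], ub[i] = float(p5), float(p95)
    return replace(problem, lb=lb, ub=ub)


def solve_with_fallback(problem: HybridLPProblem, continuity_mode: str,
                        rate_percentiles_at=None,
                        elastic_penalty: float = 1e3) -> StepSolution:
    """Strict solve, then hard-bound relaxation, then elastic band (reported).

    The escalation order preserves the constraint semantics whenever
    possible: the elastic exact-penalty stage only engages when even the
    percentile-relaxed problem is infeasible, and its band violation is
    recorded on the returned solution.
    """
    try:
        return solve_step(problem, continuity_mode)
    except StepInfeasibleError:
        pass
    relaxed = False
    if rate_percentiles_at:
        problem = relax_hard_bounds(problem, rate_percentiles_at)
        relaxed = True
        try:
            sol = solve_step(problem, continuity_mode)
            sol.relaxed = True
            return sol
        except StepInfeasibleError:
            pass
    try:
        sol = solve_step(problem, continuity_mode,
                         elastic_penalty=elastic_penalty)
    except StepInfeasibleError as err:
        raise StepInfeasibleError("irreducibly infeasible step") from err
    sol.relaxed = relaxed
    return sol


def pc_dfva(problem: HybridLPProblem, solution: StepSolution,
            objective_tol: float = 1e-6) -> pd.DataFrame:
    """Per-exchange flux ranges at the fixed hybrid optimum.

    The stage-one objective is constrained to its optimum (within tolerance)
    and every measured exchange flux is minimized and maximized in turn.
    """
    c, A_eq, b_eq, A_ub, b_ub, bounds = _assemble_lp(problem)
    A_ub2 = np.vstack([A_ub, c[None, :]])
    b_ub2 = np.concatenate([b_ub,
                            [solution.objective
                             + objective_tol * max(abs(solution.objective), 1.0)]])
    rows = []
    for analyte, i in zip(problem.measured_analytes, problem.measured_rows):
        rng_ = {}
        for sense, mult in (("min", 1.0), ("max", -1.0)):
            cc = np.zeros(len(c))
            cc[i] = mult
            r = linprog(cc, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq, b_eq=b_eq,
                        bounds=bounds, method="highs")
            rng_[sense] = float(mult * r.fun) if r.success else np.nan
        rows.append({"analyte": analyte, "minimum": rng_["min"],
                     "maximum": rng_["max"]})
    return pd.DataFrame(rows).set_index("analyte")


# --------------------------------------------------------------------------
# sequential dynamic simulation
# --------------------------------------------------------------------------

@dataclass
class PCdFBAResult:
    times: np.ndarray
    concentrations: pd.DataFrame      # time x analytes
    fluxes: pd.DataFrame              # time x measured analytes (exchange fluxes)
    scores: np.ndarray                # (n_steps, n_pc)
    vcd: np.ndarray
    relaxed_steps: list[int] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)


def simulate(network: MetabolicNetwork, loading_model: LoadingModel,
             band_stats: BandStats, hard_bound_source,
             initial_concentrations: dict[str, float], xv0: float,
             feed_schedule=None, horizon: float = 14.0, dt: float = 0.1,
             rf: float = 1.5, score_bounds=None, continuity_mode: str = "qp",
             flux_per_rate: float = 1.0, volume0: float = 1.0,
             rate_percentiles=None) -> PCdFBAResult:
    """Sequential PC-dFBA simulation over ``[0, horizon]`` at ``dt`` steps.

    Per step: the current exchange-rate estimate (hard-bounded rates from
    ``hard_bound_source`` plus the previous step's predicted free exchanges)
    is normalized and passed to the loading regressors; the hybrid LP is
    built and solved (with MOMA continuity after the first step, and hard-
    bound relaxation on infeasibility); concentrations advance by the
    bioreactor mass balance.

    ``hard_bound_source(t)`` returns a dict analyte -> specific rate
    (growth entry = effective growth rate, 1/d); ``feed_schedule(t0, t1)``
    returns a list of ``(volume_ml, {analyte: conc})`` boluses in the
    interval.  ``flux_per_rate`` converts specific rates (g/1e9 cells/d) to
    model flux units.
    """
    analytes = [a for a in band_stats.analytes if a != GROWTH_RATE_NAME]
    times = np.arange(0.0, horizon + dt / 2, dt)
    conc = {a: float(initial_concentrations.get(a, 0.0)) for a in analytes}
    xv = float(xv0)
    volume = float(volume0)
    prev_flux = None
    prev_rates: dict[str, float] = {}
    conc_rows, flux_rows, score_rows, relaxed, diags = [], [], [], [], []
    xv_rows: list[float] = []

    for k, t in enumerate(times):
        hb = dict(hard_bound_source(t))
        rate_vec = []
        for a in loading_model.feature_analytes:
            if a in hb:
                rate_vec.append(hb[a])
            else:
                rate_vec.append(prev_rates.get(a, 0.0))
        loadings = loading_model.predict_loadings(np.asarray(rate_vec))
        hard = {a: v * (1.0 if a == GROWTH_RATE_NAME else flux_per_rate)
                for a, v in hb.items()}
        problem = build_step_problem(
            network, loadings, band_stats.analytes, hard,
            band_stats.at(t), rf, score_bounds, prev_flux)
        try:
            sol = solve_with_fallback(
                problem, continuity_mode,
                rate_percentiles(t) if rate_percentiles else None)
        except StepInfeasibleError as err:
            raise RuntimeError(
                f"irreducibly infeasible at t={t:.2f} d") from err
        if sol.relaxed:
            relaxed.append(k)

        flux = {a: sol.fluxes[i] for a, i in
                zip(problem.measured_analytes, problem.measured_rows)}
        conc_rows.append(dict(conc))
        flux_rows.append(flux)
        score_rows.append(sol.scores)
        xv_rows.append(xv)
        diags.append({"t": float(t), "objective": sol.objective,
                      "relaxed": sol.relaxed,
                      "band_violation": sol.band_violation,
                      "continuity_penalty": sol.continuity_penalty})

        if k == len(times) - 1:
            break
        # dynamic update: specific rates from fluxes, mass balance, growth
        # dynamic update over [t, t+dt]: hard-bounded rates are known in
        # continuous time, so they are sampled at the interval midpoint and
        # combined with the midpoint viable-cell density (second order in
        # dt); free exchanges keep their piecewise-constant LP flux
        hb_mid = dict(hard_bound_source(t + dt / 2.0))
        mu = hb_mid.get(GROWTH_RATE_NAME,
                        hb.get(GROWTH_RATE_NAME,
                               flux.get(GROWTH_RATE_NAME, 0.0)))
        feeds = feed_schedule(t, t + dt) if feed_schedule else []
        xv_mid = xv * np.exp(0.5 * mu * dt)
        for a in analytes:
            rate = hb_mid[a] if a in hb_mid else flux[a] / flux_per_rate
            conc[a] = max(conc[a] + rate * xv_mid * dt, 0.0)
        xv = xv * float(np.exp(mu * dt))   # exact for piecewise-constant mu
        for vol, comp in feeds:
            if comp is None:            # sample withdrawal: volume only
                volume = max(volume - vol, 1e-6)
                continue
            d = volume / (volume + vol)
            for a in analytes:
                conc[a] = conc[a] * d + comp.get(a, 0.0) * (1 - d)
            xv *= d
            volume += vol
        prev_flux = sol.fluxes
        prev_rates = {a: flux[a] / flux_per_rate for a in analytes}
        prev_rates[GROWTH_RATE_NAME] = mu

    return PCdFBAResult(
        times=times,
        concentrations=pd.DataFrame(conc_rows, index=times[:len(conc_rows)]),
        fluxes=pd.DataFrame(flux_rows, index=times[:len(flux_rows)]),
        scores=np.asarray(score_rows),
        vcd=np.asarray(xv_rows),
        relaxed_steps=relaxed, diagnostics=diags)
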