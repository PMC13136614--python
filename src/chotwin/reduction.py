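"""Stepwise reduction of a metabolic network to a minimal feasible model.

Given a constraint-based model and measured exchange-rate constraints (95%
credible intervals from the rate-estimation layer, converted to flux units),
the pipeline derives a condition-specific reduced model in four stages,
verifying feasibility after every change:

(a) **resolve infeasibilities** — add demand reactions (greedy, smallest
    bound magnitude first) until the constrained model is feasible;
(b) **essential exchanges** — keep an unmeasured exchange only if closing it
    makes the constrained model infeasible;
(c) **pFBA pruning** — remove reactions that carry (numerically) zero
    parsimonious flux under *all* conditions;
(d) **loop removal** — break internal cycles that can carry flux with all
    boundary reactions closed (thermodynamically infeasible loops).

Dead-end metabolites and blocked reactions are pruned to a fixpoint after
each stage.  Reactions can be *pinned*: they are reinstated from the source
model with prescribed bounds regardless of pruning outcomes (the mechanism
used to keep biologically mandatory reactions such as asparagine synthase in
the final model).  All standard analyses (FBA, pFBA, FVA) are delegated to
COBRApy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cobra import Model, Reaction
from cobra.flux_analysis import flux_variability_analysis, pfba

logger = logging.getLogger(__name__)

FEAS_TOL = 1e-9
OPT_REL_TOL = 1e-6


@dataclass
class ReductionConfig:
    """Knobs of the reduction pipeline.

    ``demand_candidates`` maps metabolite id -> (lb, ub) demand-reaction
    bounds (mM/gDCW·h).  ``pins`` maps reaction id -> (lb, ub)."""

    measured_exchanges: tuple[str, ...] = ()
    demand_candidates: dict[str, tuple[float, float]] = field(default_factory=dict)
    pfba_threshold: float = 1e-9
    pins: dict[str, tuple[float, float]] = field(default_factory=dict)
    allow_directionality_restriction: bool = True


@dataclass
class StageRecord:
    name: str
    removed_reactions: list[str] = field(default_factory=list)
    removed_metabolites: list[str] = field(default_factory=list)
    added_reactions: list[str] = field(default_factory=list)
    feasible_after: bool = True
    objective_before: float = np.nan
    objective_after: float = np.nan
    notes: list[str] = field(default_factory=list)


@dataclass
class ReductionReport:
    stages: list[StageRecord] = field(default_factory=list)
    pinned: list[str] = field(default_factory=list)

    @property
    def removed_reactions(self) -> list[str]:
        return [r for s in self.stages for r in s.removed_reactions]

    def to_dict(self) -> dict:
        return {
            "stages": [{
                "name": s.name,
                "removed_reactions": s.removed_reactions,
                "removed_metabolites": s.removed_metabolites,
                "added_reactions": s.added_reactions,
                "feasible_after": bool(s.feasible_after),
                "objective_before": float(s.objective_before),
                "objective_after": float(s.objective_after),
                "notes": s.notes,
            } for s in self.stages],
            "pinned": self.pinned,
        }


class ReductionError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _apply_constraints(model: Model, constraints: dict[str, tuple[float, float]]):
    for rid, (lb, ub) in constraints.items():
        rxn = model.reactions.get_by_id(rid)
        rxn.bounds = (lb, ub)


def optimum(model: Model, constraints=None) -> float:
    """Objective optimum under optional temporary constraints (NaN if infeasible)."""
    with model:
        if constraints:
            _apply_constraints(model, constraints)
        return model.slim_optimize(error_value=np.nan)


def is_feasible(model: Model, constraints=None) -> bool:
    return bool(np.isfinite(optimum(model, constraints)))


def _protected(model: Model, config: ReductionConfig) -> set[str]:
    prot = {r.id for r in model.reactions if r.objective_coefficient != 0}
    prot |= set(config.pins)
    prot |= set(config.measured_exchanges)
    return prot


# --------------------------------------------------------------------------
# stage operations
# --------------------------------------------------------------------------

def resolve_infeasibilities(model: Model, flux_constraints,
                            demand_candidates=None) -> tuple[Model, list[str]]:
    """Add demand reactions until the constrained model is feasible.

    Candidates are tried greedily in order of increasing bound magnitude; a
    demand is kept only if it was needed at the moment it was added.  Raises
    :class:`ReductionError` if all candidates together cannot restore
    feasibility.
    """
    model = model.copy()
    added: list[str] = []
    if is_feasible(model, flux_constraints):
        return model, added
    cands = sorted((demand_candidates or {}).items(),
                   key=lambda kv: max(abs(kv[1][0]), abs(kv[1][1])))
    for met_id, bounds in cands:
        rxn = Reaction(f"DM_{met_id}", lower_bound=bounds[0],
                       upper_bound=bounds[1])
        model.add_reactions([rxn])
        rxn.add_metabolites({model.metabolites.get_by_id(met_id): -1.0})
        added.append(rxn.id)
        if is_feasible(model, flux_constraints):
            return model, added
    raise ReductionError(
        "model remains infeasible with all candidate demands added; "
        f"constrained exchanges: {sorted(flux_constraints)}")


def essential_exchanges(model: Model, measured_exchange_set,
                        constraints=None) -> set[str]:
    """Exchanges to retain: all measured ones plus unmeasured ones whose
    closure makes the constrained model infeasible."""
    if not is_feasible(model, constraints):
        raise ReductionError("model must be feasible before exchange analysis")
    measured = set(measured_exchange_set)
    retain = {r.id for r in model.exchanges if r.id in measured}
    for rxn in model.exchanges:
        if rxn.id in measured:
            continue
        with model:
            if constraints:
                _apply_constraints(model, constraints)
            rxn.bounds = (0.0, 0.0)
            if not np.isfinite(model.slim_optimize(error_value=np.nan)):
                retain.add(rxn.id)
    return retain


def pfba_prune(model: Model, condition_constraints_list, threshold: float = 1e-9,
               protected=(), record: StageRecord | None = None) -> Model:
    """Remove reactions with |pFBA flux| < threshold under ALL conditions.

    Each candidate removal is verified: the model must stay feasible and the
    biomass optimum must be preserved within ``1e-6`` relative under every
    condition; otherwise the reaction is restored and logged.
    """
    model = model.copy()
    conditions = list(condition_constraints_list) or [{}]
    ref_opt = [optimum(model, c) for c in conditions]
    if not all(np.isfinite(o) for o in ref_opt):
        raise ReductionError("infeasible condition in pFBA pruning")
    max_flux = {}
    for cond in conditions:
        with model:
            _apply_constraints(model, cond)
            sol = pfba(model)
        for rid, v in sol.fluxes.items():
            max_flux[rid] = max(max_flux.get(rid, 0.0), abs(v))
    candidates = sorted(rid for rid, v in max_flux.items()
                        if v < threshold and rid not in set(protected))
    for rid in candidates:
        rxn = model.reactions.get_by_id(rid)
        stash = (rxn.copy(), rxn.bounds)
        model.remove_reactions([rxn])
        ok = True
        for cond, o in zip(conditions, ref_opt):
            new = optimum(model, cond)
            if not np.isfinite(new) or abs(new - o) > OPT_REL_TOL * max(abs(o), 1.0):
                ok = False
                break
        if ok:
            if record is not None:
                record.removed_reactions.append(rid)
        else:
            model.add_reactions([stash[0]])
            model.reactions.get_by_id(rid).bounds = stash[1]
            if record is not None:
                record.notes.append(f"{rid} restored (removal broke model)")
            logger.info("pFBA prune: restored %s", rid)
    return model


def _internal_loop_reactions(model: Model, tol: float = 1e-6) -> list[str]:
    """Reactions able to carry flux with every boundary reaction closed."""
    with model:
        for rxn in model.boundary:
            rxn.bounds = (0.0, 0.0)
        internal = [r.id for r in model.reactions if r not in model.boundary]
        if not internal:
            return []
        fva = flux_variability_analysis(model, reaction_list=internal,
                                        fraction_of_optimum=0.0)
    loops = fva[(fva["maximum"].abs() > tol) | (fva["minimum"].abs() > tol)]
    return sorted(loops.index.tolist())


def remove_loops(model: Model, protected=(), constraints=None,
                 record: StageRecord | None = None,
                 allow_restriction: bool = True) -> Model:
    """Break thermodynamically infeasible internal cycles.

    While closed-boundary FVA finds internal reactions with nonzero range,
    remove the lexicographically smallest cycle member whose removal keeps
    the model feasible and optimum-preserving; if none can be removed,
    restrict directionality instead.
    """
    model = model.copy()
    ref = optimum(model, constraints)
    protected = set(protected)
    for _ in range(100):
        loops = _internal_loop_reactions(model)
        loops = [r for r in loops if r not in protected]
        if not loops:
            return model
        progressed = False
        for rid in loops:
            rxn = model.reactions.get_by_id(rid)
            stash = (rxn.copy(), rxn.bounds)
            model.remove_reactions([rxn])
            new = optimum(model, constraints)
            if np.isfinite(new) and abs(new - ref) <= OPT_REL_TOL * max(abs(ref), 1.0):
                if record is not None:
                    record.removed_reactions.append(rid)
                progressed = True
                break
            model.add_reactions([stash[0]])
            model.reactions.get_by_id(rid).bounds = stash[1]
        if not progressed and allow_restriction:
            for rid in loops:
                rxn = model.reactions.get_by_id(rid)
                old = rxn.bounds
                for nb in ((max(old[0], 0.0), old[1]), (old[0], min(old[1], 0.0))):
                    if nb == old:
                        continue
                    rxn.bounds = nb
                    new = optimum(model, constraints)
                    still = rid in _internal_loop_reactions(model)
                    if np.isfinite(new) and \
                            abs(new - ref) <= OPT_REL_TOL * max(abs(ref), 1.0) \
                            and not still:
                        if record is not None:
                            record.notes.append(
                                f"{rid} directionality restricted to {nb}")
                        progressed = True
                        break
                    rxn.bounds = old
                if progressed:
                    break
        if not progressed:
            if record is not None:
                record.notes.append(
                    f"unresolvable loop among {loops}; left in place")
            return model
    return model


def prune_dead_ends(model: Model, protected=(),
                    record: StageRecord | None = None) -> Model:
    """Iteratively remove dead-end metabolites and blocked reactions.

    A metabolite is a dead end if, considering reaction reversibilities, it
    can only be produced or only consumed; its reactions are removed and the
    check cascades.  Remaining reactions with zero FVA range are removed.
    Idempotent: a second call removes nothing.
    """
    model = model.copy()
    protected = set(protected)
    changed = True
    while changed:
        changed = False
        # dead-end metabolites
        for met in list(model.metabolites):
            producible = consumable = False
            for rxn in met.reactions:
                coef = rxn.metabolites[met]
                if (coef > 0 and rxn.upper_bound > 0) or \
                        (coef < 0 and rxn.lower_bound < 0):
                    producible = True
                if (coef < 0 and rxn.upper_bound > 0) or \
                        (coef > 0 and rxn.lower_bound < 0):
                    consumable = True
            if not met.reactions or (producible != consumable):
                doomed = [r for r in met.reactions if r.id not in protected]
                if met.reactions and not doomed:
                    continue
                for r in doomed:
                    if record is not None:
                        record.removed_reactions.append(r.id)
                model.remove_reactions(doomed)
                if not met.reactions:
                    model.remove_metabolites([met])
                    if record is not None:
                        record.removed_metabolites.append(met.id)
                changed = True
        # blocked reactions (zero FVA range under current bounds)
        if is_feasible(model):
            from cobra.flux_analysis import find_blocked_reactions
            blocked = [rid for rid in find_blocked_reactions(model)
                       if rid not in protected]
            if blocked:
                for rid in blocked:
                    if record is not None:
                        record.removed_reactions.append(rid)
                model.remove_reactions(
                    [model.reactions.get_by_id(r) for r in blocked])
                changed = True
    return model


def pin_reaction(model: Model, source: Model, reaction_id: str,
                 bounds: tuple[float, float]) -> Model:
    """Ensure ``reaction_id`` is present with the given bounds.

    The reaction is copied from the unreduced source model if pruning removed
    it; unknown ids raise ``KeyError``."""
    if reaction_id not in {r.id for r in source.reactions}:
        raise KeyError(f"reaction {reaction_id!r} not in source model")
    model = model.copy()
    if reaction_id not in {r.id for r in model.reactions}:
        src = source.reactions.get_by_id(reaction_id)
        rxn = Reaction(reaction_id)
        model.add_reactions([rxn])
        for met, coef in src.metabolites.items():
            try:
                m = model.metabolites.get_by_id(met.id)
            except KeyError:
                m = met.copy()
                model.add_metabolites([m])
            rxn.add_metabolites({m: coef})
    model.reactions.get_by_id(reaction_id).bounds = tuple(bounds)
    return model


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def reduce(model: Model, constraints_list,
           config: ReductionConfig | None = None) -> tuple[Model, ReductionReport]:
    """Run the four-stage reduction pipeline with dead-end cleanup after
    each stage; returns the reduced model and a complete change report.

    ``constraints_list``: per-condition dicts mapping exchange reaction id to
    (lb, ub) flux bounds.  The first condition serves as the feasibility /
    optimum reference.
    """
    cfg = config or ReductionConfig()
    conditions = list(constraints_list) or [{}]
    ref = conditions[0]
    report = ReductionReport(pinned=sorted(cfg.pins))
    source = model
    protected = _protected(model, cfg)

    def stage(name):
        rec = StageRecord(name=name)
        rec.objective_before = optimum(current, ref)
        report.stages.append(rec)
        return rec

    current = model

    rec = stage("resolve_infeasibilities")
    current, added = resolve_infeasibilities(current, ref, cfg.demand_candidates)
    rec.added_reactions = added
    protected |= set(added)
    current = prune_dead_ends(current, protected, rec)
    rec.objective_after = optimum(current, ref)
    rec.feasible_after = np.isfinite(rec.objective_after)

    rec = stage("essential_exchanges")
    retain = essential_exchanges(current, cfg.measured_exchanges, ref)
    for rxn in list(current.exchanges):
        if rxn.id not in retain:
            rec.removed_reactions.append(rxn.id)
            current.remove_reactions([rxn])
    current = prune_dead_ends(current, protected, rec)
    rec.objective_after = optimum(current, ref)
    rec.feasible_after = np.isfinite(rec.objective_after)

    rec = stage("pfba_prune")
    current = pfba_prune(current, conditions, cfg.pfba_threshold, protected, rec)
    current = prune_dead_ends(current, protected, rec)
    rec.objective_after = optimum(current, ref)
    rec.feasible_after = np.isfinite(rec.objective_after)

    rec = stage("remove_loops")
    current = remove_loops(current, protected, ref, rec,
                           cfg.allow_directionality_restriction)
    current = prune_dead_ends(current, protected, rec)
    for rid, bounds in cfg.pins.items():
        current = pin_reaction(current, source, rid, bounds)
    rec.objective_after = optimum(current, ref)
    rec.feasible_after = np.isfinite(rec.objective_after)

    if not all(s.feasible_after for s in report.stages):
        bad = [s.name for s in report.stages if not s.feasible_after]
        raise ReductionError(f"feasibility lost in stage(s): {bad}")
    return current, report
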