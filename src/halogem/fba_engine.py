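"""Flux balance analysis: LP optimization, conditions, screens, essentiality.

FBA maximizes (or minimizes) the flux of an objective reaction subject to the
steady-state mass balance S.v = 0 and per-reaction bounds.  With biomass as
objective the optimum equals the maximum specific growth rate in h^-1.

Conditions bundle what changes between simulated environments: exchange-bound
overrides (uptake = negative lower bound), a fixed non-growth ATP maintenance
flux (ATPM, held at both bounds), and which biomass formulation is the
objective — the low/high-salinity contrast is just two ConditionSpecs.

Only the LP objective value is treated as canonical; flux vectors at the
optimum may be degenerate (alternate optima), which FBA cannot distinguish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network_core import MetabolicModel, build_S

logger = logging.getLogger(__name__)

#: growth below this (h^-1) counts as "no growth" in screens and essentiality
GROWTH_EPSILON = 1e-6

#: default fixed ATPM flux, mmol gDW^-1 h^-1
ATPM_FLUX = 7.6


class ConditionError(ValueError):
    """A condition references reactions absent from the model."""


@dataclass
class ConditionSpec:
    """Named environment: biomass choice + exchange overrides + fixed fluxes.

    ``exchange_overrides`` maps exchange-reaction ids to (lower, upper) bound
    pairs; ``fixed_fluxes`` pins a reaction to a single value at both bounds
    (used for the obligatory ATPM drain).
    """

    name: str
    biomass_id: str
    exchange_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_fluxes: dict[str, float] = field(default_factory=dict)

    def validate(self, model: MetabolicModel) -> None:
        rids = {r.id: r for r in model.reactions}
        if self.biomass_id not in rids:
            raise ConditionError(f"biomass reaction {self.biomass_id!r} not in model")
        for rid in self.exchange_overrides:
            r = rids.get(rid)
            if r is None:
                raise ConditionError(f"override for unknown reaction {rid!r}")
            if r.kind not in ("exchange", "maintenance"):
                raise ConditionError(
                    f"override target {rid!r} is kind {r.kind!r}, "
                    "expected exchange or maintenance"
                )
        for rid in self.fixed_fluxes:
            if rid not in rids:
                raise ConditionError(f"fixed flux for unknown reaction {rid!r}")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: pd.Series | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def optimize(
    model: MetabolicModel, objective_id: str | None = None, sense: str = "max"
) -> FluxSolution:
    """Solve the FBA linear program with the HiGHS solver.

    Infeasibility and unboundedness are reported in ``status``, never raised.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    obj = objective_id or model.objective_id
    if not obj:
        raise ValueError("no objective reaction given and model has none")
    sm = build_S(model)
    try:
        j = sm.reaction_ids.index(obj)
    except ValueError:
        raise KeyError(f"objective reaction {obj!r} not in model") from None
    n = len(sm.reaction_ids)
    c = np.zeros(n)
    c[j] = -1.0 if sense == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c,
        A_eq=sm.matrix,
        b_eq=np.zeros(sm.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return FluxSolution("infeasible", None, None)
    if res.status == 3:
        return FluxSolution("unbounded", None, None)
    if not res.success:
        return FluxSolution("infeasible", None, None)
    value = -res.fun if sense == "max" else res.fun
    fluxes = pd.Series(res.x, index=sm.reaction_ids, name=model.id)
    return FluxSolution("optimal", float(value), fluxes)


def apply_condition(model: MetabolicModel, cond: ConditionSpec) -> MetabolicModel:
    """Return a modified copy with the condition's bounds and objective set.

    The input model is untouched; applying the same condition twice is a
    no-op the second time.
    """
    cond.validate(model)
    out = model.copy()
    for r in out.reactions:
        if r.id in cond.exchange_overrides:
            lb, ub = cond.exchange_overrides[r.id]
            r.lower_bound, r.upper_bound = float(lb), float(ub)
        if r.id in cond.fixed_fluxes:
            v = float(cond.fixed_fluxes[r.id])
            r.lower_bound = r.upper_bound = v
    out.objective_id = cond.biomass_id
    return out


def set_medium_m63(
    model: MetabolicModel, medium_exchange_ids: list[str]
) -> MetabolicModel:
    """Open a minimal (M63-style) medium: inorganic exchanges free, organics closed.

    Every exchange on the supplied list gets bounds (-1000, 1000); every other
    exchange has its lower bound raised to 0 (no uptake) until a carbon source
    is chosen explicitly.  A listed exchange missing from the model is logged
    as a warning, not fatal.
    """
    out = model.copy()
    present = {r.id for r in out.exchanges}
    for rid in medium_exchange_ids:
        if rid not in present:
            logger.warning("medium exchange %r not found in model %r", rid, model.id)
    medium = set(medium_exchange_ids)
    for r in out.reactions:
        if r.kind != "exchange":
            continue
        if r.id in medium:
            r.lower_bound, r.upper_bound = -1000.0, 1000.0
        else:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def screen_carbon_sources(
    model: MetabolicModel,
    source_exchange_ids: list[str],
    uptake: float = 10.0,
    glucose_exchange_id: str | None = None,
) -> pd.DataFrame:
    """Sole-carbon-source growth screen.

    One FBA per candidate: the default carbon source (glucose) is closed, the
    candidate's exchange lower bound is set to ``-uptake``, growth maximized.
    A source supports growth when the optimum exceeds GROWTH_EPSILON;
    infeasible problems are recorded as no-growth.
    """
    exch = {r.id for r in model.exchanges}
    bad = [rid for rid in source_exchange_ids if rid not in exch]
    if bad:
        raise ConditionError(f"not exchange reactions of the model: {bad}")
    rows = []
    for rid in source_exchange_ids:
        m = model.copy()
        if glucose_exchange_id and glucose_exchange_id != rid:
            m.get_reaction(glucose_exchange_id).lower_bound = 0.0
        r = m.get_reaction(rid)
        r.lower_bound = -abs(uptake)
        if r.upper_bound < 0:
            r.upper_bound = 0.0
        sol = optimize(m)
        growth = sol.objective_value if sol.ok else 0.0
        rows.append({"source": rid, "growth_rate": growth, "grows": growth > GROWTH_EPSILON})
    return pd.DataFrame(rows).set_index("source")


@dataclass
class EssentialityReport:
    """Per-gene post-deletion growth for one condition."""

    condition: str
    wild_type_growth: float
    table: pd.DataFrame  # index gene; columns growth_rate, essential

    @property
    def essential(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["essential"]])


def single_gene_deletions(
    model: MetabolicModel,
    cond: ConditionSpec | None = None,
    growth_epsilon: float = GROWTH_EPSILON,
) -> EssentialityReport:
    """Single-gene knockout screen with GPR propagation.

    For each gene, every reaction whose GPR evaluates false with that gene
    removed is constrained to zero flux (complexes break on any subunit loss;
    isozymes rescue), growth is re-maximized, and the gene is essential when
    the optimum falls below ``growth_epsilon``.
    """
    base = apply_condition(model, cond) if cond is not None else model.copy()
    wt = optimize(base)
    wt_growth = wt.objective_value if wt.ok else 0.0
    rows = []
    for gene in base.genes:
        hit = [r.id for r in base.reactions if not r.gpr.evaluate({gene})]
        if not hit:
            growth = wt_growth
        else:
            m = base.copy()
            for rid in hit:
                r = m.get_reaction(rid)
                r.lower_bound = r.upper_bound = 0.0
            sol = optimize(m)
            growth = sol.objective_value if sol.ok else 0.0
        rows.append(
            {"gene": gene, "growth_rate": growth, "essential": growth < growth_epsilon}
        )
    table = pd.DataFrame(rows).set_index("gene")
    return EssentialityReport(
        condition=cond.name if cond is not None else model.id,
        wild_type_growth=wt_growth,
        table=table,
    )


def essentiality_comparison(a: EssentialityReport, b: EssentialityReport) -> dict:
    """Shared and condition-unique essential-gene sets for two conditions."""
    ea, eb = a.essential, b.essential
    return {
        "condition_a": a.condition,
        "condition_b": b.condition,
        "essential_a": sorted(ea),
        "essential_b": sorted(eb),
        "shared": sorted(ea & eb),
        "only_a": sorted(ea - eb),
        "only_b": sorted(eb - ea),
    }


def atp_yield_per_substrate(
    model: MetabolicModel,
    cond: ConditionSpec | None,
    substrate_exchange_id: str,
    uptake: float = 10.0,
    maintenance_id: str | None = None,
) -> float:
    """Maximum mol ATP per mol substrate, via the maintenance hydrolysis flux.

    Biomass is pinned to zero, the substrate uptake is fixed, and the ATP
    hydrolysis (maintenance) flux is maximized; the yield is that optimum
    divided by the uptake rate.
    """
    m = apply_condition(model, cond) if cond is not None else model.copy()
    if maintenance_id is None:
        maint = [r.id for r in m.reactions if r.kind == "maintenance"]
        if not maint:
            raise ConditionError("model has no maintenance (ATP hydrolysis) reaction")
        maintenance_id = maint[0]
    else:
        m.get_reaction(maintenance_id)  # raises KeyError if absent
    for r in m.reactions:
        if r.kind == "biomass":
            r.lower_bound = r.upper_bound = 0.0
    mr = m.get_reaction(maintenance_id)
    mr.lower_bound, mr.upper_bound = 0.0, 1000.0
    sub = m.get_reaction(substrate_exchange_id)
    sub.lower_bound = sub.upper_bound = -abs(uptake)
    sol = optimize(m, objective_id=maintenance_id)
    if not sol.ok:
        return 0.0
    return sol.objective_value / abs(uptake)
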