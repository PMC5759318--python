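"""Dead-end and blocked-metabolite detection.

Two complementary detectors, mirroring the usual curation workflow:

* **Root gaps** come straight from the sign pattern of the stoichiometric
  matrix: after expanding each reversible reaction into forward and reverse
  directions, a metabolite that only ever appears with negative coefficients
  is never produced (root no-production); one that only appears with positive
  coefficients is never consumed (root no-consumption).

* **Blocked metabolites** need flux-capacity testing, because a metabolite
  with both producers and consumers can still be blocked when its producers
  are themselves starved (downstream gaps).  Production is probed with one LP
  per metabolite: a temporary sink is added, all exchanges are opened, and
  the sink flux is maximized; consumption symmetrically with a temporary
  source.  Two mass-balance modes are supported: ``strict`` keeps S.v = 0 on
  every row, ``relaxed`` allows accumulation (S.v >= 0 for production tests,
  S.v <= 0 for consumption tests) — the same pair of options the GapFind MILP
  is conventionally run with.  Downstream/upstream gap sets are the blocked
  sets minus the root sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .network_core import MetabolicModel, build_S

BLOCKED_TOL = 1e-8
_PROBE_BOUND = 1000.0


@dataclass
class GapReport:
    mode: str
    root_no_production: frozenset[str]
    root_no_consumption: frozenset[str]
    blocked_production: frozenset[str]
    blocked_consumption: frozenset[str]
    n_metabolites: int
    downstream_no_production: frozenset[str] = field(init=False)
    upstream_no_consumption: frozenset[str] = field(init=False)

    def __post_init__(self):
        self.downstream_no_production = self.blocked_production - self.root_no_production
        self.upstream_no_consumption = self.blocked_consumption - self.root_no_consumption

    @property
    def blocked_total(self) -> int:
        return len(
            self.root_no_production
            | self.root_no_consumption
            | self.blocked_production
            | self.blocked_consumption
        )

    @property
    def blocked_fraction(self) -> float:
        return self.blocked_total / self.n_metabolites if self.n_metabolites else 0.0

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "root_no_production": len(self.root_no_production),
            "root_no_consumption": len(self.root_no_consumption),
            "downstream_no_production": len(self.downstream_no_production),
            "upstream_no_consumption": len(self.upstream_no_consumption),
            "blocked_total": self.blocked_total,
            "blocked_fraction": self.blocked_fraction,
        }


def root_gaps(model: MetabolicModel) -> tuple[frozenset[str], frozenset[str]]:
    """Sign-scan dead ends on the direction-split stoichiometric matrix.

    Returns (root_no_production, root_no_consumption).  A metabolite touching
    no reaction at all is a member of both sets.
    """
    sm = build_S(model)
    produced = np.zeros(len(sm.metabolite_ids), dtype=bool)
    consumed = np.zeros(len(sm.metabolite_ids), dtype=bool)
    midx = sm.met_index
    for r in model.reactions:
        fwd = r.upper_bound > 0
        rev = r.lower_bound < 0
        for mid, coeff in r.stoichiometry.items():
            if coeff == 0:
                continue
            i = midx[mid]
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                produced[i] = True
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumed[i] = True
    mids = np.array(sm.metabolite_ids)
    return frozenset(mids[~produced]), frozenset(mids[~consumed])


def _capacity_blocked(model: MetabolicModel, direction: str, mode: str) -> frozenset[str]:
    """Metabolites whose production (or consumption) capacity is <= tol."""
    probe = model.copy()
    for r in probe.reactions:
        if r.kind == "exchange":
            r.lower_bound, r.upper_bound = -_PROBE_BOUND, _PROBE_BOUND
    sm = build_S(probe)
    m, n = sm.shape
    lo = np.array([r.lower_bound for r in probe.reactions])
    hi = np.array([r.upper_bound for r in probe.reactions])
    sign = -1.0 if direction == "production" else 1.0  # sink vs source column
    blocked = []
    c = np.zeros(n + 1)
    c[n] = -1.0  # maximize probe flux
    for i, mid in enumerate(sm.metabolite_ids):
        col = sp.csr_matrix(([sign], ([i], [0])), shape=(m, 1))
        A = sp.hstack([sm.matrix, col], format="csr")
        bounds = list(zip(lo, hi)) + [(0.0, _PROBE_BOUND)]
        if mode == "strict":
            res = linprog(c, A_eq=A, b_eq=np.zeros(m), bounds=bounds, method="highs")
        else:
            # accumulation-relaxed: S.v >= 0 for production, <= 0 for consumption
            A_ub = -A if direction == "production" else A
            res = linprog(c, A_ub=A_ub, b_ub=np.zeros(m), bounds=bounds, method="highs")
        capacity = -res.fun if res.success else 0.0
        if capacity <= BLOCKED_TOL:
            blocked.append(mid)
    return frozenset(blocked)


def blocked_metabolites(model: MetabolicModel, mode: str = "strict") -> GapReport:
    """Full gap report under one mass-balance mode (``strict`` or ``relaxed``)."""
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    rnp, rnc = root_gaps(model)
    return GapReport(
        mode=mode,
        root_no_production=rnp,
        root_no_consumption=rnc,
        blocked_production=_capacity_blocked(model, "production", mode),
        blocked_consumption=_capacity_blocked(model, "consumption", mode),
        n_metabolites=len(model.metabolites),
    )
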