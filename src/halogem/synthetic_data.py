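"""Toy metabolic models with analytically known ground truth.

Every pipeline stage needs fixtures whose correct answer is known without
running the pipeline.  This module generates three families:

* ``make_toy_core_model`` — a 3-compartment (cytoplasm/periplasm/
  extracellular) core network with alternate glucose-catabolism routes of
  decreasing ATP/redox yield (EMP/ED-like), a lumped TCA loop, oxidative
  phosphorylation, and an ectoine-like osmolyte drained by two biomass
  reactions whose solute coefficient differs between a low- and a
  high-salinity condition.  The maximal growth rate is derived symbolically
  from the mass balances at generation time (exact rational arithmetic), as
  is the table of stoichiometrically coupled reaction pairs and the
  essential-gene set.

* ``make_ectoine_cycles_model`` — k mutually independent linear
  pathway "cycles", each internally flux-coupled 1:1; a correlation network
  over uniform samples must recover exactly k modules.

* ``make_random_network`` — seeded random sparse networks, feasible by a
  constructed spanning pathway, for fuzzing FBA against the exact
  vertex-enumeration LP oracle and the gap finder against graph
  reachability.

The generator-side truths (``brute_force_lp_optimum`` and the closed forms
below) are deliberately independent of the LP solver path used by
:mod:`halogem.fba_engine`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .fba_engine import ConditionSpec
from .network_core import GPRRule, Metabolite, MetabolicModel, Reaction


# ---------------------------------------------------------------------------
# Exact LP oracle (vertex enumeration over basic solutions)
# ---------------------------------------------------------------------------


def _frac(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(float(x)))


def _row_reduce(rows: list[list[Fraction]]) -> list[int]:
    """Indices of a maximal linearly independent subset of rows."""
    if not rows:
        return []
    ncols = len(rows[0])
    basis: list[list[Fraction]] = []
    keep: list[int] = []
    for ri, row in enumerate(rows):
        vec = list(row)
        for b in basis:
            piv = next((j for j, v in enumerate(b) if v != 0), None)
            if piv is not None and vec[piv] != 0:
                f = vec[piv] / b[piv]
                vec = [v - f * bv for v, bv in zip(vec, b)]
        if any(v != 0 for v in vec):
            basis.append(vec)
            keep.append(ri)
        if len(keep) == ncols:
            break
    return keep


def _solve_square(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction] | None:
    """Exact Gaussian elimination; None when A is singular."""
    n = len(A)
    M = [row[:] + [bv] for row, bv in zip(A, b)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [v / pv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [v - f * pv2 for v, pv2 in zip(M[r], M[col])]
    return [M[r][n] for r in range(n)]


def brute_force_lp_optimum(
    model: MetabolicModel, objective_id: str | None = None, sense: str = "max"
) -> Fraction | None:
    """Exact FBA optimum by enumerating basic feasible solutions.

    Every vertex of {S.v = 0, lb <= v <= ub} is a basic solution: r = rank(S)
    basic variables solved from the equalities, the rest pinned at a bound.
    All C(n, r) * 2^(n-r) candidates are enumerated in rational arithmetic,
    so the result is exact; intended for toys with n <= ~8 reactions.
    Returns None when the polytope is empty.
    """
    obj = objective_id or model.objective_id
    rids = model.reaction_ids()
    n = len(rids)
    jobj = rids.index(obj)
    mids = model.metabolite_ids()
    midx = {m: i for i, m in enumerate(mids)}
    A = [[Fraction(0)] * n for _ in mids]
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            A[midx[mid]][j] = _frac(coeff)
    lo = [_frac(r.lower_bound) for r in model.reactions]
    hi = [_frac(r.upper_bound) for r in model.reactions]

    keep = _row_reduce(A)
    Ared = [A[i] for i in keep]
    r = len(Ared)
    best: Fraction | None = None
    better = (lambda a, b: a > b) if sense == "max" else (lambda a, b: a < b)

    for basic in itertools.combinations(range(n), r):
        sub = [[Ared[i][j] for j in basic] for i in range(r)]
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in itertools.product((0, 1), repeat=len(nonbasic)):
            x = [Fraction(0)] * n
            for j, c in zip(nonbasic, choice):
                x[j] = lo[j] if c == 0 else hi[j]
            rhs = [
                -sum(Ared[i][j] * x[j] for j in nonbasic) for i in range(r)
            ]
            xb = _solve_square(sub, rhs) if r else []
            if xb is None:
                break  # singular basis: no nonbasic assignment can fix that
            for j, v in zip(basic, xb):
                x[j] = v
            if all(lo[j] <= x[j] <= hi[j] for j in range(n)):
                val = x[jobj]
                if best is None or better(val, best):
                    best = val
    return best


# ---------------------------------------------------------------------------
# Core toy model
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    """Stated world of the core toy: route count, loop, osmolyte demand."""

    seed: int = 0
    n_alternate_routes: int = 2
    include_tca_loop: bool = True
    osmolyte_drain_coefficients: tuple[float, float] = (0.1, 0.5)  # mmol gDW^-1, low/high
    glucose_uptake: float = 10.0  # mmol gDW^-1 h^-1
    o2_uptake: float = 20.0
    atpm_flux: float = 7.6  # fixed NGAM applied by conditions

    def validate(self) -> None:
        if self.n_alternate_routes < 2:
            raise ValueError("need at least 2 alternate catabolic routes")
        lo, hi = self.osmolyte_drain_coefficients
        if lo < 0 or hi < 0:
            raise ValueError("osmolyte coefficients must be non-negative")


@dataclass
class ToyTruth:
    """Generator-recorded ground truth for the core toy."""

    analytic_optimum: Fraction  # max growth of the base model (BIO_L, ATPM free)
    couplings: list[tuple[str, str, float]]  # (rxn_a, rxn_b, forced ratio b/a)
    essential_genes: frozenset[str]
    nonessential_genes: frozenset[str]

    def optimum_with_atpm(self, atpm: float, osmolyte_coeff: float,
                          glucose_uptake: float | None = None) -> Fraction:
        """Closed-form optimum with a fixed ATPM drain and solute coefficient."""
        G = _frac(glucose_uptake if glucose_uptake is not None else self._G)
        e = _frac(osmolyte_coeff)
        M = _frac(atpm)
        mu = (24 * G - M) / (14 + 11 * e)
        return max(mu, Fraction(0))

    _G: float = 10.0


# biomass drains per unit growth besides the osmolyte: 1 pyruvate, 5 ATP
_BIO_PYR = 1.0
_BIO_ATP = 5.0


def _core_optimum(G: Fraction, e: Fraction, M: Fraction) -> Fraction:
    """Max growth of the core toy, derived from the mass balances.

    With the best route yielding 2 ATP + 2 NADH + 2 pyruvate per glucose, the
    TCA loop 1 ATP + 4 NADH + 3 CO2 per pyruvate, P/O = 2, osmolyte cost
    2 ATP each, and biomass drains (1 pyr + 5 ATP + e ect) per unit growth,
    ATP is the binding resource and

        mu* = (24 G - M) / (14 + 11 e)

    as long as the TCA flux 2G - (1+e) mu* and the O2 demand stay feasible.
    """
    mu = (24 * G - M) / (14 + 11 * e)
    return max(mu, Fraction(0))


def make_toy_core_model(spec: ToySpec | None = None) -> tuple[MetabolicModel, ToyTruth]:
    spec = spec or ToySpec()
    spec.validate()
    e_low, e_high = spec.osmolyte_drain_coefficients

    def met(mid, name="", formula="", charge=0):
        return Metabolite(id=mid, name=name or mid, formula=formula, charge=charge)

    mets = [
        met("glc-d[e]", "d-glucose (extracellular)", "C6H12O6"),
        met("glc-d[p]", "d-glucose (periplasm)", "C6H12O6"),
        met("glc-d[c]", "d-glucose (cytoplasm)", "C6H12O6"),
        met("pyr[c]", "pyruvate", "C3H3O3", -1),
        met("atp[c]", "ATP", "C10H12N5O13P3", -4),
        met("adp[c]", "ADP", "C10H12N5O10P2", -3),
        met("nadh[c]", "NADH", "", -2),
        met("nad[c]", "NAD+", "", -1),
        met("o2[e]", "oxygen (extracellular)", "O2"),
        met("o2[c]", "oxygen (cytoplasm)", "O2"),
        met("co2[c]", "CO2 (cytoplasm)", "CO2"),
        met("co2[e]", "CO2 (extracellular)", "CO2"),
        met("ect[c]", "ectoine-like osmolyte", "C6H10N2O2"),
        met("ect[e]", "ectoine-like osmolyte (extracellular)", "C6H10N2O2"),
    ]

    genes = ["gPorin", "gPtsA", "gPtsB", "gEd", "gTcaA", "gTcaB", "gOx", "gEct"]
    route_genes: list[str] = []

    rxns: list[Reaction] = [
        Reaction("EX_glc", "glucose exchange", {"glc-d[e]": -1.0},
                 -spec.glucose_uptake, 0.0, "Exchange", GPRRule(), "exchange"),
        Reaction("EX_o2", "oxygen exchange", {"o2[e]": -1.0},
                 -spec.o2_uptake, 0.0, "Exchange", GPRRule(), "exchange"),
        Reaction("EX_co2", "CO2 exchange", {"co2[e]": -1.0},
                 0.0, 1000.0, "Exchange", GPRRule(), "exchange"),
        Reaction("GLCt_ep", "glucose diffusion e->p",
                 {"glc-d[e]": -1.0, "glc-d[p]": 1.0},
                 0.0, 1000.0, "Transport", GPRRule.parse("gPorin"), "transport"),
        Reaction("GLCt_pc", "glucose PTS-like uptake p->c",
                 {"glc-d[p]": -1.0, "glc-d[c]": 1.0},
                 0.0, 1000.0, "Transport", GPRRule.parse("gPtsA and gPtsB"), "transport"),
        Reaction("O2t", "oxygen diffusion", {"o2[e]": -1.0, "o2[c]": 1.0},
                 0.0, 1000.0, "Transport", GPRRule(), "transport"),
        Reaction("CO2t", "CO2 diffusion", {"co2[c]": -1.0, "co2[e]": 1.0},
                 0.0, 1000.0, "Transport", GPRRule(), "transport"),
    ]

    # alternate catabolic routes: yield halves with each extra route
    for r_i in range(spec.n_alternate_routes):
        y = 2.0 * (0.5**r_i)
        if r_i == 0:
            rid, gpr, sub = "CAT_EMP", GPRRule.parse("gEmp1 or gEmp2"), "Glycolysis"
            route_genes.extend(["gEmp1", "gEmp2"])
        elif r_i == 1:
            rid, gpr, sub = "CAT_ED", GPRRule.parse("gEd"), "Entner-Doudoroff"
        else:
            rid, gpr, sub = f"CAT_ALT{r_i}", GPRRule.parse(f"gAlt{r_i}"), "Alternate catabolism"
            route_genes.append(f"gAlt{r_i}")
        rxns.append(
            Reaction(rid, f"glucose catabolism route {r_i}",
                     {"glc-d[c]": -1.0, "adp[c]": -y, "nad[c]": -y,
                      "pyr[c]": 2.0, "atp[c]": y, "nadh[c]": y},
                     0.0, 1000.0, sub, gpr, "metabolic")
        )

    if spec.include_tca_loop:
        rxns.append(
            Reaction("TCA", "lumped TCA loop",
                     {"pyr[c]": -1.0, "nad[c]": -4.0, "adp[c]": -1.0,
                      "co2[c]": 3.0, "nadh[c]": 4.0, "atp[c]": 1.0},
                     0.0, 1000.0, "TCA cycle", GPRRule.parse("gTcaA and gTcaB"),
                     "metabolic")
        )
    rxns += [
        Reaction("OXPHOS", "oxidative phosphorylation (P/O 2)",
                 {"nadh[c]": -1.0, "o2[c]": -0.5, "adp[c]": -2.0,
                  "nad[c]": 1.0, "atp[c]": 2.0},
                 0.0, 1000.0, "Oxidative phosphorylation", GPRRule.parse("gOx"),
                 "metabolic"),
        Reaction("ECT_SYN", "osmolyte synthesis",
                 {"pyr[c]": -1.0, "atp[c]": -2.0, "ect[c]": 1.0, "adp[c]": 2.0},
                 0.0, 1000.0, "Compatible solutes", GPRRule.parse("gEct"),
                 "metabolic"),
        Reaction("ECTt", "osmolyte excretion c->e",
                 {"ect[c]": -1.0, "ect[e]": 1.0},
                 0.0, 1000.0, "Transport", GPRRule(), "transport"),
        Reaction("EX_ect", "osmolyte exchange", {"ect[e]": -1.0},
                 0.0, 1000.0, "Exchange", GPRRule(), "exchange"),
        Reaction("BIO_L", "biomass, low salinity",
                 {"pyr[c]": -_BIO_PYR, "atp[c]": -_BIO_ATP, "ect[c]": -e_low,
                  "adp[c]": _BIO_ATP},
                 0.0, 1000.0, "Biomass", GPRRule(), "biomass"),
        Reaction("BIO_H", "biomass, high salinity",
                 {"pyr[c]": -_BIO_PYR, "atp[c]": -_BIO_ATP, "ect[c]": -e_high,
                  "adp[c]": _BIO_ATP},
                 0.0, 1000.0, "Biomass", GPRRule(), "biomass"),
        Reaction("ATPM", "non-growth ATP maintenance",
                 {"atp[c]": -1.0, "adp[c]": 1.0},
                 0.0, 1000.0, "Maintenance", GPRRule(), "maintenance"),
    ]

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes + route_genes,
        objective_id="BIO_L",
        id="toy_core",
    )
    model.validate()

    G, e = _frac(spec.glucose_uptake), _frac(e_low)
    mu = _core_optimum(G, e, Fraction(0))
    if not spec.include_tca_loop:
        raise ValueError(
            "the recorded closed-form optimum assumes the TCA loop; "
            "generate with include_tca_loop=True"
        )
    # feasibility guards on the closed form: TCA flux and O2 demand
    tca = 2 * G - (1 + e) * mu
    ox = 2 * G + 4 * tca
    if tca < 0 or ox / 2 > _frac(spec.o2_uptake):
        raise ValueError("spec combination breaks the closed-form optimum; adjust uptakes")

    couplings = [
        ("EX_glc", "GLCt_ep", -1.0),
        ("GLCt_ep", "GLCt_pc", 1.0),
        ("TCA", "CO2t", 3.0),
        ("CO2t", "EX_co2", 1.0),
        ("O2t", "EX_o2", -1.0),
        ("OXPHOS", "O2t", 0.5),
    ]
    # gTcaA/gTcaB are essential too: without the TCA loop the catabolic routes
    # plus P/O-2 respiration supply at most 3(1+e) ATP per unit growth, below
    # the (5+2e) biomass demand, so only zero growth balances ATP.
    essential = frozenset(
        {"gPorin", "gPtsA", "gPtsB", "gOx", "gEct", "gTcaA", "gTcaB"}
    )
    truth = ToyTruth(
        analytic_optimum=mu,
        couplings=couplings,
        essential_genes=essential,
        nonessential_genes=frozenset(model.genes) - essential,
    )
    truth._G = spec.glucose_uptake
    return model, truth


@dataclass
class ConditionPair:
    low: ConditionSpec
    high: ConditionSpec
    #: per-reaction expected mean flux difference (high minus low); exact when
    #: growth is pinned, because the osmolyte drain is then constraint-fixed
    planted_shift: dict[str, float] = field(default_factory=dict)
    pinned_growth: float | None = None


def make_condition_pair(
    spec: ToySpec | None = None, pin_growth: float | None = 1.0
) -> ConditionPair:
    """Low/high-salinity condition pair for the core toy.

    Both conditions fix the ATPM drain; when ``pin_growth`` is set the
    biomass flux is pinned there too, which constraint-fixes the osmolyte
    synthesis flux at coefficient x growth and makes the planted
    between-condition shift exact: (e_high - e_low) * growth.
    """
    spec = spec or ToySpec()
    spec.validate()
    e_low, e_high = spec.osmolyte_drain_coefficients
    overrides = {
        "EX_glc": (-spec.glucose_uptake, 0.0),
        "EX_o2": (-spec.o2_uptake, 0.0),
        # osmolyte excretion is closed under the salinity conditions so the
        # synthesis flux is pinned at coefficient x growth (exact planted shift)
        "EX_ect": (0.0, 0.0),
    }
    fixed_low: dict[str, float] = {"ATPM": spec.atpm_flux, "BIO_H": 0.0}
    fixed_high: dict[str, float] = {"ATPM": spec.atpm_flux, "BIO_L": 0.0}
    shift: dict[str, float] = {}
    if pin_growth is not None:
        fixed_low["BIO_L"] = pin_growth
        fixed_high["BIO_H"] = pin_growth
        shift["ECT_SYN"] = (e_high - e_low) * pin_growth
    low = ConditionSpec("low_salinity", "BIO_L", dict(overrides), fixed_low)
    high = ConditionSpec("high_salinity", "BIO_H", dict(overrides), fixed_high)
    return ConditionPair(low=low, high=high, planted_shift=shift, pinned_growth=pin_growth)


# ---------------------------------------------------------------------------
# Independent-cycles fixture for correlation modules
# ---------------------------------------------------------------------------


def make_ectoine_cycles_model(n_cycles: int = 4) -> MetabolicModel:
    """k independent linear pathways; each is internally flux-coupled 1:1.

    Every pathway i has its own substrate exchange (uptake free in [-10, 0]),
    a transport step, a conversion step, and a product exchange, so the flux
    polytope is a k-dimensional box and reactions correlate perfectly within
    a pathway and not at all across pathways.
    """
    mets, rxns = [], []
    for i in range(n_cycles):
        s_e, s_c, w_c = f"s{i}[e]", f"s{i}[c]", f"w{i}[c]"
        mets += [Metabolite(id=m) for m in (s_e, s_c, w_c)]
        rxns += [
            Reaction(f"EX_s{i}", "", {s_e: -1.0}, -10.0, 0.0,
                     f"cycle_{i}", GPRRule(), "exchange"),
            Reaction(f"T{i}", "", {s_e: -1.0, s_c: 1.0}, 0.0, 1000.0,
                     f"cycle_{i}", GPRRule(), "transport"),
            Reaction(f"C{i}", "", {s_c: -1.0, w_c: 1.0}, 0.0, 1000.0,
                     f"cycle_{i}", GPRRule(), "metabolic"),
            Reaction(f"EX_w{i}", "", {w_c: -1.0}, 0.0, 1000.0,
                     f"cycle_{i}", GPRRule(), "exchange"),
        ]
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                           objective_id="", id=f"cycles_{n_cycles}")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Random networks for oracle fuzzing
# ---------------------------------------------------------------------------


def make_random_network(m: int, n: int, seed: int) -> MetabolicModel:
    """Seeded random +/-1 network, feasible via a constructed spanning chain.

    ``m`` metabolites are connected by a supply exchange, a linear chain, and
    a drain exchange (guaranteeing a feasible nonzero pathway); further
    random single-substrate/single-product reactions are added until there
    are ``n`` reactions in total (floored at the chain size).  Coefficients
    are all +/-1 and no cofactors couple reactions, so graph-reachability
    arguments apply exactly.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    rng = np.random.Generator(np.random.Philox(seed))
    mets = [Metabolite(id=f"m{i}[c]") for i in range(m)]
    gene_pool = [f"g{i}" for i in range(6)]
    rxns = [
        Reaction("EX_in", "", {"m0[c]": -1.0}, -10.0, 0.0, "", GPRRule(), "exchange"),
        Reaction("EX_out", "", {f"m{m - 1}[c]": -1.0}, 0.0, 1000.0, "", GPRRule(), "exchange"),
    ]
    for i in range(m - 1):
        rxns.append(
            Reaction(f"CH{i}", "", {f"m{i}[c]": -1.0, f"m{i + 1}[c]": 1.0},
                     0.0, 1000.0, "", GPRRule(), "metabolic")
        )
    k = 0
    while len(rxns) < n and m >= 2:
        i, j = rng.choice(m, size=2, replace=False)
        reversible = bool(rng.random() < 0.3)
        gpr = GPRRule()
        u = rng.random()
        a, b, c = rng.choice(gene_pool, size=3, replace=False)
        if u < 0.2:
            gpr = GPRRule.parse(a)
        elif u < 0.35:
            gpr = GPRRule.parse(f"{a} and {b}")
        elif u < 0.5:
            gpr = GPRRule.parse(f"({a} and {b}) or {c}")
        rxns.append(
            Reaction(f"RND{k}", "", {f"m{int(i)}[c]": -1.0, f"m{int(j)}[c]": 1.0},
                     -1000.0 if reversible else 0.0, 1000.0, "", gpr, "metabolic")
        )
        k += 1
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=gene_pool,
                           objective_id="EX_out", id=f"random_{m}x{n}_s{seed}")
    model.validate()
    return model
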