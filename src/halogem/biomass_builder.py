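"""Condition-specific biomass reaction assembly.

A biomass reaction drains monomeric precursors (amino acids, dNTPs, NTPs,
lipids, compatible solutes) in growth-proportional amounts, in mmol gDW^-1,
so that flux through it equals the specific growth rate in h^-1.  Halophilic
bacteria accumulate compatible solutes (ectoine, hydroxyectoine) in
proportion to external salinity, so two biomass formulations are carried: a
low-salinity one (BIO_L analogue) and a high-salinity one (BIO_H analogue)
that differ in solute coefficients, macromolecular composition, and the
energetic cost of polymerization.

Growth-associated ATP maintenance (GAM) is the sum of a composition-agnostic
base cost (36.94 mmol gDW^-1) and a condition-specific polymerization cost
(23.04 mmol gDW^-1 at low salinity, 8.79 at high), giving 59.98 and 45.73
mmol gDW^-1.  Non-growth maintenance (ATPM) is a separate flux of
7.6 mmol gDW^-1 h^-1, handled by the FBA condition layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping

from .network_core import GPRRule, Reaction

GAM_BASE = 36.94  # mmol ATP gDW^-1, composition-independent
POLYMERIZATION_COST_LOW = 23.04  # mmol ATP gDW^-1, low salinity
POLYMERIZATION_COST_HIGH = 8.79  # mmol ATP gDW^-1, high salinity
NGAM = 7.6  # mmol ATP gDW^-1 h^-1 (the ATPM flux)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEOXYRIBONUCLEOTIDES = ("dATP", "dCTP", "dGTP", "dTTP")
RIBONUCLEOTIDES = ("ATP", "CTP", "GTP", "UTP")

#: metabolites of the GAM hydrolysis term, ATP + H2O -> ADP + Pi + H
ENERGY_TERM = {"atp[c]": -1.0, "h2o[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0, "h[c]": 1.0}


class CompositionError(ValueError):
    """A biomass composition violates an invariant."""


def compute_gam(gam_base: float, polymerization_cost: float) -> float:
    """Total growth-associated ATP maintenance, mmol gDW^-1.

    Inputs are tabulated to two decimals; the sum is done in integer cents so
    59.98 and 45.73 are reproduced exactly, with no float drift.
    """
    if gam_base < 0 or polymerization_cost < 0:
        raise CompositionError("GAM components must be non-negative")
    total = Decimal(str(gam_base)) + Decimal(str(polymerization_cost))
    return float(total)


def amino_acid_ratios_from_proteome(coding_sequences: list[str]) -> dict[str, float]:
    """Molar amino-acid ratios under the equal-expression assumption.

    Every protein of the genome is taken as equally expressed, so the ratio
    of residue *a* is its count over the concatenated proteome divided by the
    total residue count.
    """
    if not coding_sequences:
        raise CompositionError("no protein sequences supplied")
    counts = {a: 0 for a in AMINO_ACIDS}
    total = 0
    for i, seq in enumerate(coding_sequences):
        for ch in seq.upper():
            if ch not in counts:
                raise CompositionError(
                    f"non-standard amino-acid letter {ch!r} in sequence {i}"
                )
            counts[ch] += 1
            total += 1
    if total == 0:
        raise CompositionError("all supplied sequences are empty")
    return {a: counts[a] / total for a in AMINO_ACIDS}


def dnt_ratios_from_gc(gc_fraction: float) -> dict[str, float]:
    """Deoxyribonucleotide molar ratios from genomic G+C content.

    Chargaff pairing on double-stranded DNA gives dG = dC = GC/2 and
    dA = dT = (1-GC)/2.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise CompositionError(f"G+C fraction {gc_fraction} outside [0, 1]")
    g = gc_fraction / 2.0
    a = (1.0 - gc_fraction) / 2.0
    return {"dATP": a, "dCTP": g, "dGTP": g, "dTTP": a}


def nt_ratios_from_rna_mix(
    rrna_ratios: Mapping[str, float],
    trna_ratios: Mapping[str, float],
    mrna_ratios: Mapping[str, float],
    proportions: tuple[float, float, float] = (0.83, 0.14, 0.03),
) -> dict[str, float]:
    """Ribonucleotide ratios as a weighted mix of rRNA, tRNA and mRNA pools.

    Default pool proportions follow the classic exponential-growth RNA census
    (~83% rRNA, ~14% tRNA, ~3% mRNA); they are parameters, not constants of
    the organism.
    """
    w = sum(proportions)
    mix = {}
    for nt in RIBONUCLEOTIDES:
        mix[nt] = (
            proportions[0] * rrna_ratios.get(nt, 0.0)
            + proportions[1] * trna_ratios.get(nt, 0.0)
            + proportions[2] * mrna_ratios.get(nt, 0.0)
        ) / w
    total = sum(mix.values())
    if total <= 0:
        raise CompositionError("RNA pools have zero total composition")
    return {nt: v / total for nt, v in mix.items()}


def _check_ratio_group(name: str, ratios: Mapping[str, float]) -> None:
    if any(v < 0 for v in ratios.values()):
        raise CompositionError(f"{name} ratios contain negative entries")
    s = sum(ratios.values())
    if abs(s - 1.0) > 1e-9:
        raise CompositionError(f"{name} ratios sum to {s!r}, expected 1")


@dataclass
class BiomassComposition:
    """Macromolecular composition of one salinity condition.

    Mass fractions are g per gDW; monomer ratios are molar and sum to one per
    group; solute coefficients are mmol gDW^-1 drains of the compatible
    solutes into biomass.
    """

    condition: str  # "low" | "high"
    mass_fractions: dict[str, float]  # protein/dna/rna/lipid/other, g gDW^-1
    amino_acid_ratios: dict[str, float]
    dnt_ratios: dict[str, float]
    nt_ratios: dict[str, float]
    phospholipid_ratios: dict[str, float] = field(default_factory=dict)
    solute_coefficients: dict[str, float] = field(default_factory=dict)  # mmol gDW^-1
    gam_base: float = GAM_BASE
    polymerization_cost: float = POLYMERIZATION_COST_LOW
    ngam: float = NGAM
    from_template: bool = False  # True when filled from the bundled template

    def validate(self) -> None:
        if self.condition not in ("low", "high"):
            raise CompositionError(f"condition must be 'low' or 'high', got {self.condition!r}")
        for k, v in self.mass_fractions.items():
            if v < 0:
                raise CompositionError(f"mass fraction {k!r} negative")
        total_mass = sum(self.mass_fractions.values())
        if abs(total_mass - 1.0) > 0.05:
            raise CompositionError(
                f"mass fractions sum to {total_mass:.4f} g gDW^-1; expected 1 +/- 0.05"
            )
        if self.mass_fractions.get("protein", 0) > 0:
            _check_ratio_group("amino-acid", self.amino_acid_ratios)
        if self.mass_fractions.get("dna", 0) > 0:
            _check_ratio_group("deoxyribonucleotide", self.dnt_ratios)
        if self.mass_fractions.get("rna", 0) > 0:
            _check_ratio_group("ribonucleotide", self.nt_ratios)
        if self.phospholipid_ratios and self.mass_fractions.get("lipid", 0) > 0:
            _check_ratio_group("phospholipid", self.phospholipid_ratios)
        if any(v < 0 for v in self.solute_coefficients.values()):
            raise CompositionError("solute coefficients must be non-negative")
        compute_gam(self.gam_base, self.polymerization_cost)

    @property
    def gam_total(self) -> float:
        return compute_gam(self.gam_base, self.polymerization_cost)


def _group_terms(
    fraction: float,
    ratios: Mapping[str, float],
    monomer_ids: Mapping[str, str],
    weights: Mapping[str, float],
    group: str,
) -> dict[str, float]:
    """Precursor coefficients for one macromolecule group.

    With mean monomer weight w_bar = sum_k ratio_k * weight_k (g mmol^-1),
    the group contributes fraction / w_bar mmol of monomers per gDW, split by
    molar ratio, so sum_k |coeff_k| * weight_k recovers the mass fraction.
    """
    if fraction == 0:
        return {}
    active = {k: r for k, r in ratios.items() if r > 0}
    missing = [k for k in active if k not in weights]
    if missing:
        raise CompositionError(f"no molecular weight for {group} monomer(s) {missing}")
    w_bar = sum(r * weights[k] for k, r in active.items())
    total_mmol = fraction / w_bar
    out = {}
    for k, r in active.items():
        mid = monomer_ids.get(k, k)
        out[mid] = out.get(mid, 0.0) - total_mmol * r
    return out


def assemble_biomass_reaction(
    comp: BiomassComposition,
    monomer_weights: Mapping[str, float],
    monomer_ids: Mapping[str, str] | None = None,
    reaction_id: str | None = None,
) -> Reaction:
    """Build the biomass pseudo-reaction for one condition.

    ``monomer_weights`` maps monomer keys (one-letter amino acids, dNTP/NTP
    names, lipid and solute keys) to g mmol^-1.  ``monomer_ids`` maps monomer
    keys to model metabolite ids (defaults to the key itself).  Precursors
    are consumed (negative coefficients); the GAM hydrolysis
    ATP + H2O -> ADP + Pi + H is added with coefficient equal to the total
    GAM; compatible solutes are drained with their condition coefficients.
    """
    comp.validate()
    monomer_ids = dict(monomer_ids or {})
    stoich: dict[str, float] = {}

    groups = [
        ("protein", comp.amino_acid_ratios),
        ("dna", comp.dnt_ratios),
        ("rna", comp.nt_ratios),
    ]
    if comp.phospholipid_ratios:
        groups.append(("lipid", comp.phospholipid_ratios))
    for group, ratios in groups:
        frac = comp.mass_fractions.get(group, 0.0)
        for mid, c in _group_terms(frac, ratios, monomer_ids, monomer_weights, group).items():
            stoich[mid] = stoich.get(mid, 0.0) + c

    for key, coeff in comp.solute_coefficients.items():
        if coeff == 0:
            continue
        mid = monomer_ids.get(key, key)
        stoich[mid] = stoich.get(mid, 0.0) - coeff

    gam = comp.gam_total
    for mid, sign in ENERGY_TERM.items():
        stoich[mid] = stoich.get(mid, 0.0) + sign * gam

    rid = reaction_id or ("BIO_L" if comp.condition == "low" else "BIO_H")
    return Reaction(
        id=rid,
        name=f"biomass, {comp.condition} salinity",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass",
        gpr=GPRRule(),
        kind="biomass",
    )
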