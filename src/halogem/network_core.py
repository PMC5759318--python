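"""Data model for compartmentalized metabolic networks.

A genome-scale metabolic model (GEM) is represented as plain data: metabolites
with bracketed compartment suffixes (``glc-d[c]``, ``o2[e]``), reactions with
stoichiometry maps and flux bounds in mmol gDW^-1 h^-1, boolean
gene-protein-reaction (GPR) rules, and a designated objective reaction
(normally biomass).  The module also builds the stoichiometric matrix S used
by every downstream analysis: at steady state the mass balance is S.v = 0 with
per-reaction bounds lb_i <= v_i <= ub_i.

Sign conventions follow the constraint-based modeling standard: negative
stoichiometric coefficients consume, positive produce; exchange reactions are
written outward-positive, so uptake is a negative flux (glucose uptake of
10 mmol gDW^-1 h^-1 appears as a lower bound of -10).
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

DEFAULT_BOUND = 1000.0

COMPARTMENTS = ("c", "p", "e")  # cytoplasm, periplasm, extracellular

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass", "maintenance")


class ModelValidationError(ValueError):
    """A model (or model file) violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file could not be parsed."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GPRRule:
    """Boolean gene association: AND = enzyme complex, OR = isozymes.

    The expression tree is stored as nested tuples:
    ``("gene", "g1")``, ``("and", (child, ...))``, ``("or", (child, ...))``.
    ``root is None`` means no gene association; such a reaction is always
    catalyzable.
    """

    root: tuple | None = None

    @staticmethod
    def parse(text: str) -> "GPRRule":
        """Parse a parenthesized infix rule, e.g. ``(g1 and g2) or g3``.

        ``and`` binds tighter than ``or``; keywords are case-insensitive.
        """
        tokens = _GPR_TOKEN.findall(text)
        if not tokens:
            return GPRRule(None)
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            if pos >= len(tokens):
                raise ModelParseError(f"unexpected end of GPR rule: {text!r}")
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or():
            children = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                children.append(parse_and())
            if len(children) == 1:
                return children[0]
            return ("or", tuple(children))

        def parse_and():
            children = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                children.append(parse_atom())
            if len(children) == 1:
                return children[0]
            return ("and", tuple(children))

        def parse_atom():
            tok = take()
            if tok == "(":
                node = parse_or()
                if peek() != ")":
                    raise ModelParseError(f"unbalanced parenthesis in GPR: {text!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ModelParseError(f"unexpected token {tok!r} in GPR: {text!r}")
            return ("gene", tok)

        root = parse_or()
        if pos != len(tokens):
            raise ModelParseError(f"trailing tokens in GPR: {text!r}")
        return GPRRule(root)

    def to_string(self) -> str:
        if self.root is None:
            return ""

        def fmt(node, parent_op=None):
            op = node[0]
            if op == "gene":
                return node[1]
            sep = f" {op} "
            body = sep.join(fmt(c, op) for c in node[1])
            # 'and' binds tighter than 'or': parenthesize an or-node inside and
            if op == "or" and parent_op == "and":
                return f"({body})"
            return body

        return fmt(self.root)

    def genes(self) -> frozenset[str]:
        if self.root is None:
            return frozenset()
        out: set[str] = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for c in node[1]:
                    walk(c)

        walk(self.root)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        """True iff the reaction remains catalyzable with ``knocked_out`` genes
        deleted.  An empty rule is always active."""
        if self.root is None:
            return True
        ko = set(knocked_out)

        def ev(node):
            op = node[0]
            if op == "gene":
                return node[1] not in ko
            if op == "and":
                return all(ev(c) for c in node[1])
            return any(ev(c) for c in node[1])

        return ev(self.root)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def evaluate_gpr(rule: GPRRule, knocked_out: Iterable[str]) -> bool:
    """Functional wrapper over :meth:`GPRRule.evaluate`."""
    return rule.evaluate(knocked_out)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

_MET_ID = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-zA-Z0-9]+)\]$")


@dataclass
class Metabolite:
    """A compartmentalized chemical species, id suffixed ``[c]/[p]/[e]``.

    Formula and charge (fixed at pH 7.2 during curation) are carried as data;
    no protonation-state arithmetic is done here.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = ""

    def __post_init__(self):
        m = _MET_ID.match(self.id)
        if m is None:
            raise ModelValidationError(
                f"metabolite id {self.id!r} lacks a bracketed compartment suffix"
            )
        suffix = m.group("comp")
        if not self.compartment:
            self.compartment = suffix
        elif self.compartment != suffix:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment field {self.compartment!r} "
                f"does not match id suffix {suffix!r}"
            )


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gpr: GPRRule = field(default_factory=GPRRule)
    kind: str = "metabolic"

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def compartments(self) -> frozenset[str]:
        """Distinct compartments among the participating metabolites."""
        comps = set()
        for mid in self.stoichiometry:
            m = _MET_ID.match(mid)
            if m:
                comps.add(m.group("comp"))
        return frozenset(comps)

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class MetabolicModel:
    """The reconstruction as data: metabolites, reactions, genes, objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str = ""
    id: str = "model"

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id!r}")

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_id=self.objective_id,
            id=self.id,
        )

    def validate(self) -> None:
        mids = self.metabolite_ids()
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        mset = set(mids)
        gset = set(self.genes)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - mset
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {sorted(unknown)}"
                )
            missing = r.gpr.genes() - gset
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses genes absent from gene list: {sorted(missing)}"
                )
        if self.objective_id and self.objective_id not in set(rids):
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction of the model"
            )

    def summary(self) -> dict:
        """Counts by reaction kind and compartment, JSON-serializable."""
        by_kind = {k: 0 for k in REACTION_KINDS}
        multi_compartment = 0
        for r in self.reactions:
            by_kind[r.kind] += 1
            if len(r.compartments()) > 1:
                multi_compartment += 1
        met_by_comp: dict[str, int] = {}
        for m in self.metabolites:
            met_by_comp[m.compartment] = met_by_comp.get(m.compartment, 0) + 1
        return {
            "model_id": self.id,
            "n_reactions": len(self.reactions),
            "n_metabolites": len(self.metabolites),
            "n_genes": len(self.genes),
            "reactions_by_kind": by_kind,
            "reactions_multi_compartment": multi_compartment,
            "metabolites_by_compartment": met_by_comp,
            "objective": self.objective_id,
        }


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Sparse m x n matrix S; rows = metabolites, columns = reactions."""

    matrix: sp.csr_matrix
    metabolite_ids: list[str]
    reaction_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def met_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolite_ids)}

    @property
    def rxn_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def build_S(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S from the reaction stoichiometry maps.

    Entry (i, j) is reaction j's coefficient for metabolite i (negative =
    consumed, positive = produced); absent pairs are structural zeros.
    """
    model.validate()
    mids = model.metabolite_ids()
    rids = model.reaction_ids()
    midx = {m: i for i, m in enumerate(mids)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            if coeff == 0:
                continue
            rows.append(midx[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(mids), len(rids)))
    return StoichiometricMatrix(S, mids, rids)


# ---------------------------------------------------------------------------
# Tabular (TSV) dialect
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = [
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "subsystem",
    "gpr",
    "kind",
]
_METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment"]


def _format_coeff(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def format_stoichiometry(stoich: Mapping[str, float]) -> str:
    """Canonical serialization: ``-1 a[c] + 2 b[c]``, metabolites sorted by id."""
    terms = [f"{_format_coeff(c)} {m}" for m, c in sorted(stoich.items())]
    return " + ".join(terms)


def parse_stoichiometry(text: str) -> dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    for term in text.split(" + "):
        parts = term.strip().split(None, 1)
        if len(parts) != 2:
            raise ModelParseError(f"malformed stoichiometry term {term!r}")
        coeff, mid = parts
        try:
            val = float(coeff)
        except ValueError as exc:
            raise ModelParseError(f"bad coefficient in term {term!r}") from exc
        if mid in out:
            raise ModelParseError(f"metabolite {mid!r} repeated in stoichiometry")
        out[mid] = val
    return out


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("\t".join(_METABOLITE_COLUMNS) + "\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.formula}\t{m.charge}\t{m.compartment}\n")
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("\t".join(_REACTION_COLUMNS) + "\n")
        for r in model.reactions:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        format_stoichiometry(r.stoichiometry),
                        repr(float(r.lower_bound)),
                        repr(float(r.upper_bound)),
                        r.subsystem,
                        r.gpr.to_string(),
                        r.kind,
                    ]
                )
                + "\n"
            )
    with open(path / "model.json", "w") as fh:
        json.dump(
            {"id": model.id, "genes": model.genes, "objective_id": model.objective_id},
            fh,
            indent=1,
        )
        fh.write("\n")


def _read_tsv_table(path: Path, columns: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise ModelParseError(f"missing table {path}")
    rows = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ModelParseError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        if header != columns:
            raise ModelParseError(f"{path}: expected columns {columns}, found {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns):
                raise ModelParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, found {len(fields)}"
                )
            rows.append(dict(zip(columns, fields)))
    return rows


def _read_tsv(path: Path) -> MetabolicModel:
    mets = [
        Metabolite(
            id=row["id"],
            name=row["name"],
            formula=row["formula"],
            charge=int(row["charge"]),
            compartment=row["compartment"],
        )
        for row in _read_tsv_table(path / "metabolites.tsv", _METABOLITE_COLUMNS)
    ]
    rxns = [
        Reaction(
            id=row["id"],
            name=row["name"],
            stoichiometry=parse_stoichiometry(row["stoichiometry"]),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            subsystem=row["subsystem"],
            gpr=GPRRule.parse(row["gpr"]),
            kind=row["kind"],
        )
        for row in _read_tsv_table(path / "reactions.tsv", _REACTION_COLUMNS)
    ]
    meta_path = path / "model.json"
    if not meta_path.exists():
        raise ModelParseError(f"missing table {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=list(meta.get("genes", [])),
        objective_id=meta.get("objective_id", ""),
        id=meta.get("id", "model"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Public IO surface
# ---------------------------------------------------------------------------


def read_model(path, format: str = "tsv") -> MetabolicModel:
    """Read a model from the TSV dialect (a directory of tables) or SBML L3."""
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        from . import _sbml

        model = _sbml.read_sbml(path)
        model.validate()
        return model
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "tsv") -> None:
    """Write a model; ``read_model(write_model(m))`` is the identity."""
    model.validate()
    path = Path(path)
    if format == "tsv":
        _write_tsv(model, path)
    elif format == "sbml":
        from . import _sbml

        _sbml.write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
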