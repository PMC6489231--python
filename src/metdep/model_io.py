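"""Genome-scale metabolic model input/output.

Reads a metabolic model either from SBML (Level 2 with legacy
``GENE_ASSOCIATION`` notes, or Level 3 with the fbc gene-product dialect)
or from a two-file tabular fallback, into a light-weight internal
representation.  The model is used downstream purely as a bipartite
reaction/metabolite graph with gene annotations — no bounds, objectives
or flux semantics are retained.

Gene-reaction (GPR) rules are parsed into n-ary boolean trees with the
conventional precedence: ``and`` binds tighter than ``or``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import libsbml

__all__ = [
    "GprLeaf",
    "GprOp",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelParseError",
    "ModelValidationError",
    "parse_gpr",
    "gpr_to_string",
    "read_sbml",
    "read_tabular_model",
    "write_tabular_model",
]


class ModelParseError(ValueError):
    """Raised when a model document or a GPR rule cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates internal consistency rules."""


# ---------------------------------------------------------------------------
# GPR boolean trees


@dataclass(frozen=True)
class GprLeaf:
    """A single gene in a gene-reaction rule."""

    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset((self.gene,))


@dataclass(frozen=True)
class GprOp:
    """An n-ary AND/OR node over sub-rules."""

    op: str  # "and" | "or"
    children: tuple

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"invalid GPR operator: {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("GPR operator node needs at least two children")

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for child in self.children:
            out = out | child.genes()
        return out


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str):
    """Parse a GPR rule string into a boolean tree.

    AND binds tighter than OR; parentheses override.  Operator keywords are
    case-insensitive.  Returns ``None`` for an empty/whitespace rule.
    Raises :class:`ModelParseError` (with the character position) on
    unbalanced parentheses or dangling operators.
    """
    if rule is None:
        return None
    tokens = _tokenize(rule)
    if not tokens:
        return None

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(rule))

    def fail(msg: str, at: int):
        raise ModelParseError(f"GPR parse error at position {at}: {msg} in {rule!r}")

    def parse_or():
        nonlocal idx
        children = [parse_and()]
        while True:
            tok, at = peek()
            if tok is not None and tok.lower() == "or":
                idx += 1
                children.append(parse_and())
            else:
                break
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:
            if isinstance(c, GprOp) and c.op == "or":
                flat.extend(c.children)
            else:
                flat.append(c)
        return GprOp("or", tuple(flat))

    def parse_and():
        nonlocal idx
        children = [parse_atom()]
        while True:
            tok, at = peek()
            if tok is not None and tok.lower() == "and":
                idx += 1
                children.append(parse_atom())
            else:
                break
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:
            if isinstance(c, GprOp) and c.op == "and":
                flat.extend(c.children)
            else:
                flat.append(c)
        return GprOp("and", tuple(flat))

    def parse_atom():
        nonlocal idx
        tok, at = peek()
        if tok is None:
            fail("dangling operator", at)
        if tok == "(":
            idx += 1
            node = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                fail("unbalanced parentheses", at2)
            idx += 1
            return node
        if tok == ")":
            fail("unbalanced parentheses", at)
        if tok.lower() in ("and", "or"):
            fail(f"dangling operator {tok!r}", at)
        idx += 1
        return GprLeaf(tok)

    tree = parse_or()
    tok, at = peek()
    if tok is not None:
        fail(f"unexpected token {tok!r}", at)
    return tree


def gpr_to_string(tree) -> str:
    """Render a GPR tree back to a canonical rule string."""
    if tree is None:
        return ""
    if isinstance(tree, GprLeaf):
        return tree.gene
    parts = []
    for child in tree.children:
        s = gpr_to_string(child)
        if isinstance(child, GprOp):
            s = f"({s})"
        parts.append(s)
    return f" {tree.op} ".join(parts)


# ---------------------------------------------------------------------------
# Model data types


@dataclass(frozen=True)
class Metabolite:
    """A compartment-qualified species."""

    id: str
    compartment: str


@dataclass(frozen=True)
class Reaction:
    """A reaction with positive-coefficient substrate/product lists and a GPR tree."""

    id: str
    substrates: tuple  # ((metabolite_id, coefficient > 0), ...)
    products: tuple
    reversible: bool = True
    gpr: object = None  # GprLeaf | GprOp | None

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.substrates) | frozenset(
            m for m, _ in self.products
        )


@dataclass
class MetabolicModel:
    """Metabolites, reactions and the genes appearing in any GPR rule."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes()
        return frozenset(out)

    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            subs = {m for m, _ in rxn.substrates}
            prods = {m for m, _ in rxn.products}
            for mid in subs | prods:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown species {mid!r}"
                    )
            if subs & prods:
                raise ModelValidationError(
                    f"reaction {rid!r} has species on both sides: {sorted(subs & prods)}"
                )
            for mid, coeff in list(rxn.substrates) + list(rxn.products):
                if not coeff > 0:
                    raise ModelValidationError(
                        f"reaction {rid!r}: non-positive coefficient for {mid!r}"
                    )
        for mid, met in self.metabolites.items():
            if not met.compartment:
                raise ModelValidationError(f"metabolite {mid!r} has empty compartment")


# ---------------------------------------------------------------------------
# SBML reader

_GA_NOTES_RE = re.compile(
    r"GENE[_ ]?ASSOCIATION\s*:\s*([^<\n]*)", flags=re.IGNORECASE
)


def _gpr_from_notes(notes: str):
    if not notes:
        return None
    m = _GA_NOTES_RE.search(notes)
    if m is None:
        return None
    return parse_gpr(m.group(1).strip())


def _gpr_from_fbc(reaction, label_by_id: dict[str, str]):
    plugin = reaction.getPlugin("fbc")
    if plugin is None:
        return None
    gpa = plugin.getGeneProductAssociation()
    if gpa is None:
        return None

    def convert(assoc):
        if assoc is None:
            return None
        if assoc.isGeneProductRef():
            gp = assoc.getGeneProduct()
            return GprLeaf(label_by_id.get(gp, gp))
        if assoc.isFbcAnd() or assoc.isFbcOr():
            op = "and" if assoc.isFbcAnd() else "or"
            children = [convert(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
            children = [c for c in children if c is not None]
            if not children:
                return None
            if len(children) == 1:
                return children[0]
            flat = []
            for c in children:
                if isinstance(c, GprOp) and c.op == op:
                    flat.extend(c.children)
                else:
                    flat.append(c)
            return GprOp(op, tuple(flat))
        return None

    return convert(gpa.getAssociation())


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML document into a :class:`MetabolicModel`.

    Accepts both GPR dialects: legacy ``GENE_ASSOCIATION:`` notes and the
    Level-3 fbc gene-product associations (fbc gene-product labels are
    preferred over raw ids when present).  Species that take part in no
    reaction are retained.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ModelParseError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"no <model> element found in {path}")

    model = MetabolicModel()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.metabolites[sp.getId()] = Metabolite(
            id=sp.getId(), compartment=sp.getCompartment() or "default"
        )

    # fbc gene-product id -> label
    label_by_id: dict[str, str] = {}
    mplugin = sbml_model.getPlugin("fbc")
    if mplugin is not None:
        for i in range(mplugin.getNumGeneProducts()):
            gp = mplugin.getGeneProduct(i)
            label_by_id[gp.getId()] = gp.getLabel() or gp.getId()

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()

        def side(n, getter):
            out = []
            for j in range(n):
                ref = getter(j)
                sid = ref.getSpecies()
                if sid not in model.metabolites:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown species {sid!r}"
                    )
                coeff = ref.getStoichiometry()
                if coeff != coeff or coeff == 0:  # NaN or zero -> default 1
                    coeff = 1.0
                out.append((sid, abs(float(coeff))))
            return tuple(out)

        substrates = side(rxn.getNumReactants(), rxn.getReactant)
        products = side(rxn.getNumProducts(), rxn.getProduct)
        gpr = _gpr_from_fbc(rxn, label_by_id)
        if gpr is None:
            gpr = _gpr_from_notes(rxn.getNotesString())
        model.reactions[rid] = Reaction(
            id=rid,
            substrates=substrates,
            products=products,
            reversible=bool(rxn.getReversible()),
            gpr=gpr,
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Tabular dialect

_REACTIONS_COLUMNS = ["reaction_id", "metabolite_id", "coefficient", "reversible", "compartment"]
_GPR_COLUMNS = ["reaction_id", "rule"]


def read_tabular_model(reactions_path: str, gpr_path: str) -> MetabolicModel:
    """Read the two-file TSV fallback dialect.

    ``reactions_path`` columns: reaction_id, metabolite_id, coefficient
    (negative = substrate, positive = product), reversible (0/1), and an
    optional compartment column.  ``gpr_path`` columns: reaction_id, rule.
    """
    import pandas as pd

    rx = pd.read_csv(reactions_path, sep="\t", dtype={"reaction_id": str, "metabolite_id": str})
    for col in ("reaction_id", "metabolite_id", "coefficient", "reversible"):
        if col not in rx.columns:
            raise ModelParseError(f"reactions table missing column {col!r}")
    model = MetabolicModel()
    subs: dict[str, list] = {}
    prods: dict[str, list] = {}
    rev: dict[str, bool] = {}
    for row in rx.itertuples(index=False):
        rid = str(row.reaction_id)
        mid = str(row.metabolite_id)
        coeff = float(row.coefficient)
        if coeff == 0:
            raise ModelValidationError(
                f"zero coefficient for metabolite {mid!r} in reaction {rid!r}"
            )
        comp = getattr(row, "compartment", None)
        if comp is None or (isinstance(comp, float) and comp != comp):
            comp = "default"
        if mid not in model.metabolites:
            model.metabolites[mid] = Metabolite(id=mid, compartment=str(comp))
        rev[rid] = bool(int(row.reversible))
        if coeff < 0:
            subs.setdefault(rid, []).append((mid, -coeff))
        else:
            prods.setdefault(rid, []).append((mid, coeff))

    gp = pd.read_csv(gpr_path, sep="\t", dtype=str, keep_default_na=False)
    for col in _GPR_COLUMNS:
        if col not in gp.columns:
            raise ModelParseError(f"gpr table missing column {col!r}")
    rules: dict[str, str] = {}
    for row in gp.itertuples(index=False):
        rid = str(row.reaction_id)
        if rid not in rev:
            raise ModelValidationError(f"gpr table references unknown reaction {rid!r}")
        rules[rid] = row.rule

    for rid in rev:
        model.reactions[rid] = Reaction(
            id=rid,
            substrates=tuple(subs.get(rid, ())),
            products=tuple(prods.get(rid, ())),
            reversible=rev[rid],
            gpr=parse_gpr(rules.get(rid, "")),
        )
    model.validate()
    return model


def write_tabular_model(model: MetabolicModel, reactions_path: str, gpr_path: str) -> None:
    """Write a model in the tabular dialect read by :func:`read_tabular_model`."""
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REACTIONS_COLUMNS) + "\n")
        for rid in model.reactions:
            rxn = model.reactions[rid]
            for mid, coeff in rxn.substrates:
                comp = model.metabolites[mid].compartment
                fh.write(f"{rid}\t{mid}\t{-coeff:.10g}\t{int(rxn.reversible)}\t{comp}\n")
            for mid, coeff in rxn.products:
                comp = model.metabolites[mid].compartment
                fh.write(f"{rid}\t{mid}\t{coeff:.10g}\t{int(rxn.reversible)}\t{comp}\n")
    with open(gpr_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_GPR_COLUMNS) + "\n")
        for rid in model.reactions:
            fh.write(f"{rid}\t{gpr_to_string(model.reactions[rid].gpr)}\n")
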