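"""Functional relatedness derived from the metabolic network.

Two enzymes are *neighbors* when some reaction of one and some reaction of
the other share a metabolite (as substrate or product on either side;
direction is ignored), excluding *currency* metabolites — species taking
part in more than a set fraction of all reactions (cofactors, energy and
redox carriers).  Per gene, neighbor lists are capped: candidates are
ranked by the network-wide participation count of their best (least
connected) shared metabolite, ascending, and only the top ``cap`` kept.

*Isozymes* are genes that appear as alternatives in some reaction's GPR —
i.e. connected through an OR ancestor rather than jointly required by a
pure AND chain (AND denotes complex partners, not alternative catalysts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .model_io import GprLeaf, GprOp, MetabolicModel, ModelValidationError

__all__ = [
    "RelatednessMap",
    "DEFAULT_EXCLUDE",
    "identify_currency_metabolites",
    "gene_reaction_membership",
    "metabolite_reaction_counts",
    "extract_neighbors",
    "identify_isozymes",
    "build_relatedness",
    "write_relatedness_tsv",
    "write_gmt",
]

#: Genes excluded from neighbor analysis because of their central signaling role.
DEFAULT_EXCLUDE = frozenset({"EGFR", "PIK"})


@dataclass
class RelatednessMap:
    """Per-gene ordered neighbor lists, isozyme sets, and supporting evidence."""

    neighbors: dict[str, list[str]] = field(default_factory=dict)
    isozymes: dict[str, set[str]] = field(default_factory=dict)
    currency: set[str] = field(default_factory=set)
    connecting_metabolite: dict[tuple[str, str], str] = field(default_factory=dict)
    cap: int = 50

    def related(self, gene: str) -> list[str]:
        """Neighbors followed by any isozymes not already listed (order stable)."""
        nb = list(self.neighbors.get(gene, []))
        seen = set(nb)
        for iso in sorted(self.isozymes.get(gene, ())):
            if iso not in seen:
                nb.append(iso)
                seen.add(iso)
        return nb

    def genes(self) -> set[str]:
        return set(self.neighbors) | set(self.isozymes)


def metabolite_reaction_counts(
    model: MetabolicModel, drop_exchange: bool = False
) -> dict[str, int]:
    """Number of reactions each metabolite takes part in (substrate or product).

    With ``drop_exchange=True``, reactions with an empty substrate or product
    side (boundary/exchange reactions) are not counted.
    """
    counts: dict[str, int] = {mid: 0 for mid in model.metabolites}
    for rxn in model.reactions.values():
        if drop_exchange and (not rxn.substrates or not rxn.products):
            continue
        for mid in rxn.metabolite_ids():
            counts[mid] = counts.get(mid, 0) + 1
    return counts


def identify_currency_metabolites(
    model: MetabolicModel, fraction: float = 0.01, drop_exchange: bool = False
) -> set[str]:
    """Metabolites participating in strictly more than ``fraction`` of reactions."""
    if not model.reactions:
        raise ModelValidationError("cannot identify currency metabolites in an empty model")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    n_reactions = sum(
        1
        for rxn in model.reactions.values()
        if not (drop_exchange and (not rxn.substrates or not rxn.products))
    )
    counts = metabolite_reaction_counts(model, drop_exchange=drop_exchange)
    threshold = fraction * n_reactions
    return {mid for mid, c in counts.items() if c > threshold}


def gene_reaction_membership(model: MetabolicModel) -> dict[str, set[str]]:
    """Map each gene to every reaction whose GPR contains it as a leaf."""
    membership: dict[str, set[str]] = {}
    for rid, rxn in model.reactions.items():
        for gene in rxn.genes():
            membership.setdefault(gene, set()).add(rid)
    return membership


def extract_neighbors(
    model: MetabolicModel,
    currency: set[str],
    cap: int = 50,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> tuple[dict[str, list[str]], dict[tuple[str, str], str]]:
    """Capped, ranked neighboring-enzyme lists.

    Returns ``(neighbors, connecting_metabolite)`` where ``neighbors[g]`` is
    the ordered list of at most ``cap`` neighbor genes and
    ``connecting_metabolite[(g, g2)]`` records the least-connected shared
    non-currency metabolite justifying the pair.  Genes in ``exclude`` get
    no list and appear in no list.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    counts = metabolite_reaction_counts(model)
    membership = gene_reaction_membership(model)

    # metabolite -> genes touching it through any reaction
    genes_by_met: dict[str, set[str]] = {}
    for gene, rids in membership.items():
        if gene in exclude:
            continue
        for rid in rids:
            for mid in model.reactions[rid].metabolite_ids():
                if mid in currency:
                    continue
                genes_by_met.setdefault(mid, set()).add(gene)

    # (gene, candidate) -> best (lowest participation count) shared metabolite
    best: dict[str, dict[str, tuple[int, str]]] = {g: {} for g in membership if g not in exclude}
    for mid, genes in genes_by_met.items():
        c = counts[mid]
        for g, g2 in itertools.permutations(genes, 2):
            cur = best[g].get(g2)
            if cur is None or (c, mid) < cur:
                best[g][g2] = (c, mid)

    neighbors: dict[str, list[str]] = {}
    connecting: dict[tuple[str, str], str] = {}
    for gene in best:
        ranked = sorted(best[gene].items(), key=lambda kv: (kv[1][0], kv[0]))
        kept = ranked[:cap]
        neighbors[gene] = [g2 for g2, _ in kept]
        for g2, (_, mid) in kept:
            connecting[(gene, g2)] = mid
    return neighbors, connecting


def _isozyme_pairs(tree) -> set[tuple[str, str]]:
    """Unordered gene pairs whose lowest common ancestor in the tree is an OR."""
    pairs: set[tuple[str, str]] = set()

    def walk(node) -> frozenset[str]:
        if node is None:
            return frozenset()
        if isinstance(node, GprLeaf):
            return frozenset((node.gene,))
        child_sets = [walk(c) for c in node.children]
        if isinstance(node, GprOp) and node.op == "or":
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    for a in child_sets[i]:
                        for b in child_sets[j]:
                            if a != b:
                                pairs.add((min(a, b), max(a, b)))
        out: frozenset[str] = frozenset()
        for s in child_sets:
            out = out | s
        return out

    walk(tree)
    return pairs


def identify_isozymes(model: MetabolicModel) -> dict[str, set[str]]:
    """Symmetric, irreflexive isozyme map from OR-alternative GPR co-membership."""
    iso: dict[str, set[str]] = {gene: set() for gene in model.genes}
    for rxn in model.reactions.values():
        for a, b in _isozyme_pairs(rxn.gpr):
            iso[a].add(b)
            iso[b].add(a)
    return iso


def build_relatedness(
    model: MetabolicModel,
    currency_fraction: float = 0.01,
    cap: int = 50,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
    drop_exchange: bool = False,
) -> RelatednessMap:
    """Run the full relatedness derivation on a model."""
    currency = identify_currency_metabolites(
        model, fraction=currency_fraction, drop_exchange=drop_exchange
    )
    nb, connecting = extract_neighbors(model, currency, cap=cap, exclude=exclude)
    iso = identify_isozymes(model)
    for gene in exclude:
        iso.pop(gene, None)
    for sets in iso.values():
        sets -= set(exclude)
    return RelatednessMap(
        neighbors=nb,
        isozymes=iso,
        currency=currency,
        connecting_metabolite=connecting,
        cap=cap,
    )


def write_relatedness_tsv(relmap: RelatednessMap, model: MetabolicModel, path: str) -> None:
    counts = metabolite_reaction_counts(model)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trelated_gene\trelation_type\tconnecting_metabolite\tmetabolite_degree\n")
        for gene in sorted(relmap.neighbors):
            for g2 in relmap.neighbors[gene]:
                mid = relmap.connecting_metabolite.get((gene, g2), "")
                deg = counts.get(mid, "")
                fh.write(f"{gene}\t{g2}\tneighbor\t{mid}\t{deg}\n")
        for gene in sorted(relmap.isozymes):
            for g2 in sorted(relmap.isozymes[gene]):
                fh.write(f"{gene}\t{g2}\tisozyme\t\t\n")


def write_gmt(relmap: RelatednessMap, path: str, mode: str = "neighbor") -> None:
    """Write gene sets in GMT style: name, description, member genes."""
    source = relmap.neighbors if mode == "neighbor" else relmap.isozymes
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(source):
            members = list(source[gene]) if mode == "neighbor" else sorted(source[gene])
            if members:
                fh.write("\t".join([f"{gene}_{mode}s", mode] + members) + "\n")
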