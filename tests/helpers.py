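"""Shared test utilities: independent oracles and in-memory dataset builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from metdep.model_io import GprLeaf, GprOp, MetabolicModel, Metabolite, Reaction, parse_gpr
from metdep.screen_data import ScreenDataset


def make_model(reactions: list[tuple], compartment: str = "c") -> MetabolicModel:
    """Build a model from (rid, substrates, products, rule) tuples.

    substrates/products are lists of metabolite ids (coefficient 1) or
    (id, coeff) tuples.
    """
    model = MetabolicModel()

    def side(items):
        out = []
        for item in items:
            mid, coeff = item if isinstance(item, tuple) else (item, 1.0)
            if mid not in model.metabolites:
                model.metabolites[mid] = Metabolite(id=mid, compartment=compartment)
            out.append((mid, float(coeff)))
        return tuple(out)

    for rid, subs, prods, rule in reactions:
        model.reactions[rid] = Reaction(
            id=rid, substrates=side(subs), products=side(prods),
            reversible=True, gpr=parse_gpr(rule),
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Independent exhaustive relatedness oracle (third implementation, kept
# deliberately naive: nested loops over gene pairs and metabolites).


def oracle_currency(model: MetabolicModel, fraction: float) -> set[str]:
    n = len(model.reactions)
    out = set()
    for mid in model.metabolites:
        count = sum(1 for r in model.reactions.values() if mid in r.metabolite_ids())
        if count > fraction * n:
            out.add(mid)
    return out


def oracle_neighbors(
    model: MetabolicModel, fraction: float, cap: int = 50, exclude=frozenset()
) -> dict[str, list[str]]:
    currency = oracle_currency(model, fraction)
    n = len(model.reactions)

    def met_count(mid):
        return sum(1 for r in model.reactions.values() if mid in r.metabolite_ids())

    genes = sorted(g for g in model.genes if g not in exclude)
    mets_of: dict[str, set] = {}
    for g in genes:
        mets: set = set()
        for r in model.reactions.values():
            if g in r.genes():
                mets |= set(r.metabolite_ids())
        mets_of[g] = mets

    out: dict[str, list[str]] = {}
    for g in genes:
        scored = []
        for g2 in genes:
            if g2 == g:
                continue
            shared = [m for m in mets_of[g] & mets_of[g2] if m not in currency]
            if not shared:
                continue
            best = min((met_count(m), m) for m in shared)
            scored.append((best[0], g2))
        scored.sort()
        out[g] = [g2 for _, g2 in scored[:cap]]
    return out


def oracle_isozymes(model: MetabolicModel) -> dict[str, set[str]]:
    """OR-ancestor co-membership, via explicit leaf-pair lowest-common-ancestor."""

    def leaf_paths(node, path=()):
        if node is None:
            return []
        if isinstance(node, GprLeaf):
            return [(node.gene, path)]
        out = []
        for i, child in enumerate(node.children):
            out.extend(leaf_paths(child, path + ((node.op, i),)))
        return out

    iso: dict[str, set[str]] = {g: set() for g in model.genes}
    for rxn in model.reactions.values():
        paths = leaf_paths(rxn.gpr)
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                ga, pa = paths[i]
                gb, pb = paths[j]
                if ga == gb:
                    continue
                # the paths share a prefix of (op, child-index) steps; the first
                # differing step happens at the lowest common ancestor node,
                # whose operator is recorded in that step
                depth = 0
                while depth < min(len(pa), len(pb)) and pa[depth] == pb[depth]:
                    depth += 1
                if depth >= min(len(pa), len(pb)):
                    continue  # distinct leaves always diverge; safety guard
                if pa[depth][0] == "or":
                    iso[ga].add(gb)
                    iso[gb].add(ga)
    return iso


# ---------------------------------------------------------------------------
# In-memory screen dataset builder


def make_dataset(
    n_genes: int = 20,
    n_other: int = 5,
    n_lines: int = 60,
    n_oncogenes: int = 6,
    seed: int = 0,
    media=("DMEM", "RPMI"),
    n_lineages: int = 2,
) -> ScreenDataset:
    """Small fully-null dataset with round-robin annotations (no confounding)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)] + [f"NG{i:04d}" for i in range(n_other)]
    lines = [f"CL{i:04d}" for i in range(n_lines)]
    oncs = [f"ONC{i:03d}" for i in range(n_oncogenes)]
    dataset = ScreenDataset(
        dependency=pd.DataFrame(rng.normal(size=(len(genes), n_lines)), index=genes, columns=lines),
        expression=pd.DataFrame(rng.normal(5, 1, size=(len(genes), n_lines)), index=genes, columns=lines),
        cnv=pd.DataFrame(rng.normal(1, 0.1, size=(len(genes), n_lines)), index=genes, columns=lines),
        mutations=pd.DataFrame(
            (rng.random((len(oncs), n_lines)) < 0.15).astype(float), index=oncs, columns=lines
        ),
        annotations=pd.DataFrame(
            {
                "medium": [media[i % len(media)] for i in range(n_lines)],
                "culture_type": ["adherent" if i % 3 else "suspension" for i in range(n_lines)],
                # period 2*n_lineages so lineage is orthogonal to the medium cycle
                "lineage": [f"lineage{(i // 2) % n_lineages}" for i in range(n_lines)],
            },
            index=pd.Index(lines, name="cell_line"),
        ),
        metabolic_genes={g for g in genes if g.startswith("G")},
    )
    dataset.validate()
    return dataset
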