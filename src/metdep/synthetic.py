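"""Synthetic metabolic models and screen datasets with known ground truth.

The generator builds a random sparse reaction network (with designated
hub metabolites that exceed the currency threshold), assigns GPR rules
mixing single genes, OR pairs (isozymes) and AND pairs (complexes), and
simulates a screen: Gaussian log-scale expression, copy-number ratios
around 1, Bernoulli oncogene mutations, categorical media / culture-type
/ lineage labels (media deliberately correlated with culture type as a
plantable confounding structure), and dependency scores that are pure
noise plus any planted effects.

Ground-truth relatedness is derived by an independent exhaustive
double-loop enumeration so the network module can be checked against it.
Effect sizes are in units of ``noise_sd``; planted "more essential"
effects are negative shifts (lower score = more essential).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model_io import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    write_tabular_model,
)
from .neighbors import RelatednessMap
from .screen_data import ScreenDataset

__all__ = [
    "SyntheticConfig",
    "PlantedEffect",
    "generate_model",
    "generate_screen",
    "generate",
    "write_fixture",
]

EFFECT_KINDS = (
    "media_shift",
    "self_expression",
    "neighbor_expression",
    "isozyme_expression",
    "mutation_conditional",
    "lineage_shift",
)

MEDIA_LEVELS = ("RPMI", "DMEM", "McCoy", "HamsF12", "other")


@dataclass
class PlantedEffect:
    """One ground-truth cause of cell-line-specific essentiality.

    ``effect_size`` is in noise-SD units; positive sizes make the target
    gene more essential (more negative dependency) under the condition.
    ``condition`` is a medium label (media_shift), partner gene
    (…_expression kinds), oncogene id (mutation_conditional, with
    ``partner`` the coupled expression gene), or lineage label.
    """

    kind: str
    gene: str
    effect_size: float
    condition: str = ""
    partner: str = ""

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.effect_size == 0:
            raise ValueError("effect size must be nonzero")


@dataclass
class SyntheticConfig:
    n_reactions: int = 60
    n_metabolites: int = 40
    n_genes_metabolic: int = 60
    n_genes_other: int = 40
    n_cell_lines: int = 120
    n_hubs: int = 2
    hub_reaction_fraction: float = 0.25  # fraction of reactions each hub joins
    n_media: int = 3
    media_probs: tuple = ()  # defaults to uniform over the first n_media labels
    media_culture_confounding: float = 0.8
    adherent_fraction: float = 0.65
    n_lineages: int = 4
    n_oncogenes: int = 125
    mutation_rate: float = 0.08
    # At toy scale the realistic 1% rule would make every metabolite currency;
    # 10% keeps hubs above and ordinary metabolites below the threshold.
    currency_fraction_target: float = 0.10
    p_or_rule: float = 0.2
    p_and_rule: float = 0.15
    noise_sd: float = 1.0
    planted_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_reactions", "n_metabolites", "n_genes_metabolic",
                     "n_cell_lines", "n_media", "n_lineages", "n_oncogenes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_hubs > self.n_metabolites:
            raise ValueError("more hub metabolites than metabolites")
        if not self.media_probs:
            self.media_probs = tuple([1.0 / self.n_media] * self.n_media)
        if abs(sum(self.media_probs) - 1.0) > 1e-9:
            raise ValueError("media probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Model generation


def _truth_relatedness(model: MetabolicModel, fraction: float, cap: int = 50) -> RelatednessMap:
    """Exhaustive double-loop relatedness enumeration (oracle bookkeeping).

    Intentionally naive and independent of :mod:`metdep.neighbors`.
    """
    rxns = list(model.reactions.values())
    counts: dict[str, int] = {}
    for rxn in rxns:
        for mid in rxn.metabolite_ids():
            counts[mid] = counts.get(mid, 0) + 1
    currency = {m for m, c in counts.items() if c > fraction * len(rxns)}

    gene_mets: dict[str, set[str]] = {}
    for rxn in rxns:
        for g in rxn.genes():
            gene_mets.setdefault(g, set()).update(rxn.metabolite_ids())

    neighbors: dict[str, list[str]] = {}
    connecting: dict[tuple[str, str], str] = {}
    genes = sorted(gene_mets)
    for g in genes:
        candidates = []
        for g2 in genes:
            if g2 == g:
                continue
            shared = (gene_mets[g] & gene_mets[g2]) - currency
            if not shared:
                continue
            best_met = min(shared, key=lambda m: (counts[m], m))
            candidates.append((counts[best_met], g2, best_met))
        candidates.sort(key=lambda t: (t[0], t[1]))
        kept = candidates[:cap]
        neighbors[g] = [g2 for _, g2, _ in kept]
        for _, g2, met in kept:
            connecting[(g, g2)] = met

    isozymes: dict[str, set[str]] = {g: set() for g in genes}
    for rxn in rxns:
        tree = rxn.gpr

        def pairs(node):
            from .model_io import GprLeaf, GprOp
            if node is None or isinstance(node, GprLeaf):
                return
            sets = []
            for child in node.children:
                sets.append(child.genes())
                pairs(child)
            if node.op == "or":
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        for a in sets[i]:
                            for b in sets[j]:
                                if a != b:
                                    isozymes[a].add(b)
                                    isozymes[b].add(a)

        pairs(tree)
    return RelatednessMap(
        neighbors=neighbors, isozymes=isozymes, currency=currency,
        connecting_metabolite=connecting, cap=cap,
    )


def generate_model(config: SyntheticConfig) -> tuple[MetabolicModel, RelatednessMap]:
    """Random sparse reaction network plus its ground-truth relatedness."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_r = config.n_reactions
    n_m = config.n_metabolites
    compartments = ["c", "m"]
    met_ids = [f"met{i:03d}_{compartments[i % 2]}" for i in range(n_m)]
    hubs = met_ids[: config.n_hubs]
    non_hubs = met_ids[config.n_hubs:]
    if len(non_hubs) < 2:
        raise ValueError("infeasible config: need at least two non-hub metabolites")

    model = MetabolicModel()
    for mid in met_ids:
        model.metabolites[mid] = Metabolite(id=mid, compartment=mid.rsplit("_", 1)[1])

    genes = [f"G{i:04d}" for i in range(config.n_genes_metabolic)]
    # each hub joins enough reactions to exceed the currency threshold
    hub_hits = max(int(np.ceil(config.hub_reaction_fraction * n_r)),
                   int(np.floor(config.currency_fraction_target * n_r)) + 2)
    hub_rxns = {h: set(rng.choice(n_r, size=min(hub_hits, n_r), replace=False)) for h in hubs}

    for i in range(n_r):
        rid = f"R{i:04d}"
        sub, prod = rng.choice(len(non_hubs), size=2, replace=False)
        substrates = [(non_hubs[sub], 1.0)]
        products = [(non_hubs[prod], 1.0)]
        for h in hubs:
            if i in hub_rxns[h]:
                substrates.append((h, 1.0))
        u = rng.random()
        if u < config.p_or_rule and len(genes) >= 2:
            g1, g2 = rng.choice(len(genes), size=2, replace=False)
            rule = f"{genes[g1]} or {genes[g2]}"
        elif u < config.p_or_rule + config.p_and_rule and len(genes) >= 2:
            g1, g2 = rng.choice(len(genes), size=2, replace=False)
            rule = f"{genes[g1]} and {genes[g2]}"
        else:
            rule = genes[int(rng.integers(0, len(genes)))]
        model.reactions[rid] = Reaction(
            id=rid, substrates=tuple(substrates), products=tuple(products),
            reversible=bool(rng.random() < 0.5), gpr=parse_gpr(rule),
        )
    model.validate()
    truth = _truth_relatedness(model, config.currency_fraction_target)
    return model, truth


# ---------------------------------------------------------------------------
# Screen generation


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def generate_screen(
    config: SyntheticConfig,
    model: MetabolicModel,
    truth: RelatednessMap,
) -> tuple[ScreenDataset, dict]:
    """Simulate the five screen matrices plus a ground-truth effect registry."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_lines = config.n_cell_lines
    lines = [f"CL{i:04d}" for i in range(n_lines)]
    met_genes = sorted(model.genes)
    other_genes = [f"NG{i:04d}" for i in range(config.n_genes_other)]
    all_genes = met_genes + other_genes

    # annotations: culture type, then media conditioned on culture type
    adherent = rng.random(n_lines) < config.adherent_fraction
    media_levels = list(MEDIA_LEVELS[: config.n_media])
    media = np.array([
        rng.choice(media_levels, p=config.media_probs) for _ in range(n_lines)
    ], dtype=object)
    if "DMEM" in media_levels and "RPMI" in media_levels:
        confound = rng.random(n_lines) < config.media_culture_confounding
        media[confound & adherent] = "DMEM"
        media[confound & ~adherent] = "RPMI"
    lineage_levels = [f"lineage{i}" for i in range(config.n_lineages)]
    lineage_probs = np.asarray(
        [2.0 ** -(i + 1) for i in range(config.n_lineages)], dtype=float
    )
    lineage_probs /= lineage_probs.sum()  # skewed so small lineages (< 10 lines) occur
    lineage = rng.choice(lineage_levels, size=n_lines, p=lineage_probs)
    annotations = pd.DataFrame(
        {
            "medium": media,
            "culture_type": np.where(adherent, "adherent", "suspension"),
            "lineage": lineage,
        },
        index=pd.Index(lines, name="cell_line"),
    )

    # molecular matrices
    expr_mu = rng.normal(5.0, 1.0, size=len(all_genes))
    expression = pd.DataFrame(
        rng.normal(expr_mu[:, None], 1.0, size=(len(all_genes), n_lines)),
        index=all_genes, columns=lines,
    )
    cnv = pd.DataFrame(
        rng.normal(1.0, 0.1, size=(len(all_genes), n_lines)),
        index=all_genes, columns=lines,
    )
    amp = rng.random(cnv.shape) < 0.02
    cnv = cnv.where(~amp, cnv + rng.uniform(1.0, 3.0, size=cnv.shape))

    oncogenes = [f"ONC{i:03d}" for i in range(config.n_oncogenes)]
    mutations = pd.DataFrame(
        (rng.random((len(oncogenes), n_lines)) < config.mutation_rate).astype(float),
        index=oncogenes, columns=lines,
    )

    dependency = pd.DataFrame(
        rng.normal(0.0, config.noise_sd, size=(len(all_genes), n_lines)),
        index=all_genes, columns=lines,
    )

    registry: dict = {"seed": config.seed, "noise_sd": config.noise_sd, "effects": []}
    for eff in config.planted_effects:
        if eff.gene not in dependency.index:
            raise ValueError(f"planted effect targets unknown gene {eff.gene!r}")
        beta = eff.effect_size * config.noise_sd
        row = dependency.loc[eff.gene].to_numpy()
        if eff.kind == "media_shift":
            if eff.condition not in media_levels:
                raise ValueError(f"unknown medium {eff.condition!r} for planted effect")
            mask = media == eff.condition
            row[mask] -= beta
        elif eff.kind == "lineage_shift":
            if eff.condition not in lineage_levels:
                raise ValueError(f"unknown lineage {eff.condition!r} for planted effect")
            row[lineage == eff.condition] -= beta
        elif eff.kind in ("self_expression", "neighbor_expression", "isozyme_expression"):
            partner = eff.partner or (eff.gene if eff.kind == "self_expression" else "")
            if eff.kind == "neighbor_expression" and partner not in truth.neighbors.get(eff.gene, []):
                raise ValueError(
                    f"planted partner {partner!r} is not a ground-truth neighbor of {eff.gene!r}"
                )
            if eff.kind == "isozyme_expression" and partner not in truth.isozymes.get(eff.gene, set()):
                raise ValueError(
                    f"planted partner {partner!r} is not a ground-truth isozyme of {eff.gene!r}"
                )
            z = _standardize(expression.loc[partner].to_numpy())
            row -= beta * z
        elif eff.kind == "mutation_conditional":
            if eff.condition not in mutations.index:
                raise ValueError(f"unknown oncogene {eff.condition!r} for planted effect")
            partner = eff.partner or eff.gene
            z = _standardize(expression.loc[partner].to_numpy())
            row -= beta * z * mutations.loc[eff.condition].to_numpy()
        dependency.loc[eff.gene] = row
        registry["effects"].append(asdict(eff))

    dataset = ScreenDataset(
        dependency=dependency, expression=expression, cnv=cnv,
        mutations=mutations, annotations=annotations,
        metabolic_genes=set(met_genes),
    )
    dataset.validate()
    return dataset, registry


def generate(config: SyntheticConfig):
    """Generate model, ground-truth relatedness, screen dataset and registry."""
    model, truth = generate_model(config)
    dataset, registry = generate_screen(config, model, truth)
    return model, truth, dataset, registry


# ---------------------------------------------------------------------------
# Fixture writer


def write_fixture(dataset: ScreenDataset, model: MetabolicModel, outdir: str,
                  registry: dict | None = None) -> dict[str, str]:
    """Write the tabular model plus the five screen files (all relative paths)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reactions": os.path.join(outdir, "reactions.tsv"),
        "gpr": os.path.join(outdir, "gpr.tsv"),
        "dependency": os.path.join(outdir, "dependency.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "cnv": os.path.join(outdir, "cnv.tsv"),
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
    }
    write_tabular_model(model, paths["reactions"], paths["gpr"])
    float_fmt = "%.10g"
    dataset.dependency.to_csv(paths["dependency"], sep="\t", float_format=float_fmt)
    dataset.expression.to_csv(paths["expression"], sep="\t", float_format=float_fmt)
    dataset.cnv.to_csv(paths["cnv"], sep="\t", float_format=float_fmt)
    dataset.mutations.to_csv(paths["mutations"], sep="\t", float_format="%.0f")
    ann = dataset.annotations.copy()
    ann.index.name = "cell_line"
    ann.to_csv(paths["annotations"], sep="\t")
    if registry is not None:
        paths["registry"] = os.path.join(outdir, "truth.json")
        with open(paths["registry"], "w", encoding="utf-8") as fh:
            json.dump(registry, fh, indent=2, sort_keys=True)
    return paths
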