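"""Pipeline configuration, orchestration and report assembly."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import association, models, neighbors, screen_data
from .model_io import read_sbml, read_tabular_model

__all__ = ["PipelineConfig", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative record of every pipeline knob.

    The three variability thresholds are stage-specific on purpose
    (k_media=6, k_pairwise=4, k_modeling=2) — one config record guards
    against silently mixing them up.
    """

    # inputs
    model_sbml: str = ""
    model_reactions: str = ""
    model_gpr: str = ""
    dependency: str = ""
    expression: str = ""
    cnv: str = ""
    mutations: str = ""
    annotations: str = ""
    # stage toggles
    media_analysis: bool = True
    correlation_analysis: bool = True
    modeling: bool = True
    # thresholds
    k_media: float = 6.0
    k_pairwise: float = 4.0
    k_modeling: float = 2.0
    currency_fraction: float = 0.01
    neighbor_cap: int = 50
    exclude_genes: list = field(default_factory=lambda: ["EGFR", "PIK"])
    drop_exchange: bool = False
    media_pair: list = field(default_factory=lambda: ["DMEM", "RPMI"])
    fdr_threshold: float = 0.05
    lineage_min: int = 10
    # repetitions
    shuffled_set_reps: int = 1000
    permutation_null_reps: int = 25000
    shuffled_related_reps: int = 100
    # forest
    n_trees: int = 100
    min_leaf: int = 5
    min_lines: int = 30
    include_lineage: bool = False
    include_oncogene_cnv: bool = False
    # run control
    seed: int = 0
    threads: int = 1
    out_dir: str = "metdep_out"

    def __post_init__(self):
        for name in ("k_media", "k_pairwise", "k_modeling", "currency_fraction",
                     "fdr_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.neighbor_cap < 1 or self.lineage_min < 1 or self.threads < 1:
            raise ValueError("neighbor_cap, lineage_min and threads must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_model(config: PipelineConfig):
    if config.model_sbml:
        return read_sbml(config.model_sbml)
    if config.model_reactions and config.model_gpr:
        return read_tabular_model(config.model_reactions, config.model_gpr)
    raise ValueError("config must name either model_sbml or model_reactions + model_gpr")


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute model_io -> neighbors -> screen_data -> associations -> models.

    Writes every stage output under ``config.out_dir`` plus a run manifest.
    A failure in one stage raises with the stage name; outputs of completed
    stages are preserved on disk.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
        "outputs": [],
    }
    alpha = config.fdr_threshold
    medium_a, medium_b = config.media_pair

    def out(name: str) -> str:
        manifest["outputs"].append(name)
        return os.path.join(config.out_dir, name)

    def stage(name: str):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

        return done

    try:
        done = stage("relatedness")
        model = _load_model(config)
        relmap = neighbors.build_relatedness(
            model,
            currency_fraction=config.currency_fraction,
            cap=config.neighbor_cap,
            exclude=frozenset(config.exclude_genes),
            drop_exchange=config.drop_exchange,
        )
        neighbors.write_relatedness_tsv(relmap, model, out("relatedness.tsv"))
        neighbors.write_gmt(relmap, out("neighbors.gmt"), mode="neighbor")
        neighbors.write_gmt(relmap, out("isozymes.gmt"), mode="isozyme")
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'relatedness' failed: {exc}") from exc

    try:
        done = stage("screen_data")
        dataset = screen_data.load_screen(
            config.dependency, config.expression, config.cnv,
            config.mutations, config.annotations,
            metabolic_genes=set(model.genes),
        )
        done()
    except Exception as exc:
        raise RuntimeError(f"stage 'screen_data' failed: {exc}") from exc

    summary: dict = {"seed": config.seed}

    if config.media_analysis:
        try:
            done = stage("media_analysis")
            genes6 = screen_data.variability_filter(dataset.dependency, config.k_media)
            results = association.media_association(
                dataset, sorted(genes6), medium_a, medium_b
            )
            _write_tsv(results, out("media_association.tsv"))
            met = results[results["gene"].isin(dataset.metabolic_genes)]
            non = results[~results["gene"].isin(dataset.metabolic_genes)]
            stat, p = association.compare_pvalue_distributions(
                met["fdr_p"].dropna(), non["fdr_p"].dropna()
            )
            met_genes6 = sorted(genes6 & dataset.metabolic_genes)
            partial = association.media_partial_association(
                dataset, met_genes6, medium_a, medium_b, control="culture_type"
            )
            _write_tsv(partial, out("media_partial_culture.tsv"))
            lineage_tbl, robust = association.lineage_robustness_table(
                dataset, met_genes6, medium_a, medium_b,
                min_lineage=config.lineage_min, alpha=alpha,
            )
            _write_tsv(lineage_tbl, out("media_partial_lineage.tsv"))
            robust.rename("lineage_robust").reset_index().to_csv(
                out("media_lineage_robustness.tsv"), sep="\t", index=False
            )
            summary["media"] = {
                "n_tested_metabolic": int(len(met)),
                "n_tested_non_metabolic": int(len(non)),
                "n_significant_metabolic": int((met["fdr_p"] < alpha).sum()),
                "n_significant_non_metabolic": int((non["fdr_p"] < alpha).sum()),
                "metabolic_vs_other_pvalue": p,
                "n_lineage_robust": int(robust.sum()),
            }
            done()
        except Exception as exc:
            raise RuntimeError(f"stage 'media_analysis' failed: {exc}") from exc

    if config.correlation_analysis:
        try:
            done = stage("correlation_analysis")
            genes4 = sorted(
                screen_data.variability_filter(dataset.dependency, config.k_pairwise)
                & dataset.metabolic_genes
            )
            summary["correlations"] = {"n_genes": len(genes4)}
            for i, mode in enumerate(("self", "isozyme", "neighbor")):
                table, explained = association.related_expression_correlations(
                    dataset, relmap, mode, genes=genes4, alpha=alpha
                )
                _write_tsv(table, out(f"expr_{mode}.tsv"))
                frac_neg, sign_p = association.sign_fraction_test(table, alpha=alpha)
                null = association.shuffled_set_null(
                    dataset, relmap, mode,
                    repetitions=config.shuffled_set_reps,
                    seed=config.seed + 101 + i, genes=genes4, alpha=alpha,
                )
                with open(out(f"expr_{mode}_null.json"), "w", encoding="utf-8") as fh:
                    json.dump(null.to_dict(), fh, indent=2)
                summary["correlations"][mode] = {
                    "fraction_explained": float(explained.mean()) if len(explained) else float("nan"),
                    "shuffled_set_empirical_p": null.empirical_p,
                    "fraction_negative": frac_neg,
                    "sign_binomial_p": sign_p,
                }
            done()
        except Exception as exc:
            raise RuntimeError(f"stage 'correlation_analysis' failed: {exc}") from exc

    if config.modeling:
        try:
            done = stage("modeling")
            genes2 = sorted(
                screen_data.variability_filter(dataset.dependency, config.k_modeling)
                & dataset.metabolic_genes
            )
            fitted = models.fit_models(
                dataset, relmap, genes2,
                seed=config.seed + 201, threads=config.threads,
                n_trees=config.n_trees, min_leaf=config.min_leaf,
                include_lineage=config.include_lineage,
                min_lineage=config.lineage_min, min_lines=config.min_lines,
                include_oncogene_cnv=config.include_oncogene_cnv,
            )
            null_ps = models.permutation_null(
                dataset, relmap, genes2,
                repetitions=config.permutation_null_reps,
                seed=config.seed + 202,
                n_trees=config.n_trees, min_leaf=config.min_leaf,
                include_lineage=config.include_lineage,
                min_lineage=config.lineage_min, min_lines=config.min_lines,
                include_oncogene_cnv=config.include_oncogene_cnv,
            )
            np.savetxt(out("permutation_null_pvalues.tsv"), null_ps, fmt="%.10g")
            models.empirical_significance(fitted, null_ps, alpha=alpha)
            table = models.models_to_table(fitted)
            _write_tsv(table, out("models.tsv"))
            _write_tsv(models.categorize_top_features(fitted), out("feature_categories.tsv"))
            control = models.shuffled_related_control(
                dataset, relmap, genes2, null_ps,
                repetitions=config.shuffled_related_reps,
                seed=config.seed + 203, alpha=alpha, threads=config.threads,
                n_trees=config.n_trees, min_leaf=config.min_leaf,
                include_lineage=config.include_lineage,
                min_lineage=config.lineage_min, min_lines=config.min_lines,
            )
            n_sig = int(sum(m.significant for m in fitted))
            observed_fraction = n_sig / len(fitted) if fitted else float("nan")
            with open(out("shuffled_related_control.json"), "w", encoding="utf-8") as fh:
                json.dump(
                    {"observed_fraction": observed_fraction, "control_fractions": control},
                    fh, indent=2,
                )
            mean_spearman = (
                float(np.nanmean([m.oob_spearman_r for m in fitted if m.significant]))
                if n_sig else float("nan")
            )
            summary["models"] = {
                "n_modeled": len(fitted),
                "n_significant": n_sig,
                "fraction_significant": observed_fraction,
                "mean_oob_spearman_significant": mean_spearman,
            }
            done()
        except Exception as exc:
            raise RuntimeError(f"stage 'modeling' failed: {exc}") from exc

    manifest["summary"] = summary
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize(out_dir: str) -> str:
    """Assemble a human-readable markdown summary from a run's output files."""
    lines = ["# metdep run summary", ""]
    manifest_path = os.path.join(out_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        return "\n".join(lines + ["No manifest found — run the pipeline first."])
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    summary = manifest.get("summary", {})
    lines.append(f"- seed: {summary.get('seed')}")
    lines.append(f"- package version: {manifest.get('version')}")
    lines.append("")

    media = summary.get("media")
    if media:
        lines.append("## Media association")
        n_met, s_met = media["n_tested_metabolic"], media["n_significant_metabolic"]
        n_non, s_non = media["n_tested_non_metabolic"], media["n_significant_non_metabolic"]
        lines.append(f"- metabolic genes significant: {s_met}/{n_met}")
        lines.append(f"- non-metabolic genes significant: {s_non}/{n_non}")
        lines.append(f"- metabolic vs non-metabolic p-value distribution test p = "
                     f"{media['metabolic_vs_other_pvalue']:.3g}")
        lines.append(f"- genes robust to lineage control: {media['n_lineage_robust']}")
        lines.append("- table: media_association.tsv")
        lines.append("")
    else:
        lines.append("## Media association: not run\n")

    corr = summary.get("correlations")
    if corr:
        lines.append("## Dependency vs related-gene expression")
        lines.append(f"- genes analyzed: {corr['n_genes']}")
        for mode in ("self", "isozyme", "neighbor"):
            if mode in corr:
                c = corr[mode]
                lines.append(
                    f"- {mode}: explained fraction {c['fraction_explained']:.3f}, "
                    f"shuffled-set empirical p {c['shuffled_set_empirical_p']:.4g}, "
                    f"negative fraction {c['fraction_negative']:.3f} "
                    f"(binomial p {c['sign_binomial_p']:.3g})"
                )
        lines.append("- tables: expr_self.tsv, expr_isozyme.tsv, expr_neighbor.tsv")
        lines.append("")
    else:
        lines.append("## Correlation analysis: not run\n")

    mod = summary.get("models")
    if mod:
        lines.append("## Predictive models")
        lines.append(f"- significant models: {mod['n_significant']}/{mod['n_modeled']} "
                     f"({100 * mod['fraction_significant']:.1f}%)")
        lines.append(f"- mean OOB Spearman of significant models: "
                     f"{mod['mean_oob_spearman_significant']:.3f}")
        cat_path = os.path.join(out_dir, "feature_categories.tsv")
        if os.path.exists(cat_path):
            cats = pd.read_csv(cat_path, sep="\t")
            cats = cats[cats["kind"] == "category"]
            for row in cats.itertuples(index=False):
                lines.append(f"- {row.name}: top {100 * row.fraction_top:.1f}%, "
                             f"top-5 {100 * row.fraction_top5:.1f}%")
        lines.append("- tables: models.tsv, feature_categories.tsv")
        lines.append("")
    else:
        lines.append("## Modeling: not run\n")
    return "\n".join(lines)
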