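"""Association statistics for screen analyses.

Kernels: two-sided Wilcoxon rank-sum, Spearman and partial Spearman
correlation on ranks, Benjamini-Hochberg FDR, exact binomial sign test,
and shuffled-gene-set permutation nulls.  Higher-level drivers implement
the per-gene media association (with culture-type / lineage confounder
controls) and the dependency-vs-related-gene-expression analysis.

Conventions: all tests two-sided; ties get average ranks; empirical
permutation p-values use the add-one estimator (1 + hits) / (1 + reps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationError",
    "NullSummary",
    "bh_fdr",
    "rank_sum_test",
    "spearman",
    "partial_spearman",
    "media_association",
    "media_partial_association",
    "lineage_robustness",
    "lineage_robustness_table",
    "related_expression_correlations",
    "shuffled_set_null",
    "sign_fraction_test",
    "compare_pvalue_distributions",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene", "test", "partner", "statistic", "direction", "p", "fdr_p"]


class AssociationError(ValueError):
    pass


@dataclass
class NullSummary:
    """Observed statistic versus a shuffled-set permutation null."""

    observed_fraction: float
    null_fractions: list[float] = field(default_factory=list)
    empirical_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "observed_fraction": self.observed_fraction,
            "null_fractions": list(self.null_fractions),
            "empirical_p": self.empirical_p,
        }


# ---------------------------------------------------------------------------
# Kernels


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise AssociationError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adjusted
    out[mask] = res
    return out


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with tie correction (no
    continuity correction, so identical samples give p = 1).
    Returns ``(U statistic of a, two-sided p)``; groups with fewer than 3
    values give ``(nan, nan)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        return (float("nan"), float("nan"))
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return (float(res.statistic), float(res.pvalue))


def compare_pvalue_distributions(group_a, group_b) -> tuple[float, float]:
    """Rank-sum comparison of two p-value collections (delegates to rank_sum_test)."""
    return rank_sum_test(group_a, group_b)


def _complete(*arrays):
    mats = [np.asarray(a, dtype=float) for a in arrays]
    mask = ~np.any([np.isnan(m) for m in mats], axis=0)
    return [m[mask] for m in mats]


def spearman(x, y, min_pairs: int = 5) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Pairs with a missing value in either vector are dropped; fewer than
    ``min_pairs`` complete pairs gives ``(nan, nan)``.
    """
    x, y = _complete(x, y)
    n = x.size
    if n < min_pairs:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return (float("nan"), float("nan"))
    r = float(np.corrcoef(rx, ry)[0, 1])
    return (r, _t_pvalue(r, n - 2))


def _t_pvalue(r: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def partial_spearman(x, y, z, min_pairs: int = 5) -> tuple[float, float]:
    """Spearman partial correlation of x and y controlling for z.

    Ranks all three vectors (average ties) and applies the first-order
    partial-correlation formula; p from a t distribution with n - 3
    degrees of freedom.  Degenerate cases (|r_xz| or |r_yz| = 1, or a
    constant vector) return ``(nan, nan)``.
    """
    x, y, z = _complete(x, y, z)
    n = x.size
    if n < max(min_pairs, 4):
        return (float("nan"), float("nan"))
    rx, ry, rz = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    if min(np.ptp(rx), np.ptp(ry), np.ptp(rz)) == 0:
        return (float("nan"), float("nan"))
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom_sq = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
    if denom_sq <= 1e-14:
        return (float("nan"), float("nan"))
    r = float((rxy - rxz * ryz) / np.sqrt(denom_sq))
    return (r, _t_pvalue(r, n - 3))


def sign_fraction_test(results: pd.DataFrame, alpha: float = 0.05) -> tuple[float, float]:
    """Fraction of negative directions among significant correlations.

    Two-sided exact binomial test of the number of negative directions at
    success probability 0.5.  Returns ``(fraction_negative, p)``; with no
    significant results, ``(nan, nan)``.
    """
    sig = results[(results["fdr_p"] < alpha) & results["direction"].isin([-1, 1])]
    n = len(sig)
    if n == 0:
        return (float("nan"), float("nan"))
    k_neg = int((sig["direction"] == -1).sum())
    p = float(stats.binomtest(k_neg, n, 0.5, alternative="two-sided").pvalue)
    return (k_neg / n, p)


# ---------------------------------------------------------------------------
# Media association analysis


def media_association(
    dataset,
    genes,
    medium_a: str,
    medium_b: str,
    min_per_group: int = 3,
    split_by_metabolic: bool = True,
) -> pd.DataFrame:
    """Per-gene rank-sum test of dependency scores between two media.

    direction = +1 when the gene is more essential (lower median score) in
    ``medium_a``, -1 in ``medium_b``, 0 when tied.  BH-FDR is applied
    within metabolic and within non-metabolic genes separately when
    ``split_by_metabolic`` (families reported separately downstream).
    """
    media = dataset.annotations["medium"]
    for medium in (medium_a, medium_b):
        if medium not in set(media):
            raise AssociationError(f"unknown medium label {medium!r}")
    lines_a = media.index[media == medium_a]
    lines_b = media.index[media == medium_b]
    genes = [g for g in genes if g in dataset.dependency.index]

    rows = []
    for gene in genes:
        a = dataset.dependency.loc[gene, lines_a].to_numpy(dtype=float)
        b = dataset.dependency.loc[gene, lines_b].to_numpy(dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < min_per_group or b.size < min_per_group:
            stat, p, direction = float("nan"), float("nan"), 0
        else:
            stat, p = rank_sum_test(a, b)
            med_a, med_b = np.median(a), np.median(b)
            direction = +1 if med_a < med_b else (-1 if med_b < med_a else 0)
        rows.append((gene, "media_wilcoxon", "", stat, direction, p, np.nan))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    if split_by_metabolic and dataset.metabolic_genes:
        is_met = out["gene"].isin(dataset.metabolic_genes)
        for mask in (is_met, ~is_met):
            if mask.any():
                out.loc[mask, "fdr_p"] = bh_fdr(out.loc[mask, "p"])
    else:
        out["fdr_p"] = bh_fdr(out["p"])
    return out


def media_partial_association(
    dataset,
    genes,
    medium_a: str,
    medium_b: str,
    control: str = "culture_type",
) -> pd.DataFrame:
    """Partial Spearman of dependency vs a binary media vector, controlling a covariate.

    ``control`` is ``"culture_type"`` (binary adherent/suspension vector) or
    the name of a lineage (0/1 indicator).  Restricted to cell lines grown
    in either medium.  BH-FDR across the tested genes.
    """
    indicator = dataset.media_indicator(medium_a, medium_b)
    lines = list(indicator.index)
    if control == "culture_type":
        ct = dataset.annotations.loc[lines, "culture_type"]
        levels = sorted(ct.unique())
        z = (ct == levels[0]).astype(float).to_numpy()
        test_name = "partial_media_culture"
    else:
        z = (dataset.annotations.loc[lines, "lineage"] == control).astype(float).to_numpy()
        test_name = "partial_media_lineage"

    degenerate_control = np.ptp(z) == 0
    media_vec = indicator.to_numpy()
    rows = []
    for gene in genes:
        if gene not in dataset.dependency.index:
            continue
        y = dataset.dependency.loc[gene, lines].to_numpy(dtype=float)
        if degenerate_control:
            # cannot control with a constant covariate: fall back to plain Spearman
            r, p = spearman(y, media_vec)
        else:
            r, p = partial_spearman(y, media_vec, z)
        direction = 0 if np.isnan(r) else (+1 if r < 0 else -1 if r > 0 else 0)
        rows.append((gene, test_name, control, r, direction, p, np.nan))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["fdr_p"] = bh_fdr(out["p"])
    return out


def lineage_robustness_table(
    dataset,
    genes,
    medium_a: str,
    medium_b: str,
    min_lineage: int = 10,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Media association robustness to lineage confounding.

    For every lineage with >= ``min_lineage`` cell lines, the dependency /
    media partial Spearman is recomputed controlling for that lineage's
    indicator, with BH-FDR across genes per lineage.  A gene is robust iff
    it stays significant under every qualifying lineage control.  With no
    qualifying lineage, all genes are vacuously robust (logged).
    """
    genes = [g for g in genes if g in dataset.dependency.index]
    lineages = dataset.lineage_indicators(min_lines=min_lineage)
    if not lineages:
        log.info("no lineage with >= %d cell lines; robustness vacuously true", min_lineage)
        verdict = pd.Series(True, index=pd.Index(genes, name="gene"))
        return pd.DataFrame(columns=RESULT_COLUMNS), verdict

    tables = []
    verdict = pd.Series(True, index=pd.Index(genes, name="gene"))
    for lineage in sorted(lineages):
        table = media_partial_association(
            dataset, genes, medium_a, medium_b, control=lineage
        )
        tables.append(table)
        sig = table.set_index("gene")["fdr_p"] < alpha
        verdict &= sig.reindex(verdict.index).fillna(False).astype(bool)
    return pd.concat(tables, ignore_index=True), verdict


def lineage_robustness(
    dataset, gene: str, medium_a: str, medium_b: str,
    genes=None, min_lineage: int = 10, alpha: float = 0.05,
) -> bool:
    """Single-gene view of :func:`lineage_robustness_table`.

    ``genes`` is the FDR family (defaults to all metabolic genes in the
    dependency matrix, or all genes when no metabolic set is recorded).
    """
    if genes is None:
        genes = sorted(dataset.metabolic_genes) or list(dataset.dependency.index)
    if gene not in genes:
        genes = list(genes) + [gene]
    _, verdict = lineage_robustness_table(
        dataset, genes, medium_a, medium_b, min_lineage=min_lineage, alpha=alpha
    )
    return bool(verdict.loc[gene])


# ---------------------------------------------------------------------------
# Dependency vs expression of functionally related genes


class _PairCorrEngine:
    """Spearman correlations for many (dependency row, expression row) pairs.

    When both matrices are NaN-free the rank transforms are precomputed
    once and each pair costs a dot product; otherwise pairs fall back to
    the generic pairwise-complete kernel.
    """

    def __init__(self, dependency: pd.DataFrame, expression: pd.DataFrame):
        self.dependency = dependency
        self.expression = expression
        self.n = dependency.shape[1]
        dep_ok = not np.isnan(dependency.to_numpy()).any()
        expr_ok = not np.isnan(expression.to_numpy()).any()
        self.fast = dep_ok and expr_ok and self.n >= 5
        if self.fast:
            self._dep_z = self._rank_standardize(dependency)
            self._expr_z = self._rank_standardize(expression)

    @staticmethod
    def _rank_standardize(df: pd.DataFrame) -> dict[str, np.ndarray | None]:
        values = df.to_numpy(dtype=float)
        ranks = stats.rankdata(values, axis=1)
        sd = ranks.std(axis=1)
        mean = ranks.mean(axis=1, keepdims=True)
        out: dict[str, np.ndarray | None] = {}
        for i, gene in enumerate(df.index):
            out[gene] = None if sd[i] == 0 else (ranks[i] - mean[i]) / sd[i]
        return out

    def corr(self, gene: str, partner: str) -> tuple[float, float]:
        if self.fast:
            zx = self._dep_z.get(gene)
            zy = self._expr_z.get(partner)
            if zx is None or zy is None:
                return (float("nan"), float("nan"))
            r = float(zx @ zy / self.n)
            return (r, _t_pvalue(r, self.n - 2))
        return spearman(
            self.dependency.loc[gene].to_numpy(dtype=float),
            self.expression.loc[partner].to_numpy(dtype=float),
        )


def _partner_sets(relatedness, mode: str, genes) -> dict[str, list[str]]:
    if mode == "self":
        return {g: [g] for g in genes}
    if mode == "isozyme":
        return {g: sorted(relatedness.isozymes.get(g, ())) for g in genes}
    if mode == "neighbor":
        return {g: list(relatedness.neighbors.get(g, [])) for g in genes}
    raise ValueError(f"unknown mode {mode!r}")


def related_expression_correlations(
    dataset,
    relatedness,
    mode: str,
    genes=None,
    alpha: float = 0.05,
    _engine: _PairCorrEngine | None = None,
    _partners: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlations between dependency and related-gene expression.

    ``mode``: ``self`` (own expression), ``isozyme`` or ``neighbor`` (one
    correlation per gene/partner pair).  BH-FDR across all tested pairs of
    the call.  Returns ``(pair table, explained)`` where ``explained[g]``
    is True iff any of g's partners is significant at ``alpha`` after FDR.
    Partners without an expression row are skipped (logged).
    """
    if genes is None:
        genes = sorted(dataset.metabolic_genes & set(dataset.dependency.index))
    genes = [g for g in genes if g in dataset.dependency.index]
    engine = _engine or _PairCorrEngine(dataset.dependency, dataset.expression)
    partners = _partners or _partner_sets(relatedness, mode, genes)

    expr_genes = set(dataset.expression.index)
    rows = []
    skipped = 0
    for gene in genes:
        for partner in partners.get(gene, []):
            if partner not in expr_genes:
                skipped += 1
                continue
            r, p = engine.corr(gene, partner)
            direction = 0 if np.isnan(r) else (+1 if r > 0 else -1 if r < 0 else 0)
            rows.append((gene, f"expr_{mode}", partner, r, direction, p, np.nan))
    if skipped:
        log.info("%s mode: skipped %d pairs without expression data", mode, skipped)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(out):
        out["fdr_p"] = bh_fdr(out["p"])
    sig = out[out["fdr_p"] < alpha]
    explained = pd.Series(False, index=pd.Index(genes, name="gene"))
    for gene in sig["gene"].unique():
        explained.loc[gene] = True
    return out, explained


def shuffled_set_null(
    dataset,
    relatedness,
    mode: str,
    repetitions: int = 1000,
    seed: int = 0,
    genes=None,
    alpha: float = 0.05,
) -> NullSummary:
    """Shuffled-partner-set permutation null for the explained-gene fraction.

    Each repetition replaces every gene's partner set with a uniformly
    random, equally sized set of expression-measured genes (excluding the
    gene itself), recomputes the fraction of genes explained, and the
    empirical p is the add-one upper tail of the observed fraction.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if genes is None:
        genes = sorted(dataset.metabolic_genes & set(dataset.dependency.index))
    genes = [g for g in genes if g in dataset.dependency.index]
    engine = _PairCorrEngine(dataset.dependency, dataset.expression)
    partners = _partner_sets(relatedness, mode, genes)

    _, explained = related_expression_correlations(
        dataset, relatedness, mode, genes=genes, alpha=alpha,
        _engine=engine, _partners=partners,
    )
    observed = float(explained.mean()) if len(explained) else float("nan")
    if np.isnan(observed):
        return NullSummary(observed, [], float("nan"))

    pool = np.array(sorted(dataset.expression.index))
    rng = np.random.default_rng(seed)
    null_fractions = []
    for _ in range(repetitions):
        shuffled: dict[str, list[str]] = {}
        for gene in genes:
            size = len(partners.get(gene, []))
            if size == 0:
                shuffled[gene] = []
                continue
            candidates = pool[pool != gene]
            shuffled[gene] = list(rng.choice(candidates, size=size, replace=False))
        _, expl = related_expression_correlations(
            dataset, relatedness, mode, genes=genes, alpha=alpha,
            _engine=engine, _partners=shuffled,
        )
        null_fractions.append(float(expl.mean()) if len(expl) else float("nan"))

    hits = sum(1 for f in null_fractions if f >= observed)
    empirical_p = (1 + hits) / (repetitions + 1)
    return NullSummary(observed, null_fractions, empirical_p)
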