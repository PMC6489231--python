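"""Per-gene predictive models of dependency scores.

Each modeled gene gets a bagged ensemble of regression trees (default 100
trees, min leaf 5, one-third of features per split) over molecular,
media and lineage features.  Goodness of fit is the Pearson correlation
between out-of-bag predictions and observed scores; statistical
significance is calibrated against a permutation null (random gene,
shuffled dependency vector, same modeling procedure), with BH-FDR across
modeled genes.  Feature importance is the out-of-bag permutation increase
in squared error, averaged over trees and divided by its standard
deviation across trees; positive-importance features are kept and the
model refit on them.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .association import bh_fdr

__all__ = [
    "FEATURE_CATEGORIES",
    "ModelingError",
    "BaggedForest",
    "DependencyModel",
    "assemble_features",
    "fit_forest",
    "oob_goodness_of_fit",
    "model_gene",
    "fit_models",
    "permutation_null",
    "empirical_significance",
    "importance_and_refit",
    "shuffled_related_control",
    "categorize_top_features",
    "models_to_table",
]

log = logging.getLogger(__name__)

FEATURE_CATEGORIES = (
    "self_exp", "self_cnv", "iso_exp", "iso_cnv",
    "related_exp", "related_cnv", "mutation", "media", "lineage",
)


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bagged regression forest with explicit out-of-bag structure


class BaggedForest:
    """Bootstrap-aggregated regression trees with per-tree OOB bookkeeping.

    A deliberately small implementation so that out-of-bag predictions and
    out-of-bag permutation importance are fully deterministic given the
    seed, independent of thread count.
    """

    def __init__(self, n_trees: int = 100, min_leaf: int = 5,
                 max_features: float = 1.0 / 3.0, seed: int = 0):
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.max_features = max_features
        self.seed = seed
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []
        self.n_samples = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        self.n_samples = n
        rng = np.random.default_rng(self.seed)
        self.trees = []
        self.oob_masks = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, n)
            mask = np.ones(n, dtype=bool)
            mask[idx] = False  # True = out of bag
            tree = DecisionTreeRegressor(
                min_samples_leaf=self.min_leaf,
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(mask)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.zeros(len(X))
        for tree in self.trees:
            preds += tree.predict(X)
        return preds / len(self.trees)

    def oob_prediction(self, X: np.ndarray) -> np.ndarray:
        """Mean prediction per sample over trees that left it out of the bag.

        Samples in every bag get NaN (excluded from scoring, logged by the
        caller).
        """
        X = np.asarray(X, dtype=float)
        total = np.zeros(self.n_samples)
        count = np.zeros(self.n_samples)
        for tree, mask in zip(self.trees, self.oob_masks):
            if mask.any():
                total[mask] += tree.predict(X[mask])
                count[mask] += 1
        out = np.full(self.n_samples, np.nan)
        scored = count > 0
        out[scored] = total[scored] / count[scored]
        return out

    def oob_importance(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> np.ndarray:
        """OOB permutation importance per feature.

        For every tree: squared-error increase on its OOB samples after
        permuting one feature column, relative to the unpermuted baseline.
        Importance = mean over trees / standard deviation over trees (the
        raw mean when the spread is zero).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n_features = X.shape[1]
        rng = np.random.default_rng(seed)
        deltas = np.zeros((len(self.trees), n_features))
        for t, (tree, mask) in enumerate(zip(self.trees, self.oob_masks)):
            if not mask.any():
                continue
            X_oob = X[mask]
            y_oob = y[mask]
            baseline = np.mean((tree.predict(X_oob) - y_oob) ** 2)
            m = len(y_oob)
            # one batched predict over all per-feature permuted copies
            stacked = np.broadcast_to(X_oob, (n_features, m, n_features)).copy()
            for f in range(n_features):
                stacked[f, :, f] = X_oob[rng.permutation(m), f]
            preds = tree.predict(stacked.reshape(n_features * m, n_features))
            err = (preds.reshape(n_features, m) - y_oob) ** 2
            deltas[t] = err.mean(axis=1) - baseline
        mean = deltas.mean(axis=0)
        sd = deltas.std(axis=0, ddof=0)
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean)
        return out


# ---------------------------------------------------------------------------
# Feature assembly


def assemble_features(
    gene: str,
    dataset,
    relatedness,
    include_lineage: bool = False,
    min_lineage: int = 10,
    include_oncogene_cnv: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build the feature table for one gene's dependency model.

    Columns: own expression and copy number; expression and copy number of
    each isozyme and each (ranked) neighbor; one binary column per
    oncogene mutation; one-hot media; optionally one-hot lineage (lineages
    below ``min_lineage`` lines pooled into "other").  Missing values are
    mean-imputed per column and constant columns dropped (logged).
    Oncogene copy-number columns are off by default (adding them did not
    increase model counts).
    """
    lines = dataset.cell_lines
    columns: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}

    def add_molecular(partner: str, prefix: str):
        if partner in dataset.expression.index:
            columns[f"exp:{partner}"] = dataset.expression.loc[partner].to_numpy(dtype=float)
            categories[f"exp:{partner}"] = f"{prefix}_exp"
        if partner in dataset.cnv.index:
            columns[f"cnv:{partner}"] = dataset.cnv.loc[partner].to_numpy(dtype=float)
            categories[f"cnv:{partner}"] = f"{prefix}_cnv"

    add_molecular(gene, "self")
    isozymes = sorted(relatedness.isozymes.get(gene, ())) if relatedness else []
    for iso in isozymes:
        add_molecular(iso, "iso")
    neighbors = list(relatedness.neighbors.get(gene, [])) if relatedness else []
    if relatedness and gene not in relatedness.genes():
        log.info("gene %s absent from relatedness map; using self/mutation/media features", gene)
    for nb in neighbors:
        if f"exp:{nb}" not in columns:
            add_molecular(nb, "related")

    for onc in dataset.mutations.index:
        columns[f"mut:{onc}"] = dataset.mutations.loc[onc].to_numpy(dtype=float)
        categories[f"mut:{onc}"] = "mutation"
        if include_oncogene_cnv and onc in dataset.cnv.index:
            columns[f"onc_cnv:{onc}"] = dataset.cnv.loc[onc].to_numpy(dtype=float)
            categories[f"onc_cnv:{onc}"] = "related_cnv"

    media = dataset.annotations["medium"]
    for level in sorted(media.unique()):
        columns[f"media:{level}"] = (media == level).to_numpy(dtype=float)
        categories[f"media:{level}"] = "media"

    if include_lineage:
        lin = dataset.annotations["lineage"]
        counts = lin.value_counts()
        big = sorted(str(name) for name, c in counts.items() if c >= min_lineage)
        for level in big:
            columns[f"lineage:{level}"] = (lin == level).to_numpy(dtype=float)
            categories[f"lineage:{level}"] = "lineage"
        pooled = ~lin.isin(big)
        if pooled.any():
            columns["lineage:other"] = pooled.to_numpy(dtype=float)
            categories["lineage:other"] = "lineage"

    X = pd.DataFrame(columns, index=lines)
    # mean-impute, then drop constants
    X = X.fillna(X.mean())
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if constant:
        log.info("gene %s: dropping %d constant feature columns", gene, len(constant))
        X = X.drop(columns=constant)
        for c in constant:
            categories.pop(c, None)
    return X, categories


# ---------------------------------------------------------------------------
# Fitting, scoring, significance


@dataclass
class DependencyModel:
    """Summary of one gene's fitted dependency model."""

    gene: str
    oob_r: float = float("nan")
    oob_p: float = float("nan")
    oob_spearman_r: float = float("nan")
    empirical_p: float = float("nan")
    fdr_p: float = float("nan")
    importances: list[tuple[str, str, float]] = field(default_factory=list)
    n_features_final: int = 0
    n_lines: int = 0
    seed: int = 0
    unexplainable: bool = False
    significant: bool = False

    @property
    def top_feature(self) -> str:
        return self.importances[0][0] if self.importances else ""

    @property
    def top5(self) -> list[tuple[str, str, float]]:
        return self.importances[:5]


def fit_forest(
    features: pd.DataFrame,
    y,
    n_trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
    min_lines: int = 30,
) -> tuple[BaggedForest, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the ensemble on lines with observed dependency.

    Returns ``(forest, X_used, y_used, oob_predictions)``.  Lines with a
    missing response are dropped; raises on too few lines, zero features,
    or a constant response.
    """
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < min_lines:
        raise ModelingError(f"only {int(keep.sum())} lines with observed dependency (< {min_lines})")
    if features.shape[1] == 0:
        raise ModelingError("no usable features")
    X = features.to_numpy(dtype=float)[keep]
    yy = y[keep]
    if np.ptp(yy) == 0:
        raise ModelingError("constant dependency vector: scoring degenerate")
    forest = BaggedForest(n_trees=n_trees, min_leaf=min_leaf, seed=seed).fit(X, yy)
    oob = forest.oob_prediction(X)
    n_unscored = int(np.isnan(oob).sum())
    if n_unscored:
        log.info("%d samples never out of bag; excluded from scoring", n_unscored)
    return forest, X, yy, oob


def oob_goodness_of_fit(oob_predictions, y, min_scored: int = 10) -> tuple[float, float]:
    """Pearson r and two-sided p between OOB predictions and observations."""
    pred = np.asarray(oob_predictions, dtype=float)
    obs = np.asarray(y, dtype=float)
    mask = ~(np.isnan(pred) | np.isnan(obs))
    if mask.sum() < min_scored:
        return (float("nan"), float("nan"))
    pred, obs = pred[mask], obs[mask]
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return (float("nan"), float("nan"))
    res = stats.pearsonr(pred, obs)
    return (float(res.statistic), float(res.pvalue))


def importance_and_refit(
    forest: BaggedForest,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    categories: dict[str, str],
    seed: int = 0,
) -> tuple[list[tuple[str, str, float]], BaggedForest | None, bool]:
    """Select positive-importance features and refit on them only.

    Returns ``(ordered importances from the refit model, refit forest,
    unexplainable)``.  Importance order is descending, ties broken by
    original column order.  A model with no positive-importance feature is
    unexplainable (empty list, no refit).
    """
    imp = forest.oob_importance(X, y, seed=seed)
    keep = np.where(imp > 0)[0]
    if keep.size == 0:
        return [], None, True
    X_kept = X[:, keep]
    refit = BaggedForest(
        n_trees=forest.n_trees, min_leaf=forest.min_leaf,
        max_features=forest.max_features, seed=seed + 1,
    ).fit(X_kept, y)
    imp2 = refit.oob_importance(X_kept, y, seed=seed + 2)
    order = sorted(range(len(keep)), key=lambda i: (-imp2[i], i))
    ordered = [
        (feature_names[keep[i]], categories.get(feature_names[keep[i]], ""), float(imp2[i]))
        for i in order
    ]
    return ordered, refit, False


def model_gene(
    gene: str,
    dataset,
    relatedness,
    seed: int = 0,
    n_trees: int = 100,
    min_leaf: int = 5,
    include_lineage: bool = False,
    min_lineage: int = 10,
    min_lines: int = 30,
    compute_importance: bool = True,
    include_oncogene_cnv: bool = False,
) -> DependencyModel:
    """Assemble features, fit, score, and (optionally) rank features for one gene."""
    X, categories = assemble_features(
        gene, dataset, relatedness,
        include_lineage=include_lineage, min_lineage=min_lineage,
        include_oncogene_cnv=include_oncogene_cnv,
    )
    y = dataset.dependency.loc[gene].to_numpy(dtype=float)
    forest, X_used, y_used, oob = fit_forest(
        X, y, n_trees=n_trees, min_leaf=min_leaf, seed=seed, min_lines=min_lines
    )
    r, p = oob_goodness_of_fit(oob, y_used)
    rho = float("nan")
    mask = ~np.isnan(oob)
    if mask.sum() >= 10:
        rho = float(stats.spearmanr(oob[mask], y_used[mask]).statistic)

    model = DependencyModel(
        gene=gene, oob_r=r, oob_p=p, oob_spearman_r=rho,
        n_lines=int(len(y_used)), seed=seed,
    )
    if compute_importance:
        names = list(X.columns)
        ordered, _, unexplainable = importance_and_refit(
            forest, X_used, y_used, names, categories, seed=seed
        )
        model.importances = ordered
        model.n_features_final = len(ordered)
        model.unexplainable = unexplainable
    else:
        model.n_features_final = X.shape[1]
    return model


def _gene_seed(master_seed: int, index: int) -> int:
    """Stable per-gene seed, independent of execution order or thread count."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def fit_models(
    dataset,
    relatedness,
    genes,
    seed: int = 0,
    threads: int = 1,
    **kwargs,
) -> list[DependencyModel]:
    """Fit dependency models for a list of genes (deterministic at any thread count)."""
    genes = list(genes)

    def work(item):
        i, gene = item
        try:
            return model_gene(gene, dataset, relatedness, seed=_gene_seed(seed, i), **kwargs)
        except ModelingError as exc:
            log.info("gene %s skipped: %s", gene, exc)
            return None

    items = list(enumerate(genes))
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(work, items))
    else:
        results = [work(item) for item in items]
    return [m for m in results if m is not None]


def permutation_null(
    dataset,
    relatedness,
    genes,
    repetitions: int = 25000,
    seed: int = 0,
    n_trees: int = 100,
    min_leaf: int = 5,
    include_lineage: bool = False,
    min_lineage: int = 10,
    min_lines: int = 30,
    include_oncogene_cnv: bool = False,
) -> np.ndarray:
    """Null distribution of OOB Pearson p-values under shuffled dependency.

    Each repetition draws a gene uniformly from the modeled set, permutes
    its observed dependency scores across cell lines, fits the same model,
    and records the OOB Pearson p.  Returns the sorted p-values.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    genes = list(genes)
    if not genes:
        raise ModelingError("empty modeled-gene set for permutation null")
    rng = np.random.default_rng(seed)
    feature_cache: dict[str, pd.DataFrame] = {}
    pvals = []
    for _ in range(repetitions):
        gene = genes[int(rng.integers(0, len(genes)))]
        if gene not in feature_cache:
            feature_cache[gene], _ = assemble_features(
                gene, dataset, relatedness,
                include_lineage=include_lineage, min_lineage=min_lineage,
                include_oncogene_cnv=include_oncogene_cnv,
            )
        X = feature_cache[gene]
        y = dataset.dependency.loc[gene].to_numpy(dtype=float).copy()
        obs = ~np.isnan(y)
        y[obs] = rng.permutation(y[obs])
        try:
            forest, X_used, y_used, oob = fit_forest(
                X, y, n_trees=n_trees, min_leaf=min_leaf,
                seed=int(rng.integers(0, 2**31 - 1)), min_lines=min_lines,
            )
        except ModelingError:
            continue
        _, p = oob_goodness_of_fit(oob, y_used)
        if not np.isnan(p):
            pvals.append(p)
    return np.sort(np.asarray(pvals))


def empirical_significance(
    models: list[DependencyModel], null_ps: np.ndarray, alpha: float = 0.05
) -> list[DependencyModel]:
    """Attach empirical p (add-one fraction of null p <= observed) and BH-FDR."""
    null_ps = np.sort(np.asarray(null_ps, dtype=float))
    n = null_ps.size
    if n == 0:
        raise ModelingError("empty permutation null")
    for m in models:
        if np.isnan(m.oob_p):
            m.empirical_p = float("nan")
        else:
            hits = int(np.searchsorted(null_ps, m.oob_p, side="right"))
            m.empirical_p = (1 + hits) / (n + 1)
    fdr = bh_fdr([m.empirical_p for m in models])
    for m, q in zip(models, fdr):
        m.fdr_p = float(q)
        m.significant = bool(q < alpha) and not m.unexplainable
    return models


def shuffled_related_control(
    dataset,
    relatedness,
    genes,
    null_ps: np.ndarray,
    repetitions: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    threads: int = 1,
    **kwargs,
) -> list[float]:
    """Fraction of significant models per repetition with shuffled related sets.

    Each repetition replaces every gene's neighbor and isozyme sets with
    equal-size random draws from the expression-measured metabolic genes
    and reruns the modeling stage (scored against the same permutation
    null).  Feature ranking is skipped — only significance is recorded.
    """
    from .neighbors import RelatednessMap

    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    genes = list(genes)
    pool = np.array(sorted(
        (dataset.metabolic_genes or set(dataset.dependency.index))
        & set(dataset.expression.index)
    ))
    rng = np.random.default_rng(seed)
    fractions = []
    kwargs = dict(kwargs)
    kwargs["compute_importance"] = False
    for _ in range(repetitions):
        shuffled = RelatednessMap(cap=relatedness.cap)
        for gene in set(genes) | relatedness.genes():
            others = pool[pool != gene]
            n_nb = len(relatedness.neighbors.get(gene, []))
            n_iso = len(relatedness.isozymes.get(gene, ()))
            shuffled.neighbors[gene] = (
                list(rng.choice(others, size=min(n_nb, len(others)), replace=False))
                if n_nb else []
            )
            shuffled.isozymes[gene] = (
                set(rng.choice(others, size=min(n_iso, len(others)), replace=False))
                if n_iso else set()
            )
        models = fit_models(
            dataset, shuffled, genes,
            seed=int(rng.integers(0, 2**31 - 1)), threads=threads, **kwargs
        )
        if not models:
            fractions.append(float("nan"))
            continue
        empirical_significance(models, null_ps, alpha=alpha)
        fractions.append(float(np.mean([m.significant for m in models])))
    return fractions


# ---------------------------------------------------------------------------
# Reporting


def categorize_top_features(models: list[DependencyModel]) -> pd.DataFrame:
    """Prevalence of feature categories (and individual mutation/lineage
    features) as the top or a top-5 feature, over significant models."""
    sig = [m for m in models if m.significant and m.importances]
    rows = []
    if not sig:
        return pd.DataFrame(columns=["kind", "name", "fraction_top", "fraction_top5"])
    n = len(sig)
    top_cats = [m.importances[0][1] for m in sig]
    top5_cats = [{c for _, c, _ in m.top5} for m in sig]
    for cat in FEATURE_CATEGORIES:
        rows.append((
            "category", cat,
            sum(1 for c in top_cats if c == cat) / n,
            sum(1 for cats in top5_cats if cat in cats) / n,
        ))
    # individual mutation / lineage features
    for kind, prefix in (("mutation", "mut:"), ("lineage", "lineage:")):
        names = sorted({
            f for m in sig for f, _, _ in m.top5 if f.startswith(prefix)
        })
        for name in names:
            rows.append((
                kind, name,
                sum(1 for m in sig if m.top_feature == name) / n,
                sum(1 for m in sig if any(f == name for f, _, _ in m.top5)) / n,
            ))
    return pd.DataFrame(rows, columns=["kind", "name", "fraction_top", "fraction_top5"])


def models_to_table(models: list[DependencyModel]) -> pd.DataFrame:
    """Flatten model summaries to the output table schema."""
    rows = []
    for m in models:
        top5 = ";".join(f"{f}[{c}]" for f, c, _ in m.top5)
        rows.append((
            m.gene, m.oob_r, m.oob_p, m.oob_spearman_r, m.empirical_p, m.fdr_p,
            m.n_features_final, m.top_feature, top5,
            int(m.significant), int(m.unexplainable), m.n_lines, m.seed,
        ))
    return pd.DataFrame(rows, columns=[
        "gene", "oob_r", "oob_p", "oob_spearman_r", "empirical_p", "fdr_p",
        "n_features", "top_feature", "top5", "significant", "unexplainable",
        "n_lines", "seed",
    ])
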