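"""Screen dataset loading, alignment and variability filtering.

A :class:`ScreenDataset` bundles the gene x cell-line matrices of a
loss-of-function screen (dependency scores, lower = more essential),
CCLE-style molecular features (expression, copy number, binary oncogene
mutations) and per-cell-line annotations (medium, culture type, lineage).
All matrices share one ordered cell-line axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellLineAnnotation",
    "ScreenDataset",
    "ScreenDataError",
    "load_screen",
    "load_matrix",
    "variability_filter",
    "variability_stats",
]

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("cell_line", "medium", "culture_type", "lineage")


class ScreenDataError(ValueError):
    """Raised on malformed or inconsistent screen inputs."""


@dataclass(frozen=True)
class CellLineAnnotation:
    cell_line: str
    medium: str
    culture_type: str
    lineage: str


@dataclass
class ScreenDataset:
    """Aligned screen matrices plus annotations.

    All frames are gene (row) x cell line (column); ``annotations`` is
    indexed by cell line with columns medium / culture_type / lineage in
    the same order as the matrix columns.
    """

    dependency: pd.DataFrame
    expression: pd.DataFrame
    cnv: pd.DataFrame
    mutations: pd.DataFrame
    annotations: pd.DataFrame
    metabolic_genes: set[str] = field(default_factory=set)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.dependency.columns)

    def media_indicator(self, medium_a: str, medium_b: str) -> pd.Series:
        """Binary vector over lines in either medium: 1 = medium_a, 0 = medium_b."""
        med = self.annotations["medium"]
        mask = med.isin([medium_a, medium_b])
        return (med[mask] == medium_a).astype(float)

    def lineage_indicators(self, min_lines: int = 10) -> dict[str, pd.Series]:
        """One 0/1 indicator per lineage with at least ``min_lines`` cell lines."""
        lin = self.annotations["lineage"]
        out: dict[str, pd.Series] = {}
        for name, count in lin.value_counts().items():
            if count >= min_lines:
                out[str(name)] = (lin == name).astype(float)
        return out

    def validate(self) -> None:
        axis = list(self.dependency.columns)
        for name in ("expression", "cnv", "mutations"):
            cols = list(getattr(self, name).columns)
            if cols != axis:
                raise ScreenDataError(f"{name} matrix cell-line axis differs from dependency")
        if list(self.annotations.index) != axis:
            raise ScreenDataError("annotation index differs from matrix cell-line axis")
        if not self.metabolic_genes <= set(self.dependency.index):
            raise ScreenDataError("metabolic_genes not a subset of dependency genes")


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_matrix(path: str) -> pd.DataFrame:
    """Read a gene x cell-line matrix from TSV/CSV (first column = gene id)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ScreenDataError(f"duplicate gene rows in {path}: {dups[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ScreenDataError(
                    f"non-numeric value in {path} at row {bad[0]!r}, column {col!r}"
                )
            df[col] = coerced
    return df.astype(float)


def _load_annotations(path: str, media_map: dict[str, str] | None) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ScreenDataError(f"annotation table missing columns {missing}")
    ann = ann.set_index("cell_line")
    if ann.index.duplicated().any():
        raise ScreenDataError("duplicate cell lines in annotation table")
    ann = ann[["medium", "culture_type", "lineage"]].fillna("unknown")
    ann = ann.replace("", "unknown")
    if media_map is not None:
        ann["medium"] = ann["medium"].map(lambda m: media_map.get(m, "other"))
    return ann


def load_screen(
    dependency_path: str,
    expression_path: str,
    cnv_path: str,
    mutation_path: str,
    annotation_path: str,
    metabolic_genes: set[str] | None = None,
    media_map: dict[str, str] | None = None,
) -> ScreenDataset:
    """Load and align the five screen files.

    Cell-line axes are intersected across all matrices and the annotation
    table; lines dropped in the intersection are logged.  Order follows the
    dependency matrix's column order.
    """
    dependency = load_matrix(dependency_path)
    expression = load_matrix(expression_path)
    cnv = load_matrix(cnv_path)
    mutations = load_matrix(mutation_path)
    ann = _load_annotations(annotation_path, media_map)

    common = [
        c
        for c in dependency.columns
        if c in set(expression.columns)
        and c in set(cnv.columns)
        and c in set(mutations.columns)
        and c in set(ann.index)
    ]
    if not common:
        raise ScreenDataError("empty intersection of cell lines across inputs")
    dropped = sorted(
        (set(dependency.columns) | set(expression.columns) | set(cnv.columns)
         | set(mutations.columns) | set(ann.index)) - set(common)
    )
    if dropped:
        log.warning("dropping %d cell lines absent from some input: %s", len(dropped), dropped[:10])

    ds = ScreenDataset(
        dependency=dependency[common],
        expression=expression[common],
        cnv=cnv[common],
        mutations=mutations[common],
        annotations=ann.loc[common],
        metabolic_genes=(metabolic_genes or set()) & set(dependency.index),
    )
    ds.validate()
    return ds


def variability_stats(dependency: pd.DataFrame, k: float) -> pd.DataFrame:
    """Per-gene min/mean/sd and pass flag for the k-SD variability filter.

    A gene passes iff its minimum score over cell lines is strictly below
    ``mean - k * sd`` (sample sd, n-1 denominator, non-missing entries only).
    Genes with fewer than 3 non-missing values or zero sd fail.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    values = dependency.to_numpy(dtype=float)
    n = np.sum(~np.isnan(values), axis=1)
    mean = np.full(len(values), np.nan)
    sd = np.full(len(values), np.nan)
    mn = np.full(len(values), np.inf)
    some = n > 0
    mean[some] = np.nanmean(values[some], axis=1)
    mn[some] = np.nanmin(np.where(np.isnan(values[some]), np.inf, values[some]), axis=1)
    ok = n >= 2
    sd[ok] = np.nanstd(values[ok], axis=1, ddof=1)
    passes = (n >= 3) & (sd > 0) & (mn < mean - k * sd)
    return pd.DataFrame(
        {
            "gene": dependency.index,
            "passes": passes,
            "min_score": mn,
            "mean": mean,
            "sd": sd,
            "threshold_k": k,
        }
    ).set_index("gene")


def variability_filter(dependency: pd.DataFrame, k: float) -> set[str]:
    """Genes passing the k-SD variability filter (see :func:`variability_stats`)."""
    stats = variability_stats(dependency, k)
    return set(stats.index[stats["passes"]])
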