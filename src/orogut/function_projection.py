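"""Functional pathway projection: a declared linear gene-copy surrogate for
16S-based metagenome prediction.

The predicted abundance of a pathway in a sample is the relative abundance
of each taxon multiplied by that taxon's gene-copy count for the pathway,
summed over taxa — an explicit, controllable linear projection through a
taxa x pathways reference.  Downstream the projected table is ranked by
log-mean abundance, screened for type-enriched pathways (Kruskal-Wallis
with BH control) and correlated taxon-against-pathway (Spearman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance_io import AbundanceTable

logger = logging.getLogger("orogut")

#: floor inside the log so zero-abundance pathways stay finite (and last)
LOG_EPSILON = 1e-12

__all__ = [
    "GeneCopyReference", "PathwayTable",
    "project_pathways", "rank_pathways", "type_enriched_pathways",
    "taxon_pathway_correlation", "read_reference", "write_reference",
]


@dataclass(frozen=True)
class GeneCopyReference:
    """Taxa x pathways non-negative gene-copy matrix."""

    taxon_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]
    copies: np.ndarray
    category: dict[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_ids", tuple(map(str, self.taxon_ids)))
        object.__setattr__(self, "pathway_ids",
                           tuple(map(str, self.pathway_ids)))
        copies = np.asarray(self.copies, dtype=float)
        object.__setattr__(self, "copies", copies)
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids in reference")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway ids in reference")
        if copies.shape != (len(self.taxon_ids), len(self.pathway_ids)):
            raise ValueError(
                f"copies shape {copies.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.pathway_ids)} pathways")
        if copies.size and copies.min() < 0:
            raise ValueError("gene-copy numbers must be non-negative")


@dataclass(frozen=True)
class PathwayTable:
    """Samples x pathways predicted abundance matrix."""

    sample_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]
    values: np.ndarray
    category: dict[str, str] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.sample_ids), len(self.pathway_ids)):
            raise ValueError("pathway matrix shape mismatch")
        if vals.size and vals.min() < 0:
            raise ValueError("pathway abundances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.sample_ids),
                            columns=list(self.pathway_ids))


def project_pathways(table: AbundanceTable,
                     ref: GeneCopyReference) -> PathwayTable:
    """Project relative taxon abundances through the gene-copy reference.

    ``pathways = abundances @ copies`` restricted to the table's taxa; every
    table taxon must appear in the reference (missing taxa are an error,
    listed by name).  The projection is linear in the abundances.
    """
    if table.mode != "relative":
        raise ValueError("project_pathways requires a relative table")
    ref_index = {t: i for i, t in enumerate(ref.taxon_ids)}
    missing = [t for t in table.taxon_ids if t not in ref_index]
    if missing:
        raise ValueError(
            f"{len(missing)} taxa absent from the gene-copy reference: "
            f"{missing[:5]}")
    rows = [ref_index[t] for t in table.taxon_ids]
    values = table.values @ ref.copies[rows, :]
    return PathwayTable(table.sample_ids, ref.pathway_ids, values,
                        category=ref.category)


def rank_pathways(pt: PathwayTable, top_n: int = 20) -> pd.DataFrame:
    """Top pathways by log10 mean abundance.

    score = log10(mean abundance + 1e-12), sorted descending with ties
    broken by pathway id; global rescaling of the table shifts every score
    equally and never reorders.
    """
    if top_n > len(pt.pathway_ids):
        raise ValueError(f"top_n={top_n} exceeds {len(pt.pathway_ids)} pathways")
    means = pt.values.mean(axis=0)
    scores = np.log10(means + LOG_EPSILON)
    df = pd.DataFrame({
        "pathway": list(pt.pathway_ids),
        "mean_abundance": means,
        "log10_mean": scores,
    })
    if pt.category:
        df["category"] = [pt.category.get(p, "") for p in pt.pathway_ids]
    df = df.sort_values(["log10_mean", "pathway"],
                        ascending=[False, True], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)


def type_enriched_pathways(pt: PathwayTable, types, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Pathways that differ between community types.

    Kruskal-Wallis across types per pathway, BH adjustment across all
    pathways tested; the representative type of a significant pathway is
    the type with the highest mean abundance.  Pathways constant across all
    samples are untestable and reported with NaN statistics.
    """
    from .cross_site_stats import bh_adjust, kruskal_wallis

    types = np.asarray(types)
    if len(types) != len(pt.sample_ids):
        raise ValueError("one type label per sample required")
    if len(np.unique(types)) < 2:
        raise ValueError("need at least 2 types")
    rows = []
    for j, pwy in enumerate(pt.pathway_ids):
        vals = pt.values[:, j]
        if np.all(vals == vals[0]):
            rows.append((pwy, np.nan, np.nan, None))
            continue
        cmp = kruskal_wallis(vals, types, variable=pwy)
        rep = max(cmp.group_means, key=lambda g: (cmp.group_means[g], g))
        rows.append((pwy, cmp.H, cmp.p, rep))
    df = pd.DataFrame(rows, columns=["pathway", "H", "p", "representative_type"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p_adjusted"] < alpha).fillna(False)
    df.loc[~df["significant"], "representative_type"] = None
    if pt.category:
        df["category"] = [pt.category.get(p, "") for p in pt.pathway_ids]
    return df[["pathway", "H", "p", "p_adjusted", "significant",
               "representative_type"] + (["category"] if pt.category else [])]


def taxon_pathway_correlation(table: AbundanceTable, pt: PathwayTable,
                              taxa=None, pathways=None, alpha: float = 0.05):
    """Spearman rho/p/BH grid between selected taxa and selected pathways."""
    from .cross_site_stats import spearman_matrix

    if tuple(table.sample_ids) != tuple(pt.sample_ids):
        raise ValueError("table and pathway table must share subjects in order")
    taxa = list(taxa) if taxa is not None else list(table.taxon_ids)
    pathways = list(pathways) if pathways is not None else list(pt.pathway_ids)
    x = table.to_frame()[taxa]
    y = pt.to_frame()[pathways]
    return spearman_matrix(x, y, alpha=alpha)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_reference(path) -> GeneCopyReference:
    """Read a taxa-rows TSV gene-copy reference (optional last column
    ``category`` is ignored; a ``#category`` comment row labels pathways)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    category = None
    if df.index[-1] == "#category":
        category = {p: str(v) for p, v in df.iloc[-1].items()}
        df = df.iloc[:-1]
    return GeneCopyReference(tuple(map(str, df.index)),
                             tuple(map(str, df.columns)),
                             df.to_numpy(float), category=category)


def write_reference(ref: GeneCopyReference, path) -> None:
    df = pd.DataFrame(ref.copies, index=list(ref.taxon_ids),
                      columns=list(ref.pathway_ids))
    if ref.category:
        df.loc["#category"] = [ref.category.get(p, "") for p in ref.pathway_ids]
    df.to_csv(path, sep="\t", index_label="taxon_id")
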