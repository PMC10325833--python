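"""Core-microbiome extraction by minimum prevalence.

A taxon belongs to a site's core when it is detected (abundance > 0) in at
least 30% of that site's samples — taxa below the minimum-incidence
criterion are treated as individual variability.  The cross-site core is
the intersection of the per-site cores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .abundance_io import AbundanceTable

logger = logging.getLogger("orogut")

__all__ = ["CoreSet", "prevalence", "core_filter", "core_intersection"]


@dataclass(frozen=True)
class CoreSet:
    """Per-site prevalences and core lists plus their intersection."""

    site_prevalence: dict[str, dict[str, float]]
    site_core: dict[str, tuple[str, ...]]
    core: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        for site, prev in self.site_prevalence.items():
            bad = [t for t, f in prev.items() if not 0 <= f <= 1]
            if bad:
                raise ValueError(f"{site} prevalence out of [0,1]: {bad[:3]}")
        for site, taxa in self.site_core.items():
            if not set(self.core) <= set(taxa):
                raise ValueError(
                    f"cross-site core must be a subset of the {site} core")

    def to_json(self) -> str:
        return json.dumps({
            "threshold": self.threshold,
            "site_core": {s: list(t) for s, t in self.site_core.items()},
            "core": list(self.core),
            "site_prevalence": self.site_prevalence,
        }, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Flat (taxon, per-site prevalence, in_core) table."""
        sites = sorted(self.site_prevalence)
        taxa = sorted({t for p in self.site_prevalence.values() for t in p})
        rows = []
        core = set(self.core)
        for t in taxa:
            row = {"taxon": t}
            for s in sites:
                row[f"{s}_prevalence"] = self.site_prevalence[s].get(t, 0.0)
            row["in_core"] = t in core
            rows.append(row)
        return pd.DataFrame(rows)


def prevalence(table: AbundanceTable) -> dict[str, float]:
    """Fraction of samples in which each taxon is detected (> 0)."""
    frac = (table.values > 0).mean(axis=0)
    return {t: float(f) for t, f in zip(table.taxon_ids, frac)}


def core_filter(table: AbundanceTable,
                min_prevalence: float = 0.30) -> AbundanceTable:
    """Retain taxa with prevalence >= ``min_prevalence``; samples unchanged.

    The boundary is inclusive: a taxon present in exactly 30% of samples
    stays (only those *below* the minimum incidence are discarded).
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    prev = prevalence(table)
    kept = [t for t in table.taxon_ids if prev[t] >= min_prevalence]
    logger.info("core_filter(%s): kept %d/%d taxa at prevalence >= %g",
                table.site, len(kept), table.n_taxa, min_prevalence)
    return table.select_taxa(kept)


def core_intersection(gut_core: AbundanceTable, oral_core: AbundanceTable,
                      threshold: float = 0.30) -> CoreSet:
    """Cross-site core: taxa in both per-site cores, in gut-table order."""
    oral_set = set(oral_core.taxon_ids)
    shared = tuple(t for t in gut_core.taxon_ids if t in oral_set)
    if not shared:
        logger.warning("core_intersection: per-site cores are disjoint")
    return CoreSet(
        site_prevalence={"gut": prevalence(gut_core),
                         "oral": prevalence(oral_core)},
        site_core={"gut": gut_core.taxon_ids, "oral": oral_core.taxon_ids},
        core=shared,
        threshold=threshold,
    )


def family_edge_list(core: CoreSet,
                     taxonomy: dict[str, str] | None) -> pd.DataFrame:
    """Node/edge table (site or core -> family) for external alluvial or
    arc rendering; family falls back to the taxon id without a lineage."""
    rows = []
    core_set = set(core.core)
    for site, taxa in core.site_core.items():
        for t in taxa:
            family = t
            if taxonomy and t in taxonomy:
                levels = taxonomy[t].split(";")
                if len(levels) >= 4:
                    family = levels[3].strip() or t
            rows.append({"source": site, "target": family, "taxon": t,
                         "in_core": t in core_set})
    return pd.DataFrame(rows)
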