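"""Abundance-table I/O, validation, normalisation and paired-sample alignment.

Genus-level abundance tables are the pipeline's sole sequence-derived input:
a samples x taxa matrix of read counts (or relative abundances) for one body
site, with an optional semicolon-delimited lineage per taxon.  Tables are
exchanged as TSV in the common QIIME orientation (taxa as rows, samples as
columns); BIOM 2.x HDF5 files are accepted read-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("orogut")

SITES = ("gut", "oral", "other")
MODES = ("counts", "relative")

#: header cells that mark a taxa-as-rows TSV (first column holds taxon ids)
_TAXA_ROW_SENTINELS = {"", "#otu id", "#otu_id", "otu id", "taxon", "taxon_id",
                       "taxonid", "feature id", "feature_id", "genus"}
_SAMPLE_ROW_SENTINELS = {"sample", "sample_id", "sampleid", "subject",
                         "subject_id"}

_ROW_SUM_TOL = 1e-9


class TableFormatError(ValueError):
    """Malformed input file (duplicate ids, bad orientation, bad header)."""


class TableValidationError(ValueError):
    """Well-formed file whose values violate an abundance-table invariant."""


@dataclass(frozen=True)
class AbundanceTable:
    """A samples x taxa abundance matrix for one body site.

    Parameters
    ----------
    sample_ids, taxon_ids : ordered, duplicate-free identifier lists.
    values : ``(n_samples, n_taxa)`` non-negative float array.
    site : one of ``gut``, ``oral``, ``other``.
    mode : ``counts`` (raw reads) or ``relative`` (rows sum to 1).
    taxonomy : optional map taxon id -> ``phylum;class;order;family;genus``.
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray
    site: str = "other"
    mode: str = "counts"
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "taxon_ids", tuple(map(str, self.taxon_ids)))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise TableValidationError("values must be a 2-D matrix")
        object.__setattr__(self, "values", vals)
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise TableFormatError(f"duplicate {name} id(s): {sorted(dupes)}")
        if vals.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableValidationError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa")
        if self.site not in SITES:
            raise TableValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if self.mode not in MODES:
            raise TableValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if vals.size and vals.min() < 0:
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            raise TableValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}")
        if self.mode == "relative" and vals.size:
            # low-abundance filtering may leave rows summing to < 1 (never
            # renormalised here), so only the upper bound and positivity are
            # structural; exact unit sums are enforced at the I/O boundary.
            sums = vals.sum(axis=1)
            bad = np.flatnonzero((sums <= 0) | (sums > 1.0 + _ROW_SUM_TOL))
            if bad.size:
                raise TableValidationError(
                    f"relative rows must sum to at most 1 and be non-empty: "
                    f"sample {self.sample_ids[bad[0]]!r} sums to "
                    f"{sums[bad[0]]:.12g}")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.taxon_ids)
            if unknown:
                raise TableValidationError(
                    f"taxonomy keys not in taxon_ids: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        """Samples x taxa DataFrame view (copy)."""
        return pd.DataFrame(self.values.copy(), index=list(self.sample_ids),
                            columns=list(self.taxon_ids))

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        """Sub-table restricted to ``taxa`` (kept in the given order);
        relative rows are not renormalised (sums may drop below 1)."""
        idx = [self._taxon_index()[t] for t in taxa]
        vals = self.values[:, idx]
        tax = None
        if self.taxonomy:
            tax = {t: self.taxonomy[t] for t in taxa if t in self.taxonomy}
        return AbundanceTable(self.sample_ids, tuple(taxa), vals,
                              site=self.site, mode=self.mode, taxonomy=tax)

    def select_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in samples]
        return AbundanceTable(tuple(samples), self.taxon_ids,
                              self.values[idx], site=self.site, mode=self.mode,
                              taxonomy=self.taxonomy)

    def _taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxon_ids)}


@dataclass(frozen=True)
class PairedCohort:
    """One gut and one oral table over a shared, ordered subject list."""

    gut: AbundanceTable
    oral: AbundanceTable
    subjects: tuple[str, ...]
    #: subject -> (gut sample id, oral sample id)
    pairing: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gut.site != "gut" or self.oral.site != "oral":
            raise TableValidationError("cohort tables must be tagged gut/oral")
        n = len(self.subjects)
        if self.gut.n_samples != n or self.oral.n_samples != n:
            raise TableValidationError(
                "both tables must hold exactly one sample per subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    return {i for i in ids if i in seen or seen.add(i)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_table(path: str | Path, site: str = "other", mode: str = "counts",
               orientation: str = "auto") -> AbundanceTable:
    """Read an abundance table from TSV or BIOM 2.x.

    TSV dialect: tab-separated, UTF-8, ``#`` comment lines ignored (a header
    starting with ``#OTU ID`` is kept).  Default orientation is taxa as rows
    with samples as columns and an optional trailing ``taxonomy`` column; the
    orientation is auto-detected from the header's first cell and logged, and
    can be forced with ``orientation`` = ``taxa_rows`` | ``samples_rows``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such abundance table: {path}")
    if path.suffix.lower() == ".biom":
        table = _read_biom(path, site=site, mode=mode)
    else:
        table = _read_tsv(path, site=site, mode=mode, orientation=orientation)
    if mode == "relative":
        sums = table.values.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
        if bad.size:
            raise TableValidationError(
                f"{path}: relative abundances for sample "
                f"{table.sample_ids[bad[0]]!r} sum to {sums[bad[0]]:.12g}, "
                f"expected 1")
    return table


def _read_tsv(path: Path, site: str, mode: str, orientation: str) -> AbundanceTable:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and not line.lower().startswith("#otu id"):
                continue
            if line.strip():
                lines.append(line.rstrip("\n"))
    if len(lines) < 2:
        raise TableFormatError(f"{path}: need a header and at least one data row")
    header = lines[0].split("\t")
    first_cell = header[0].lstrip("#").strip().lower()
    if orientation == "auto":
        if first_cell in _SAMPLE_ROW_SENTINELS:
            orientation = "samples_rows"
        else:
            if first_cell not in _TAXA_ROW_SENTINELS:
                logger.info("read_table: header sentinel %r unrecognised; "
                            "assuming taxa-as-rows", header[0])
            orientation = "taxa_rows"
    logger.info("read_table %s: orientation=%s", path.name, orientation)

    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    col_ids = header[1:-1] if has_taxonomy else header[1:]
    row_ids, rows, lineages = [], [], {}
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}: row {cells[0]!r} has {len(cells)} fields, "
                f"expected {len(header)}")
        row_ids.append(cells[0].strip())
        data = cells[1:-1] if has_taxonomy else cells[1:]
        try:
            rows.append([float(c) for c in data])
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric value in row "
                                   f"{cells[0]!r}: {exc}") from None
        if has_taxonomy and cells[-1].strip():
            lineages[cells[0].strip()] = cells[-1].strip()

    matrix = np.asarray(rows, dtype=float)
    col_ids = [c.strip() for c in col_ids]
    if orientation == "taxa_rows":
        taxon_ids, sample_ids, values = row_ids, col_ids, matrix.T
        taxonomy = lineages or None
    else:
        sample_ids, taxon_ids, values = row_ids, col_ids, matrix
        taxonomy = None
    return AbundanceTable(tuple(sample_ids), tuple(taxon_ids), values,
                          site=site, mode=mode, taxonomy=taxonomy)


def _read_biom(path: Path, site: str, mode: str) -> AbundanceTable:
    """Minimal BIOM 2.x (HDF5) reader: observation = taxon, sample = sample."""
    import h5py

    with h5py.File(path, "r") as f:
        taxon_ids = [_dec(x) for x in f["observation/ids"][:]]
        sample_ids = [_dec(x) for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
        from scipy.sparse import csr_matrix
        mat = csr_matrix((data, indices, indptr),
                         shape=(len(taxon_ids), len(sample_ids)))
        taxonomy = None
        if "observation/metadata/taxonomy" in f:
            lin = f["observation/metadata/taxonomy"][:]
            taxonomy = {}
            for tid, levels in zip(taxon_ids, lin):
                if isinstance(levels, (bytes, str)):
                    taxonomy[tid] = _dec(levels)
                else:
                    taxonomy[tid] = ";".join(_dec(v) for v in levels)
    return AbundanceTable(tuple(sample_ids), tuple(taxon_ids),
                          np.asarray(mat.todense(), dtype=float).T,
                          site=site, mode=mode, taxonomy=taxonomy)


def _dec(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as taxa-rows TSV (with a taxonomy column when present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["taxon_id", *table.sample_ids]
        if table.taxonomy:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for j, taxon in enumerate(table.taxon_ids):
            cells = [taxon] + [_fmt(v) for v in table.values[:, j]]
            if table.taxonomy:
                cells.append(table.taxonomy.get(taxon, ""))
            fh.write("\t".join(cells) + "\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(float(v))


def read_pairing(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``subject_id<TAB>sample_id`` (one file per site)."""
    pairing: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 2:
                raise TableFormatError(f"pairing line needs 2 columns: {line!r}")
            subject, sample = cells[0].strip(), cells[1].strip()
            if subject in pairing:
                raise TableFormatError(
                    f"subject {subject!r} mapped to two samples")
            pairing[subject] = sample
    return pairing


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to relative abundances (each row divided by its sum)."""
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise TableValidationError(
            f"cannot normalise all-zero sample {table.sample_ids[zero[0]]!r}")
    rel = table.values / sums[:, None]
    return replace(table, values=rel, mode="relative")


def filter_low_abundance(table: AbundanceTable,
                         threshold: float = 1e-4) -> AbundanceTable:
    """Drop taxa whose mean relative abundance across samples is below
    ``threshold`` (default 0.01%, strict comparison).

    Requires a relative table.  Retained rows are deliberately NOT
    renormalised here; the distance layer renormalises internally, keeping
    the filter side-effect free.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if table.mode != "relative":
        raise TableValidationError("filter_low_abundance requires mode=relative")
    means = table.values.mean(axis=0)
    keep = means >= threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_abundance: dropped %d/%d taxa below %.2g",
                    dropped, table.n_taxa, threshold)
    kept_taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not kept_taxa:
        raise TableValidationError("low-abundance filter removed every taxon")
    return table.select_taxa(kept_taxa)


def align_pairs(gut: AbundanceTable, oral: AbundanceTable,
                gut_pairing: Mapping[str, str],
                oral_pairing: Mapping[str, str]) -> PairedCohort:
    """Align the two site tables on subjects present at both sites.

    ``*_pairing`` map subject id -> sample id in the respective table.
    Subjects missing from either site (or whose sample is absent from the
    table) are dropped with a log entry; subject order follows the gut
    pairing file.
    """
    for name, pairing, table in (("gut", gut_pairing, gut),
                                 ("oral", oral_pairing, oral)):
        samples = list(pairing.values())
        dupes = _duplicates(samples)
        if dupes:
            raise TableFormatError(
                f"{name} pairing maps two subjects to sample(s) {sorted(dupes)}")
    gut_samples = set(gut.sample_ids)
    oral_samples = set(oral.sample_ids)
    subjects = []
    for subject in gut_pairing:
        if subject not in oral_pairing:
            logger.info("align_pairs: subject %r has no oral sample; dropped",
                        subject)
            continue
        gs, os_ = gut_pairing[subject], oral_pairing[subject]
        if gs not in gut_samples or os_ not in oral_samples:
            logger.info("align_pairs: subject %r sample missing from table; "
                        "dropped", subject)
            continue
        subjects.append(subject)
    for subject in oral_pairing:
        if subject not in gut_pairing:
            logger.info("align_pairs: subject %r has no gut sample; dropped",
                        subject)
    if not subjects:
        raise TableValidationError("no paired subjects")
    gut_aligned = gut.select_samples([gut_pairing[s] for s in subjects])
    oral_aligned = oral.select_samples([oral_pairing[s] for s in subjects])
    pairing = {s: (gut_pairing[s], oral_pairing[s]) for s in subjects}
    return PairedCohort(gut_aligned, oral_aligned, tuple(subjects), pairing)
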