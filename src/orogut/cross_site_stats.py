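"""Cross-site statistics: Spearman correlation networks with BH control,
Euclidean taxon-profile distances with UPGMA clustering, Bray-Curtis PCoA,
PERMANOVA, and Kruskal-Wallis group comparisons.

These are the descriptive and inferential statistics applied after typing
and core extraction: how taxa co-vary between the gut and the mouth of the
same subjects, how taxon profiles cluster across the joint sample space,
and whether community types differ in any per-subject covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .abundance_io import AbundanceTable, PairedCohort
from .community_typing import DistanceMatrix
from .core_microbiome import CoreSet

logger = logging.getLogger("orogut")

__all__ = [
    "CorrelationResult", "GroupComparison", "Dendrogram",
    "spearman_matrix", "same_taxon_cross_site", "euclidean_profile_distance",
    "average_linkage", "bray_curtis_matrix", "pcoa", "permanova",
    "kruskal_wallis", "bh_adjust",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho / p / BH-adjusted p grid between two variable sets."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    alpha: float = 0.05

    def significant(self, level: float | None = None,
                    adjusted: bool = True) -> np.ndarray:
        """Boolean mask of significant cells (BH-adjusted by default)."""
        level = self.alpha if level is None else level
        mat = self.p_adjusted if adjusted else self.p
        with np.errstate(invalid="ignore"):
            return np.asarray(mat < level) & ~np.isnan(mat)

    def flags(self) -> np.ndarray:
        """Fig-style marks on raw p: ``**`` (<0.01), ``*`` (<0.05), ``''``."""
        out = np.full(self.p.shape, "", dtype=object)
        with np.errstate(invalid="ignore"):
            out[self.p < 0.05] = "*"
            out[self.p < 0.01] = "**"
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(self.row_ids),
                            columns=list(self.col_ids))

    def as_distance(self) -> DistanceMatrix:
        """1 - rho as a (pseudo-)distance; requires a square symmetric grid
        (e.g. a correlation matrix of one variable set against itself)."""
        if self.row_ids != self.col_ids:
            raise ValueError("1 - rho distance needs a square self-grid")
        d = 1.0 - self.rho
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(self.row_ids, (d + d.T) / 2,
                              metric_name="one-minus-spearman")


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis comparison of one variable across community types."""

    variable: str
    groups: tuple[str, ...]
    H: float
    p: float
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def df(self) -> int:
        return len(self.groups) - 1


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus recorded leaf order."""

    ids: tuple[str, ...]
    merges: np.ndarray          # (n-1, 4) scipy linkage matrix
    leaf_order: tuple[int, ...]

    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.ids)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.ids[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            # ultrametric: each child hangs at half the merge height
            la = h / 2 - height[a]
            lb = h / 2 - height[b]
            node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + step] = h / 2
        return node[n + len(self.merges) - 1] + ";"


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _rank_columns(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def spearman_matrix(x: AbundanceTable | pd.DataFrame,
                    y: AbundanceTable | pd.DataFrame,
                    alpha: float = 0.05) -> CorrelationResult:
    """All-pairs Spearman correlation between the columns of ``x`` and ``y``.

    Rho uses mid-ranks; two-sided p-values come from the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom;
    Benjamini-Hochberg adjustment is applied across every pair tested in
    this call.  A constant column yields undefined rho, recorded as NaN
    with a log entry.
    """
    xf = x.to_frame() if isinstance(x, AbundanceTable) else x
    yf = y.to_frame() if isinstance(y, AbundanceTable) else y
    if len(xf) != len(yf):
        raise ValueError("x and y must cover the same subjects in order")
    n = len(xf)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx, ry = _rank_columns(xf.to_numpy(float)), _rank_columns(yf.to_numpy(float))
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean(axis=0)
    sx = np.sqrt((rx_c ** 2).sum(axis=0))
    sy = np.sqrt((ry_c ** 2).sum(axis=0))
    const_x = sx == 0
    const_y = sy == 0
    for name in xf.columns[const_x]:
        logger.info("spearman_matrix: column %r constant; rho undefined", name)
    for name in yf.columns[const_y]:
        logger.info("spearman_matrix: column %r constant; rho undefined", name)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx_c.T @ ry_c) / np.outer(sx, sy)
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = np.nan
    rho[:, const_y] = np.nan
    p = _spearman_p(rho, n)
    p_adj = bh_adjust(p)
    return CorrelationResult(tuple(map(str, xf.columns)),
                             tuple(map(str, yf.columns)),
                             rho, p, p_adj, alpha=alpha)


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[np.isnan(rho)] = np.nan
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    if mask.any():
        _, adj, _, _ = multipletests(flat[mask], method="fdr_bh")
        res = out.ravel()
        res[mask] = adj
        out = res.reshape(p.shape)
    return out


def same_taxon_cross_site(cohort: PairedCohort, core: CoreSet,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Gut-vs-oral Spearman correlation of each core taxon across subjects.

    Returns one row per core taxon: ``taxon, rho, p, p_adjusted,
    significant`` (BH at ``alpha``).  Taxa with a constant profile at either
    site are kept with NaN statistics and logged.
    """
    if not core.core:
        raise ValueError("core set is empty")
    gut = cohort.gut.to_frame()
    oral = cohort.oral.to_frame()
    rows = []
    for taxon in core.core:
        gx = gut[taxon].to_numpy(float)
        ox = oral[taxon].to_numpy(float)
        if np.all(gx == gx[0]) or np.all(ox == ox[0]):
            logger.info("same_taxon_cross_site: %r constant at one site", taxon)
            rows.append((taxon, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(gx, ox)
        rows.append((taxon, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["taxon", "rho", "p"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p_adjusted"] < alpha).fillna(False)
    return df


# ---------------------------------------------------------------------------
# taxon-profile clustering (heatmap pipeline)
# ---------------------------------------------------------------------------

def euclidean_profile_distance(x: AbundanceTable,
                               y: AbundanceTable) -> DistanceMatrix:
    """Euclidean distances between taxon abundance profiles of two sites.

    Each object is one taxon at one site, tagged ``gut:<taxon>`` /
    ``oral:<taxon>``; its coordinates are that taxon's abundances across
    the shared, ordered subjects.  Both tables' taxa enter one joint
    distance matrix so cross-site profile similarity is directly visible.
    """
    if x.n_samples != y.n_samples:
        raise ValueError("profile dimensions differ between the two tables")
    ids = [f"{x.site}:{t}" for t in x.taxon_ids] + \
          [f"{y.site}:{t}" for t in y.taxon_ids]
    profiles = np.vstack([x.values.T, y.values.T])
    d = squareform(pdist(profiles, metric="euclidean"))
    return DistanceMatrix(tuple(ids), d, metric_name="euclidean")


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomerative clustering of a distance matrix."""
    if dist.n < 2:
        raise ValueError("need at least 2 objects to cluster")
    merges = linkage(dist.condensed(), method="average")
    order = tuple(int(i) for i in leaves_list(merges))
    return Dendrogram(dist.ids, merges, order)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples,
    ``1 - 2 sum(min) / (sum + sum)``, in [0, 1]."""
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(
            f"Bray-Curtis undefined for all-zero sample "
            f"{table.sample_ids[zero[0]]!r}")
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, metric_name="bray-curtis")


def pcoa(dist: DistanceMatrix, n_axes: int = 3
         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal coordinates analysis by Gower double-centering.

    Returns ``(coordinates, eigenvalues, explained)``: sample coordinates on
    the first ``n_axes`` positive-eigenvalue axes, ALL eigenvalues in
    descending order (negative ones reported, never embedded), and the
    fraction of positive inertia explained by each returned axis.
    """
    n = dist.n
    if n < n_axes + 1:
        raise ValueError(f"need at least {n_axes + 1} samples for {n_axes} axes")
    d2 = dist.values ** 2
    if not d2.any():
        raise ValueError("all distances are zero; ordination undefined")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval[0]), 0.0)
    n_pos = int(pos.sum())
    take = min(n_axes, n_pos)
    coords = eigvec[:, :take] * np.sqrt(eigval[:take])
    explained = eigval[:take] / eigval[:n_pos].sum()
    return coords, eigval, explained


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) with
    SS_total = sum_{i<j} d^2 / n and SS_within summed per group; the p-value
    counts permuted pseudo-F statistics at least as large as the observed
    one, ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    groups = np.asarray(groups)
    if len(groups) != dist.n:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 1:
        raise ValueError("every group must be non-empty")
    d2 = dist.values ** 2
    n = dist.n
    k = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    codes = np.searchsorted(labels, groups)

    def f_stat(codes_: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            idx = np.flatnonzero(codes_ == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub.sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def kruskal_wallis(values, groups, variable: str = "value") -> GroupComparison:
    """Kruskal-Wallis rank test of ``values`` across community types.

    Mid-rank ties correction via scipy; identical values in every group give
    H = 0, p = 1 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    means = {str(g): float(np.mean(s)) for g, s in zip(labels, samples)}
    return GroupComparison(variable=variable,
                           groups=tuple(map(str, labels)),
                           H=float(h), p=float(p), group_means=means)
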