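"""Community typing: the enterotype/orotype clustering engine.

Samples are stratified into discrete community types by

1. computing pairwise sqrt-Jensen-Shannon-divergence distances between
   relative genus-abundance profiles (sqrt-JSD is a true metric; a 1e-10
   pseudocount with renormalisation guards zero abundances),
2. partitioning around medoids (classical BUILD + SWAP, deterministic),
3. choosing the cluster number k that maximises the Calinski-Harabasz
   index, computed in a distance-only form that coincides with the
   familiar centroid form on Euclidean data,
4. judging significance of the optimal clustering by comparing its mean
   silhouette width against a null distribution obtained by independently
   permuting each taxon across samples (destroying inter-taxon structure
   while preserving every marginal), and
5. supporting the clustering with between-class analysis (BCA) and a
   per-type driver taxon: the genus most over-represented in each cluster.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.special import xlogy
from sklearn.metrics import silhouette_samples

from .abundance_io import AbundanceTable

logger = logging.getLogger("orogut")

#: pseudocount added (then renormalised away) before taking logarithms
PSEUDOCOUNT = 1e-10

__all__ = [
    "DistanceMatrix", "TypingSolution", "BCAResult",
    "shannon_entropy", "jsd", "jsd_distance_matrix",
    "pam", "ch_index", "select_k", "silhouette", "null_silhouette_test",
    "bca", "identify_drivers", "type_labels_frame",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with the ids they index."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(map(str, self.ids)))
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if vals.size:
            if np.abs(np.diag(vals)).max(initial=0.0) > 1e-12:
                raise ValueError("distance matrix diagonal must be zero")
            if np.abs(vals - vals.T).max(initial=0.0) > 1e-12:
                raise ValueError("distance matrix must be symmetric")
            if vals.min() < 0:
                raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class TypingSolution:
    """A chosen clustering of one site's samples into community types."""

    sample_ids: tuple[str, ...]
    k: int
    labels: np.ndarray                  # cluster index per sample
    medoids: tuple[str, ...]            # medoid sample ids, one per cluster
    ch_by_k: dict[int, float]
    mean_silhouette: float
    silhouette_p: float | None = None
    #: type name per cluster index; clusters numbered by descending size
    type_names: tuple[str, ...] = ()
    drivers: dict[str, str] | None = None
    metric_name: str = "sqrt-jsd"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("every cluster 0..k-1 must be non-empty")
        if len(self.medoids) != self.k:
            raise ValueError("medoid count must equal k")
        if self.k in self.ch_by_k:
            best = max(self.ch_by_k.values())
            if self.ch_by_k[self.k] < best - 1e-12:
                raise ValueError("chosen k must maximise the CH index")

    def type_of(self) -> list[str]:
        """Per-sample type names (falls back to cluster numbers)."""
        names = self.type_names or tuple(f"T{c + 1}" for c in range(self.k))
        return [names[c] for c in self.labels]

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "metric": self.metric_name,
            "labels": {s: int(c) for s, c in zip(self.sample_ids, self.labels)},
            "medoids": list(self.medoids),
            "ch_by_k": {str(k): v for k, v in sorted(self.ch_by_k.items())},
            "mean_silhouette": self.mean_silhouette,
            "silhouette_p": self.silhouette_p,
            "type_names": list(self.type_names),
            "drivers": self.drivers,
        }, indent=2)


@dataclass(frozen=True)
class BCAResult:
    """Between-class analysis: ordination of class means."""

    axes: np.ndarray                # taxa x n_axes loadings
    eigenvalues: np.ndarray         # descending, >= 0
    sample_scores: np.ndarray       # n x n_axes
    class_scores: np.ndarray        # k x n_axes
    between_inertia_ratio: float
    taxon_ids: tuple[str, ...] = ()
    classes: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def shannon_entropy(p) -> float:
    """Shannon entropy H(p) = -sum p_i ln p_i in nats, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if p.size and p.min() < 0:
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {total:.12g}")
    return float(-xlogy(p, p).sum())


def jsd(p, q) -> float:
    """Jensen-Shannon divergence in nats: H((p+q)/2) - (H(p)+H(q))/2.

    Symmetric, bounded by ln 2 (attained on disjoint supports).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    m = (p + q) / 2.0
    return float(max(shannon_entropy(m)
                     - 0.5 * (shannon_entropy(p) + shannon_entropy(q)), 0.0))


def _sqrt_jsd_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise sqrt-JSD between the rows of a non-negative matrix.

    Rows are regularised with the pseudocount and renormalised, so inputs
    need not lie exactly on the simplex (e.g. after low-abundance
    filtering).
    """
    p = np.asarray(values, dtype=float) + PSEUDOCOUNT
    p /= p.sum(axis=1, keepdims=True)
    h = -xlogy(p, p).sum(axis=1)                      # per-row entropy
    m = (p[:, None, :] + p[None, :, :]) / 2.0
    hm = -xlogy(m, m).sum(axis=2)
    div = hm - (h[:, None] + h[None, :]) / 2.0
    np.maximum(div, 0.0, out=div)
    np.fill_diagonal(div, 0.0)
    d = np.sqrt(div)
    return (d + d.T) / 2.0


def jsd_distance_matrix(table: AbundanceTable) -> DistanceMatrix:
    """sqrt-JSD distance matrix between a table's samples.

    Entry (i, j) is sqrt(JSD(p_i', p_j')) where p' adds a 1e-10 pseudocount
    and renormalises; sqrt-JSD satisfies the triangle inequality.
    """
    if table.mode != "relative":
        raise ValueError("jsd_distance_matrix requires a relative table")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    return DistanceMatrix(table.sample_ids, _sqrt_jsd_matrix(table.values),
                          metric_name="sqrt-jsd")


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------

#: below this many candidate medoid sets the k-medoids problem is solved
#: exactly by enumeration; BUILD+SWAP local search takes over beyond it
_EXACT_LIMIT = 300


def pam(dist: DistanceMatrix | np.ndarray, k: int
        ) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Partitioning around medoids.

    Returns ``(medoid_indices, labels, total_cost)``.  Tiny instances
    (at most ``_EXACT_LIMIT`` candidate medoid sets) are solved exactly by
    enumeration; larger ones use the classical BUILD + best-improvement
    SWAP local search, which stops when no single medoid/non-medoid
    exchange lowers the total distance-to-medoid cost.  Deterministic
    given the matrix: all ties break toward the lowest sample index.
    """
    import itertools
    from math import comb

    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    if comb(n, k) <= _EXACT_LIMIT:
        best_cost, best = np.inf, None
        for cand in itertools.combinations(range(n), k):
            cost = d[:, cand].min(axis=1).sum()
            if cost < best_cost:
                best_cost, best = cost, cand
        med = np.asarray(best)
        labels = np.argmin(d[:, med], axis=1)
        return tuple(best), labels, float(best_cost)

    # BUILD: greedy initialisation
    medoids = [int(np.argmin(d.sum(axis=0)))]
    d_near = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        np.minimum(d_near, d[:, c], out=d_near)

    medoids = sorted(medoids)
    while True:
        med = np.asarray(medoids)
        dm = d[:, med]                                 # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        n1 = med[order[:, 0]]
        d2 = dm[np.arange(n), order[:, 1]] if k > 1 else \
            np.full(n, np.inf)

        best = (0.0, None)
        base = d1.sum()
        for pos, m in enumerate(medoids):
            w = np.where(n1 == m, d2, d1)
            deltas = np.minimum(d, w[:, None]).sum(axis=0) - base
            deltas[med] = np.inf
            h = int(np.argmin(deltas))
            if deltas[h] < best[0] - 1e-12:
                best = (float(deltas[h]), (pos, h))
        if best[1] is None:
            break
        pos, h = best[1]
        medoids[pos] = h
        medoids = sorted(medoids)

    med = np.asarray(medoids)
    labels = np.argmin(d[:, med], axis=1)
    cost = float(d[np.arange(n), med[labels]].sum())
    return tuple(medoids), labels, cost


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def ch_index(dist: DistanceMatrix | np.ndarray, labels) -> float:
    """Calinski-Harabasz index computed from distances alone.

    W = sum over clusters of (1/(2 n_c)) sum_{i,j in c} d_ij^2 (ordered
    pairs), T = (1/(2n)) sum_{i,j} d_ij^2, B = T - W and
    CH = (B/(k-1)) / (W/(n-k)).  On Euclidean distances this equals the
    centroid-based index.  Coincident clusters (W = 0) return +inf.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    n = d.shape[0]
    clusters = np.unique(labels)
    k = len(clusters)
    if not 2 <= k <= n - 1:
        raise ValueError(f"need 2 <= k <= n-1 clusters, got k={k}, n={n}")
    d2 = d ** 2
    t = d2.sum() / (2 * n)
    w = 0.0
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    b = t - w
    if w <= 0.0:
        return float("inf")
    return float((b / (k - 1)) / (w / (n - k)))


def silhouette(dist: DistanceMatrix | np.ndarray, labels
               ) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths and their mean.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a the mean within-cluster
    distance (self excluded) and b the smallest mean distance to another
    cluster; members of singleton clusters score 0.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    vals = silhouette_samples(d, labels, metric="precomputed")
    return vals, float(vals.mean())


def _type_names(labels: np.ndarray, k: int, site: str) -> tuple[str, ...]:
    """Cluster-index -> display name, numbering clusters by descending size
    (ties toward the lower cluster index): E1..Ek for gut, O1..Ok for oral."""
    prefix = {"gut": "E", "oral": "O"}.get(site, "T")
    sizes = np.bincount(labels, minlength=k)
    by_size = sorted(range(k), key=lambda c: (-sizes[c], c))
    names = [""] * k
    for rank, c in enumerate(by_size):
        names[c] = f"{prefix}{rank + 1}"
    return tuple(names)


def select_k(dist: DistanceMatrix, k_range: tuple[int, int] = (2, 6),
             site: str = "other") -> TypingSolution:
    """Run PAM for every k in ``k_range`` and keep the CH-optimal solution.

    Ties break toward smaller k; the full CH profile is recorded in
    ``ch_by_k``.  ``silhouette_p`` is left unset (see
    :func:`null_silhouette_test`).
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo > hi:
        raise ValueError(f"empty k range {k_range}")
    if lo < 2 or hi > dist.n - 1:
        raise ValueError(f"k range must lie within [2, {dist.n - 1}]")
    ch_by_k: dict[int, float] = {}
    solutions = {}
    for k in range(lo, hi + 1):
        medoids, labels, _ = pam(dist, k)
        ch_by_k[k] = ch_index(dist, labels)
        solutions[k] = (medoids, labels)
    best_k = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    medoids, labels = solutions[best_k]
    _, mean_sil = silhouette(dist, labels)
    return TypingSolution(
        sample_ids=dist.ids, k=best_k, labels=labels,
        medoids=tuple(dist.ids[m] for m in medoids),
        ch_by_k=ch_by_k, mean_silhouette=mean_sil,
        type_names=_type_names(labels, best_k, site),
        metric_name=dist.metric_name or "sqrt-jsd")


def null_silhouette_test(table: AbundanceTable,
                         k_range: tuple[int, int] = (2, 6),
                         n_null: int = 99, seed: int = 0,
                         site: str = "other"
                         ) -> tuple[TypingSolution, float]:
    """Significance of the optimal clustering against a no-clustering null.

    The observed statistic is the mean silhouette of the CH-optimal
    clustering of ``table``.  Null datasets independently permute each
    taxon column across samples — inter-taxon structure (and hence any
    clustering) is destroyed while every taxon's marginal distribution is
    preserved — and pass through the identical distance/PAM/CH pipeline.
    Returns the observed solution with
    ``p = (1 + #{null >= observed}) / (1 + n_null)`` filled in.
    """
    if n_null < 19:
        raise ValueError("n_null must be at least 19")
    if table.mode != "relative":
        raise ValueError("null_silhouette_test requires a relative table")
    dist = jsd_distance_matrix(table)
    observed = select_k(dist, k_range, site=site)
    rng = np.random.default_rng(seed)
    exceed = 0
    values = table.values
    n = table.n_samples
    for _ in range(n_null):
        perm = np.empty_like(values)
        for j in range(values.shape[1]):
            perm[:, j] = values[rng.permutation(n), j]
        null_d = DistanceMatrix(table.sample_ids, _sqrt_jsd_matrix(perm),
                                metric_name="sqrt-jsd")
        null_sol = select_k(null_d, k_range, site=site)
        if null_sol.mean_silhouette >= observed.mean_silhouette:
            exceed += 1
    p = (1 + exceed) / (1 + n_null)
    return replace(observed, silhouette_p=float(p)), float(p)


# ---------------------------------------------------------------------------
# between-class analysis & drivers
# ---------------------------------------------------------------------------

def bca(table: AbundanceTable, labels, scale: bool = False) -> BCAResult:
    """Between-class analysis: eigenanalysis of class-size-weighted class
    means of the (column-centred, optionally scaled) abundance matrix.

    The leading axes are the taxon loadings that best separate the classes;
    ``between_inertia_ratio`` is the fraction of total inertia carried by
    the class means (0 with a single class, 1 when classes are internally
    homogeneous).
    """
    if table.mode != "relative":
        raise ValueError("bca requires a relative table")
    labels = np.asarray(labels)
    if len(labels) != table.n_samples:
        raise ValueError("one label per sample required")
    classes = np.unique(labels)
    x = table.values.astype(float)
    xc = x - x.mean(axis=0)
    if scale:
        sd = xc.std(axis=0)
        sd[sd == 0] = 1.0
        xc = xc / sd
    n = len(labels)
    g = np.vstack([xc[labels == c].mean(axis=0) for c in classes])
    w = np.array([(labels == c).sum() / n for c in classes])
    if np.any(w == 0):
        raise ValueError("every class must be non-empty")

    m = np.sqrt(w)[:, None] * g
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    n_axes = max(len(classes) - 1, 1)
    keep = min(n_axes, len(s))
    eigenvalues = (s ** 2)[:keep]
    axes = vt[:keep].T
    total = float((xc ** 2).sum() / n)
    between = float((w[:, None] * g ** 2).sum())
    ratio = 0.0 if total <= 0 else min(max(between / total, 0.0), 1.0)
    return BCAResult(axes=axes, eigenvalues=eigenvalues,
                     sample_scores=xc @ axes, class_scores=g @ axes,
                     between_inertia_ratio=ratio,
                     taxon_ids=table.taxon_ids,
                     classes=tuple(int(c) for c in classes))


def identify_drivers(table: AbundanceTable, solution: TypingSolution
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-type driver taxon and its abundance summary.

    The driver of a type is the taxon maximising (mean abundance within the
    type - mean abundance elsewhere), ties broken lexicographically.  The
    summary frame gives each driver's mean, quartiles and range per type.
    """
    if tuple(table.sample_ids) != tuple(solution.sample_ids):
        raise ValueError("table and solution must cover the same samples")
    labels = solution.labels
    x = table.values
    drivers: dict[str, str] = {}
    rows = []
    names = solution.type_names or tuple(f"T{c + 1}" for c in range(solution.k))
    taxa = np.asarray(table.taxon_ids)
    for c in range(solution.k):
        inside = labels == c
        mean_in = x[inside].mean(axis=0)
        mean_out = x[~inside].mean(axis=0) if (~inside).any() else \
            np.zeros_like(mean_in)
        score = mean_in - mean_out
        best = score.max()
        candidates = taxa[np.isclose(score, best, rtol=0, atol=1e-15)]
        driver = str(min(candidates))
        drivers[names[c]] = driver
        j = int(np.flatnonzero(taxa == driver)[0])
        for c2 in range(solution.k):
            vals = x[labels == c2, j]
            rows.append({
                "type": names[c2], "driver_of": names[c], "taxon": driver,
                "mean": float(vals.mean()),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.percentile(vals, 50)),
                "q3": float(np.percentile(vals, 75)),
                "min": float(vals.min()), "max": float(vals.max()),
            })
    summary = pd.DataFrame(rows)
    return drivers, summary


def type_labels_frame(solution: TypingSolution, site: str) -> pd.DataFrame:
    """Per-sample (sample_id, site, type) table for export."""
    return pd.DataFrame({
        "sample_id": list(solution.sample_ids),
        "site": site,
        "type": solution.type_of(),
    })
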