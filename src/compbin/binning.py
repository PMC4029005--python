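"""Composition-based contig binning by two independent routes with a
consensus-and-discard reconciliation.

Route 1 embeds the full composition matrix (GC + k-mer frequencies for
k = 2..5, z-scored) with PCA and runs best-of-``runs`` K-means (Euclidean,
k = 10 by default) on the components covering >= 90% of the variance.

Route 2 trains an emergent self-organizing map (ESOM) on z-scored
tetranucleotide frequencies: a large toroidal neuron grid is fitted by
online updates with a Gaussian neighborhood of decaying radius and
learning rate; the U-matrix (each neuron's mean weight distance to its
grid neighbors) then shows genomes as low-distance "valleys" separated by
high-distance "ridges", and connected valley components define clusters.

Both clusterings are labeled by majority vote over a partial taxon
annotation table, and the consensus keeps a contig's taxon only when the
two routes agree; contigs with conflicting taxa are DISCARDED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import (
    DegenerateThresholdError,
    EmptyInputError,
    ParameterError,
    UndefinedValueError,
)
from .features import Contig, FeatureMatrix
from .io import logger

__all__ = [
    "UNLABELED",
    "DISCARDED",
    "Embedding",
    "ClusterAssignment",
    "EsomMap",
    "BinAssignment",
    "pca_embed",
    "kmeans_best_of",
    "esom_train",
    "esom_clusters",
    "label_clusters",
    "consensus_bins",
    "agreement_fraction",
    "bin_summary",
]

UNLABELED = "UNLABELED"
DISCARDED = "DISCARDED"


# ---------------------------------------------------------------------------
# PCA / K-means route


@dataclass
class Embedding:
    """PCA embedding: coordinates, eigenvalues (descending) and loadings."""

    contig_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    component_loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def retained(self, variance: float) -> "Embedding":
        """The sub-embedding on the leading components whose summed
        variance ratio first reaches ``variance``."""
        if not 0.0 < variance <= 1.0:
            raise ParameterError("variance must lie in (0, 1]")
        cum = np.cumsum(self.explained_variance_ratio)
        n = int(np.searchsorted(cum, variance - 1e-12) + 1)
        n = min(n, self.coordinates.shape[1])
        return Embedding(
            contig_ids=list(self.contig_ids),
            coordinates=self.coordinates[:, :n],
            eigenvalues=self.eigenvalues[:n],
            component_loadings=self.component_loadings[:n],
            explained_variance_ratio=self.explained_variance_ratio[:n],
            mean=self.mean,
        )


def _matrix_and_ids(data, require_normalized: bool = False):
    if isinstance(data, FeatureMatrix):
        if require_normalized and not data.normalized:
            raise ParameterError("a normalized FeatureMatrix is required")
        return np.asarray(data.values, dtype=float), list(data.contig_ids)
    if isinstance(data, Embedding):
        return np.asarray(data.coordinates, dtype=float), list(data.contig_ids)
    arr = np.asarray(data, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def pca_embed(fm, n_components: int | None = None) -> Embedding:
    """Project onto the top eigenvectors of the feature covariance.

    Components are orthonormal and eigenvalues non-increasing; with all
    components retained, the centered data are reconstructed exactly.
    """
    values, ids = _matrix_and_ids(fm)
    n, d = values.shape
    if n < 2:
        raise ParameterError("PCA requires at least 2 rows")
    max_comp = min(n - 1, d)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ParameterError(
            f"n_components must lie in 1..{max_comp}, got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(values)
    ratio = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return Embedding(
        contig_ids=ids,
        coordinates=coords,
        eigenvalues=pca.explained_variance_.copy(),
        component_loadings=pca.components_.copy(),
        explained_variance_ratio=ratio,
        mean=pca.mean_.copy(),
    )


@dataclass
class ClusterAssignment:
    """A hard clustering of contigs; indices are contiguous from 0."""

    contig_ids: list[str]
    cluster: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    score: float = float("nan")
    cluster_taxa: dict[int, str] = field(default_factory=dict)
    label_support: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=int)
        if len(self.contig_ids) != self.cluster.size:
            raise ParameterError("one cluster index per contig required")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1 if self.cluster.size else 0

    def taxon_of(self, contig_id: str) -> str:
        idx = self.contig_ids.index(contig_id)
        return self.cluster_taxa.get(int(self.cluster[idx]), UNLABELED)

    def taxa(self) -> dict[str, str]:
        """Per-contig taxon labels (UNLABELED where the cluster has none)."""
        return {
            cid: self.cluster_taxa.get(int(c), UNLABELED)
            for cid, c in zip(self.contig_ids, self.cluster)
        }


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Re-index cluster labels to be contiguous from 0, preserving order of
    first appearance by original index."""
    uniq = np.unique(labels)
    remap = {int(u): i for i, u in enumerate(uniq)}
    return np.array([remap[int(x)] for x in labels], dtype=int)


def kmeans_best_of(data, k: int = 10, runs: int = 100, seed: int = 0) -> ClusterAssignment:
    """Euclidean K-means (Lloyd), best of ``runs`` seeded random
    initializations by within-cluster sum of squares."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if runs < 1:
        raise ParameterError("runs must be >= 1")
    values, ids = _matrix_and_ids(data)
    if values.shape[0] < k:
        raise ParameterError(f"need at least k={k} rows, got {values.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=runs,
        algorithm="lloyd",
        random_state=int(seed) % (2**32),
    )
    labels = km.fit_predict(values)
    return ClusterAssignment(
        contig_ids=ids,
        cluster=_compact_labels(labels),
        method="kmeans_pca",
        params={"k": k, "runs": runs, "seed": int(seed)},
        score=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# ESOM route


@dataclass
class EsomMap:
    """A trained self-organizing map on a toroidal grid."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows*cols, n_features)
    contig_ids: list[str]
    bmu: np.ndarray  # contig -> flat neuron index
    umatrix: np.ndarray  # (rows, cols)
    quantization_error: float
    epoch_errors: np.ndarray
    topology: str = "toroidal"

    def neuron_grid(self) -> np.ndarray:
        return self.weights.reshape(self.rows, self.cols, -1)


@njit(cache=True, fastmath=True)
def _som_fit(W, X, orders, rows, cols, lr0, lr1, rad0, rad1):
    """Online SOM training; returns the per-epoch mean BMU distance
    (quantization error measured at assignment time)."""
    epochs, n = orders.shape
    n_neurons, d = W.shape
    total_steps = epochs * n
    qe = np.zeros(epochs)
    step = 0
    for e in range(epochs):
        if epochs > 1:
            sigma = rad0 + (rad1 - rad0) * e / (epochs - 1)
        else:
            sigma = rad0
        cutoff2 = (3.0 * sigma) * (3.0 * sigma)
        two_sigma2 = 2.0 * sigma * sigma
        acc = 0.0
        for ii in range(n):
            i = orders[e, ii]
            if total_steps > 1:
                lr = lr0 + (lr1 - lr0) * step / (total_steps - 1)
            else:
                lr = lr0
            # best-matching unit
            best = 0
            best_d = 1e300
            for m in range(n_neurons):
                s = 0.0
                for f in range(d):
                    diff = W[m, f] - X[i, f]
                    s += diff * diff
                if s < best_d:
                    best_d = s
                    best = m
            acc += np.sqrt(best_d)
            br = best // cols
            bc = best % cols
            # neighborhood update with toroidal wrap-around
            for r in range(rows):
                dr = r - br
                if dr < 0:
                    dr = -dr
                if rows - dr < dr:
                    dr = rows - dr
                for c in range(cols):
                    dc = c - bc
                    if dc < 0:
                        dc = -dc
                    if cols - dc < dc:
                        dc = cols - dc
                    d2 = float(dr * dr + dc * dc)
                    if d2 > cutoff2:
                        continue
                    h = lr * np.exp(-d2 / two_sigma2)
                    m = r * cols + c
                    for f in range(d):
                        W[m, f] += h * (X[i, f] - W[m, f])
            step += 1
        qe[e] = acc / n
    return qe


def _toroidal_umatrix(weights: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Mean Euclidean distance of each neuron's weight vector to its eight
    grid neighbors, with wrap-around."""
    grid = weights.reshape(rows, cols, -1)
    total = np.zeros((rows, cols))
    count = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
            total += np.sqrt(((grid - shifted) ** 2).sum(axis=2))
            count += 1
    return total / count


def esom_train(
    tetra_fm,
    rows: int = 50,
    cols: int = 82,
    epochs: int = 20,
    seed: int = 0,
    lr: tuple[float, float] = (0.5, 0.05),
    radius: tuple[float, float] | None = None,
) -> EsomMap:
    """Train an emergent SOM on (normalized) tetranucleotide frequencies.

    Per epoch the contigs are visited in a seeded shuffled order; each
    contig's best-matching unit pulls nearby neuron weights toward it with
    a Gaussian neighborhood whose radius decays linearly from
    ``max(rows, cols)/2`` to 1 across epochs, while the learning rate
    decays linearly across all steps.
    """
    if rows < 2 or cols < 2:
        raise ParameterError("SOM grid must be at least 2x2")
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    X, ids = _matrix_and_ids(tetra_fm)
    n, d = X.shape
    if n < 1:
        raise EmptyInputError("no contigs to train on")
    if radius is None:
        radius = (max(rows, cols) / 2.0, 1.0)
    rng = np.random.default_rng(seed)
    n_neurons = rows * cols
    # initialize neurons from random data points with small jitter
    init_idx = rng.integers(0, n, size=n_neurons)
    scale = X.std() if X.std() > 0 else 1.0
    W = X[init_idx] + rng.normal(0.0, 0.01 * scale, size=(n_neurons, d))
    orders = np.empty((epochs, n), dtype=np.int64)
    for e in range(epochs):
        orders[e] = rng.permutation(n)

    W32 = np.ascontiguousarray(W, dtype=np.float64)
    X64 = np.ascontiguousarray(X, dtype=np.float64)
    epoch_errors = _som_fit(
        W32, X64, orders, rows, cols,
        float(lr[0]), float(lr[1]), float(radius[0]), float(radius[1]),
    )

    # final BMU assignment and quantization error with frozen weights
    d2 = (
        (X64**2).sum(axis=1)[:, None]
        - 2.0 * X64 @ W32.T
        + (W32**2).sum(axis=1)[None, :]
    )
    bmu = np.argmin(d2, axis=1)
    qe = float(np.sqrt(np.maximum(d2[np.arange(n), bmu], 0.0)).mean())
    umatrix = _toroidal_umatrix(W32, rows, cols)
    logger.info(
        "ESOM %dx%d trained for %d epochs; quantization error %.4f",
        rows, cols, epochs, qe,
    )
    return EsomMap(
        rows=rows,
        cols=cols,
        weights=W32,
        contig_ids=ids,
        bmu=bmu,
        umatrix=umatrix,
        quantization_error=qe,
        epoch_errors=np.asarray(epoch_errors),
    )


def _toroidal_components(valley: np.ndarray) -> np.ndarray:
    """Connected components (8-connectivity) of a boolean grid on a torus;
    returns an int grid with -1 outside valleys and component ids from 0."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(valley, structure=structure)
    if n == 0:
        return np.full(valley.shape, -1, dtype=int)
    # merge components that touch across the wrapped edges
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    rows, cols = valley.shape
    for j in range(cols):
        for dj in (-1, 0, 1):
            jj = (j + dj) % cols
            if labels[0, j] and labels[rows - 1, jj]:
                union(labels[0, j], labels[rows - 1, jj])
    for i in range(rows):
        for di in (-1, 0, 1):
            ii = (i + di) % rows
            if labels[i, 0] and labels[ii, cols - 1]:
                union(labels[i, 0], labels[ii, cols - 1])

    roots = sorted({find(x) for x in range(1, n + 1)})
    remap = {r: i for i, r in enumerate(roots)}
    out = np.full(valley.shape, -1, dtype=int)
    nz = labels > 0
    flat = np.array([remap[find(int(x))] for x in labels[nz]])
    out[nz] = flat
    return out


def _toroidal_grid_distance2(rows: int, cols: int, r0: int, c0: int) -> np.ndarray:
    dr = np.abs(np.arange(rows) - r0)
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(np.arange(cols) - c0)
    dc = np.minimum(dc, cols - dc)
    return dr[:, None] ** 2 + dc[None, :] ** 2


def esom_clusters(som: EsomMap, ridge_quantile: float = 0.6) -> ClusterAssignment:
    """Extract clusters from the U-matrix: neurons below the
    ``ridge_quantile`` U-value form valleys; connected valley components
    (toroidal adjacency) define clusters.  Contigs whose BMU sits on a
    ridge join the nearest valley component by grid distance (ties break
    toward the lower component index)."""
    if not 0.0 < ridge_quantile <= 1.0:
        raise ParameterError("ridge_quantile must lie in (0, 1]")
    threshold = np.quantile(som.umatrix, ridge_quantile)
    valley = som.umatrix <= threshold
    if not valley.any():
        raise DegenerateThresholdError("no valley neuron below the threshold")
    comp = _toroidal_components(valley)

    n = len(som.contig_ids)
    raw = np.empty(n, dtype=int)
    for i in range(n):
        r, c = divmod(int(som.bmu[i]), som.cols)
        if comp[r, c] >= 0:
            raw[i] = comp[r, c]
        else:
            d2 = _toroidal_grid_distance2(som.rows, som.cols, r, c)
            d2 = np.where(comp >= 0, d2, np.inf)
            flat_d2 = d2.ravel()
            flat_comp = comp.ravel()
            nearest = flat_d2.min()
            # ties break toward the lower component index
            raw[i] = int(flat_comp[flat_d2 == nearest].min())

    return ClusterAssignment(
        contig_ids=list(som.contig_ids),
        cluster=_compact_labels(raw),
        method="esom",
        params={
            "rows": som.rows,
            "cols": som.cols,
            "ridge_quantile": ridge_quantile,
        },
        score=som.quantization_error,
    )


# ---------------------------------------------------------------------------
# labeling, consensus, summary


def label_clusters(
    ca: ClusterAssignment,
    labels: Mapping[str, str],
    min_frac: float = 0.5,
) -> ClusterAssignment:
    """Give each cluster the majority taxon among its labeled members.

    The majority must exceed ``min_frac`` of the cluster's labeled members
    (strict, so a 50/50 tie at the default stays UNLABELED).  Returns a new
    ClusterAssignment carrying per-cluster taxa and label support.
    """
    if not 0.0 <= min_frac < 1.0:
        raise ParameterError("min_frac must lie in [0, 1)")
    if not labels:
        logger.warning("empty label table: all clusters UNLABELED")
    votes: dict[int, dict[str, int]] = {}
    for cid, cluster in zip(ca.contig_ids, ca.cluster):
        taxon = labels.get(cid)
        if taxon is not None:
            votes.setdefault(int(cluster), {}).setdefault(taxon, 0)
            votes[int(cluster)][taxon] += 1
    cluster_taxa: dict[int, str] = {}
    support: dict[int, float] = {}
    for cluster in range(ca.n_clusters):
        tally = votes.get(cluster, {})
        total = sum(tally.values())
        if total == 0:
            cluster_taxa[cluster] = UNLABELED
            support[cluster] = 0.0
            continue
        best_count = max(tally.values())
        winners = sorted(t for t, c in tally.items() if c == best_count)
        frac = best_count / total
        if frac > min_frac and len(winners) == 1:
            cluster_taxa[cluster] = winners[0]
        else:
            cluster_taxa[cluster] = UNLABELED
        support[cluster] = frac
    return ClusterAssignment(
        contig_ids=list(ca.contig_ids),
        cluster=ca.cluster.copy(),
        method=ca.method,
        params=dict(ca.params, min_frac=min_frac),
        score=ca.score,
        cluster_taxa=cluster_taxa,
        label_support=support,
    )


@dataclass
class BinAssignment:
    """Per-contig taxon bin, DISCARDED on route disagreement, or UNLABELED
    when neither route could name a taxon."""

    assignments: dict[str, str]
    single_route: set[str]
    dropped: list[str]
    provenance: tuple[ClusterAssignment, ClusterAssignment] | None = None

    @property
    def discarded(self) -> list[str]:
        return [c for c, t in self.assignments.items() if t == DISCARDED]

    def binned(self) -> dict[str, str]:
        """Contigs that received a real taxon."""
        return {
            c: t
            for c, t in self.assignments.items()
            if t not in (DISCARDED, UNLABELED)
        }


def consensus_bins(a: ClusterAssignment, b: ClusterAssignment) -> BinAssignment:
    """Reconcile two labeled clusterings on their shared contig universe.

    Agreeing taxa are kept; conflicting taxa are DISCARDED; if exactly one
    route is UNLABELED the other route's taxon is adopted and flagged as
    single-route.
    """
    taxa_a = a.taxa()
    taxa_b = b.taxa()
    shared = sorted(set(taxa_a) & set(taxa_b))
    if not shared:
        raise EmptyInputError("the two clusterings share no contigs")
    dropped = sorted((set(taxa_a) | set(taxa_b)) - set(shared))
    assignments: dict[str, str] = {}
    single: set[str] = set()
    for cid in shared:
        ta, tb = taxa_a[cid], taxa_b[cid]
        if ta == UNLABELED and tb == UNLABELED:
            assignments[cid] = UNLABELED
        elif ta == UNLABELED:
            assignments[cid] = tb
            single.add(cid)
        elif tb == UNLABELED:
            assignments[cid] = ta
            single.add(cid)
        elif ta == tb:
            assignments[cid] = ta
        else:
            assignments[cid] = DISCARDED
    n_disc = sum(1 for t in assignments.values() if t == DISCARDED)
    logger.info(
        "consensus: %d contigs, %d discarded, %d single-route",
        len(shared), n_disc, len(single),
    )
    return BinAssignment(
        assignments=assignments,
        single_route=single,
        dropped=dropped,
        provenance=(a, b),
    )


def agreement_fraction(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Fraction of contigs, among those with a (non-UNLABELED) taxon from
    both routes, on which the two routes give the same taxon."""
    taxa_a = a.taxa()
    taxa_b = b.taxa()
    shared = set(taxa_a) & set(taxa_b)
    both = [
        cid
        for cid in shared
        if taxa_a[cid] != UNLABELED and taxa_b[cid] != UNLABELED
    ]
    if not both:
        raise UndefinedValueError("no contig labeled by both routes")
    same = sum(1 for cid in both if taxa_a[cid] == taxa_b[cid])
    return same / len(both)


def bin_summary(bins: BinAssignment, contigs: Sequence[Contig]) -> pd.DataFrame:
    """Per-taxon contig count, total bases (exact and MB at 2 dp) and mean
    coverage where available; DISCARDED/UNLABELED rows included."""
    by_id = {c.id: c for c in contigs}
    rows: dict[str, dict] = {}
    for cid, taxon in bins.assignments.items():
        contig = by_id.get(cid)
        if contig is None:
            continue
        entry = rows.setdefault(
            taxon, {"contig_count": 0, "total_bases": 0, "_cov": []}
        )
        entry["contig_count"] += 1
        entry["total_bases"] += contig.length
        if contig.coverage is not None:
            entry["_cov"].append(contig.coverage)
    records = []
    for taxon in sorted(rows):
        entry = rows[taxon]
        records.append(
            {
                "taxon": taxon,
                "contig_count": entry["contig_count"],
                "total_bases": entry["total_bases"],
                "total_mb": round(entry["total_bases"] / 1e6, 2),
                "mean_coverage": (
                    float(np.mean(entry["_cov"])) if entry["_cov"] else np.nan
                ),
            }
        )
    return pd.DataFrame.from_records(records).set_index("taxon")
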