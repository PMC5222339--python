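"""Ordination and network views of the MLG-level genotype space.

Two band/allele-sharing dissimilarities between multi-locus genotypes feed
(1) a principal-coordinates ordination (classical metric MDS via Gower
double-centering) and (2) a clone network thresholded at the percolation
point — the smallest distance at which the graph becomes connected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .genotype_io import AllelePair, MISSING
from .discrimination import ClonalPartition


class MultivariateError(ValueError):
    pass


def dice_distance(genotypes: dict[str, tuple[AllelePair, ...]]
                  ) -> tuple[list[str], np.ndarray]:
    """Dice (Sorensen) dissimilarity on (locus, allele) band presences.

    Each MLG is scored as the set of bands it shows — a homozygote
    contributes one band at that locus, a heterozygote two;
    d(A,B) = 1 - 2|A n B| / (|A| + |B|).
    """
    ids = sorted(genotypes)
    bands = []
    for i in ids:
        g = genotypes[i]
        if any(p is MISSING for p in g):
            raise MultivariateError(f"MLG {i}: incomplete genotype")
        bands.append({(k, a) for k, pair in enumerate(g) for a in set(pair)})
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        inter = len(bands[i] & bands[j])
        d[i, j] = d[j, i] = 1.0 - 2.0 * inter / (len(bands[i]) +
                                                 len(bands[j]))
    return ids, d


def shared_allele_distance(genotypes: dict[str, tuple[AllelePair, ...]]
                           ) -> tuple[list[str], np.ndarray]:
    """D_AS = 1 - (shared allele copies)/(2L), multiset overlap per locus."""
    ids = sorted(genotypes)
    glist = [genotypes[i] for i in ids]
    n_loci = len(glist[0])
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        shared = 0
        for k in range(n_loci):
            p1, p2 = glist[i][k], glist[j][k]
            if p1 is MISSING or p2 is MISSING:
                raise MultivariateError("incomplete genotype")
            a1, a2 = p1
            b1, b2 = p2
            # multiset intersection of two unordered pairs (0, 1 or 2)
            shared += max(int(a1 == b1) + int(a2 == b2),
                          int(a1 == b2) + int(a2 == b1))
        d[i, j] = d[j, i] = 1.0 - shared / (2.0 * n_loci)
    return ids, d


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray       # (n, n_axes)
    eigenvalues: np.ndarray       # all eigenvalues, decreasing
    percent_variance: np.ndarray  # per retained axis, over positive eigs


def pcoa(distance: np.ndarray, ids: list[str] | None = None,
         n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates of a dissimilarity matrix.

    Gower centering of -d^2/2, eigendecomposition, coordinates scaled by
    sqrt(eigenvalue).  Axes are ordered by decreasing eigenvalue; variance
    percentages are taken over positive eigenvalues only (non-Euclidean
    dissimilarities produce negative ones, which are reported but carry no
    coordinates).
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MultivariateError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise MultivariateError("distance matrix must be symmetric")
    n = d.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_keep = min(n_axes, int(pos.sum()))
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    total_pos = eigvals[pos].sum()
    pct = (100.0 * eigvals[:n_keep] / total_pos) if total_pos > 0 \
        else np.zeros(n_keep)
    return OrdinationResult(ids=list(ids), coordinates=coords,
                            eigenvalues=eigvals, percent_variance=pct)


@dataclass
class CloneNetwork:
    graph: nx.Graph
    threshold: float
    ids: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def percolation_threshold(distance: np.ndarray) -> float:
    """Smallest edge weight at which the thresholded graph is connected.

    Binary search over the sorted unique off-diagonal weights; at the
    returned value, keeping edges with d <= threshold yields one component.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    weights = np.unique(d[iu])

    def connected(t: float) -> bool:
        g = nx.from_numpy_array(np.where(d <= t, 1, 0) - np.eye(n, dtype=int))
        return nx.is_connected(g)

    lo, hi = 0, len(weights) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(weights[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(weights[lo])


def build_network(distance: np.ndarray, ids: list[str],
                  node_sizes: dict[str, int] | None = None,
                  site_composition: dict[str, dict[str, int]] | None = None,
                  threshold: float | None = None) -> CloneNetwork:
    """Clone network: nodes are MLGs, edges join pairs at d <= threshold.

    Without an explicit threshold the percolation threshold is used — the
    sparsest graph that still connects every MLG.  Node attributes carry
    ramet counts and per-site composition for plotting downstream.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if threshold is None:
        threshold = percolation_threshold(d) if n > 1 else 0.0
    g = nx.Graph()
    for i, mid in enumerate(ids):
        attrs: dict = {}
        if node_sizes is not None:
            attrs["size"] = node_sizes.get(mid, 0)
        if site_composition is not None:
            for site, cnt in site_composition.get(mid, {}).items():
                attrs[f"n_{site}"] = cnt
        g.add_node(mid, **attrs)
    for i, j in itertools.combinations(range(n), 2):
        if d[i, j] <= threshold:
            g.add_edge(ids[i], ids[j], weight=float(d[i, j]))
    return CloneNetwork(graph=g, threshold=float(threshold), ids=list(ids))


def mlg_site_composition(partition: ClonalPartition,
                         site_of: dict[str, str]
                         ) -> dict[str, dict[str, int]]:
    """Per-MLG ramet counts by site, for network node annotation."""
    out: dict[str, dict[str, int]] = {m: {} for m in partition.mlg_genotype}
    for sid, mlg in partition.mlg_of.items():
        site = site_of[sid]
        out[mlg][site] = out[mlg].get(site, 0) + 1
    return out
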