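"""Permutation-tested spatial statistics of clonal structure.

Within a mapped site three questions are asked of the clone mosaic:

* aggregation (Ac) — are nearest neighbours clonemates more often than the
  all-pairs clonemate rate predicts?  Positive Ac is the signature of local
  fragmentation-driven spread.
* edge effect (Ee) — do singleton genotypes (putative sexual recruits) sit
  closer to the edge of the sampled area than the average colony?
* Moran's I — is genetic similarity (per-allele frequencies within
  individuals) correlated with spatial proximity?

Significance comes from label/coordinate permutations with the
(b + 1)/(m + 1) p-value estimator, so a recorded seed makes every p-value
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotype_io import GenotypeTable, MISSING


class SpatialError(ValueError):
    pass


@dataclass
class SpatialReport:
    population: str
    ac: float | None
    p_ac: float | None
    ee: float | None
    p_ee: float | None
    morans_i: float | None
    p_i: float | None
    n_permutations: int
    seed: int


def _perm_p(null: np.ndarray, observed: float, alternative: str) -> float:
    """(b+1)/(m+1) permutation p-value.

    "greater": b = #{null >= obs}; "two-sided": doubled smaller tail,
    capped at 1.
    """
    m = null.size
    if alternative == "greater":
        b = int(np.sum(null >= observed))
        return (b + 1) / (m + 1)
    if alternative == "two-sided":
        p_hi = (int(np.sum(null >= observed)) + 1) / (m + 1)
        p_lo = (int(np.sum(null <= observed)) + 1) / (m + 1)
        return min(1.0, 2.0 * min(p_hi, p_lo))
    raise ValueError(alternative)


def _nearest_neighbour(coords: np.ndarray) -> np.ndarray:
    """Index of each point's nearest neighbour (ties -> lowest index)."""
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return np.argmin(d, axis=1)


def aggregation_index(coords: np.ndarray, mlg_labels: np.ndarray,
                      n_perm: int = 1000, seed: int = 0
                      ) -> tuple[float, float]:
    """Ac = (P_nn - P_all)/(1 - P_all) with a one-sided permutation test.

    P_all is the clonemate fraction among all unordered pairs, P_nn the
    fraction of colonies whose nearest neighbour shares their MLG.  Ac is 0
    in expectation when clone labels are spatially random and 1 when every
    nearest neighbour is a clonemate.  The null shuffles MLG labels over
    the fixed coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(mlg_labels)
    n = len(labels)
    if coords.shape[0] != n or n < 3:
        raise SpatialError("need >= 3 samples with coordinates")
    _, counts = np.unique(labels, return_counts=True)
    if counts.max() < 2:
        raise SpatialError("aggregation undefined without clonemates")
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    p_all = float(same[iu].mean())
    nn = _nearest_neighbour(coords)

    def _ac(lab: np.ndarray) -> float:
        p_nn = float(np.mean(lab == lab[nn]))
        return (p_nn - p_all) / (1.0 - p_all)

    observed = _ac(labels)
    rng = np.random.default_rng(seed)
    null = np.array([_ac(rng.permutation(labels)) for _ in range(n_perm)])
    return observed, _perm_p(null, observed, "greater")


def edge_effect(coords: np.ndarray, mlg_labels: np.ndarray,
                n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Ee = (D_uniq - D_all)/D_all with a one-sided permutation test.

    D_all is the mean distance of all colonies to the sample centroid,
    D_uniq the same mean over colonies carrying singleton MLGs.  Positive
    Ee means unique genotypes concentrate toward the periphery; the
    one-sided null (labels shuffled) tests that direction.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(mlg_labels)
    n = len(labels)
    if coords.shape[0] != n or n < 3:
        raise SpatialError("need >= 3 samples with coordinates")
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() > 1:
        raise SpatialError("edge effect undefined without singleton MLGs")
    centroid = coords.mean(axis=0)
    dist_c = np.linalg.norm(coords - centroid, axis=1)
    d_all = float(dist_c.mean())
    if d_all == 0:
        raise SpatialError("all samples coincident")
    singleton_label = {u for u, c in zip(uniq, counts) if c == 1}

    def _ee(lab: np.ndarray) -> float:
        mask = np.array([l in singleton_label for l in lab])
        return (float(dist_c[mask].mean()) - d_all) / d_all

    observed = _ee(labels)
    rng = np.random.default_rng(seed)
    null = np.array([_ee(rng.permutation(labels)) for _ in range(n_perm)])
    return observed, _perm_p(null, observed, "greater")


def _allele_dosage(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample allele dosages x_i in [0, 1] for every (locus, allele).

    Returns (X of shape samples x alleles, column variances); zero-variance
    columns (alleles fixed or absent in the site) are dropped.
    """
    cols: list[np.ndarray] = []
    for k in range(len(table.loci)):
        alleles = sorted({a for s in table.samples
                          if s.genotype[k] is not MISSING
                          for a in s.genotype[k]})
        for a in alleles:
            x = np.array([
                np.nan if s.genotype[k] is MISSING
                else s.genotype[k].count(a) / 2.0
                for s in table.samples])
            cols.append(x)
    if not cols:
        raise SpatialError("no scorable alleles")
    x_mat = np.column_stack(cols)
    # missing dosages imputed at the column mean: neutral for covariance
    col_mean = np.nanmean(x_mat, axis=0)
    nan_mask = np.isnan(x_mat)
    x_mat[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    var = x_mat.var(axis=0)
    keep = var > 0
    if not np.any(keep):
        raise SpatialError("all alleles monomorphic in this population")
    return x_mat[:, keep], var[keep]


def morans_i(coords: np.ndarray, table: GenotypeTable,
             n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Variance-weighted multi-allele Moran's I with inverse-distance weights.

    Per (locus, allele) column x (dosage per individual), Moran's
    I_a = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i-xbar)^2
    with w_ij = 1/d_ij (coincident pairs get the minimum positive
    distance); the report is the allele-variance-weighted mean over
    columns.  The two-sided null permutes the coordinate assignment.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise SpatialError("need >= 4 samples with coordinates")
    d = squareform(pdist(coords))
    pos = d[d > 0]
    if pos.size == 0:
        raise SpatialError("all samples coincident")
    d[d == 0] = pos.min()
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w_sum = w.sum()

    x_mat, var = _allele_dosage(table)
    xc = x_mat - x_mat.mean(axis=0)
    denom = np.sum(xc ** 2, axis=0)
    weights = var / var.sum()

    def _stat(perm: np.ndarray) -> float:
        xp = xc[perm]
        num = np.sum(xp * (w @ xp), axis=0)
        return float(np.sum(weights * (n / w_sum) * num / denom))

    identity = np.arange(n)
    observed = _stat(identity)
    rng = np.random.default_rng(seed)
    null = np.array([_stat(rng.permutation(n)) for _ in range(n_perm)])
    return observed, _perm_p(null, observed, "two-sided")


def spatial_report(table: GenotypeTable, mlg_of: dict[str, str],
                   n_perm: int = 1000, seed: int = 0) -> list[SpatialReport]:
    """Run Ac, Ee and Moran's I per site; sites without coordinates or with
    degenerate clone structure report None for the affected statistics."""
    reports = []
    for site in table.sites:
        sub = table.for_site(site)
        with_xy = [s for s in sub.samples if s.has_coords]
        if len(with_xy) < 4:
            reports.append(SpatialReport(site, None, None, None, None,
                                         None, None, n_perm, seed))
            continue
        coords = np.array([[s.x, s.y] for s in with_xy])
        labels = np.array([mlg_of[s.id] for s in with_xy])
        sub_xy = sub.subset(s.id for s in with_xy)
        try:
            ac, p_ac = aggregation_index(coords, labels, n_perm, seed)
        except SpatialError:
            ac = p_ac = None
        try:
            ee, p_ee = edge_effect(coords, labels, n_perm, seed)
        except SpatialError:
            ee = p_ee = None
        try:
            mi, p_i = morans_i(coords, sub_xy, n_perm, seed)
        except SpatialError:
            mi = p_i = None
        reports.append(SpatialReport(site, ac, p_ac, ee, p_ee, mi, p_i,
                                     n_perm, seed))
    return reports
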