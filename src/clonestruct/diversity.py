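"""Clonal-diversity and within-population diversity indices.

Per population: clonal richness R, genotypic diversity G_O and G, Simpson
evenness ED*, the Pareto exponent of the clone-size spectrum, rarefied
allelic richness, and observed/expected heterozygosities on the genet-level
(truncated) dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotype_io import GenotypeTable, GenotypeError, MISSING
from .discrimination import ClonalPartition


class DiversityError(ValueError):
    pass


def clonal_richness(n_samples: int, n_mlg: int) -> float:
    """R = (N_MLG - 1)/(N - 1): 0 monoclonal, 1 all genotypes distinct."""
    if n_samples < 1 or not 1 <= n_mlg <= n_samples:
        raise DiversityError(
            f"need 1 <= n_mlg <= n_samples, got ({n_samples}, {n_mlg})")
    if n_samples == 1:
        return 0.0
    return (n_mlg - 1) / (n_samples - 1)


def genotypic_diversity(clone_sizes: list[int]) -> tuple[float, float]:
    """(G_O, G): inverse Simpson concentration and its ratio to N.

    G_O = 1 / sum p_i^2 is the effective number of clones; G = G_O / N
    spans (0, 1], 1 in a fully sexual sample and ->0 in a monoclonal one.
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size == 0 or np.any(sizes < 1):
        raise DiversityError("clone sizes must be positive integers")
    n = sizes.sum()
    p = sizes / n
    g_o = 1.0 / float(np.sum(p ** 2))
    return g_o, g_o / float(n)


def simpson_evenness(clone_sizes: list[int]) -> float:
    """ED*: unbiased Simpson diversity rescaled between the least- and
    most-even clone-size configurations with the same N and G.

    D = 1 - sum n_i(n_i-1)/(N(N-1)); D_max from sizes differing by at most
    one; D_min from one clone of N-G+1 plus G-1 singletons.
    """
    sizes = np.asarray(sorted(clone_sizes, reverse=True), dtype=int)
    g = sizes.size
    n = int(sizes.sum())
    if g < 2:
        raise DiversityError("ED* undefined for a single clone")
    if n <= g:
        raise DiversityError(
            "ED* undefined when all clones are singletons (D_max = D_min)")

    def _d(s: np.ndarray) -> float:
        return 1.0 - float(np.sum(s * (s - 1))) / (n * (n - 1))

    base, extra = divmod(n, g)
    most_even = np.array([base + 1] * extra + [base] * (g - extra))
    least_even = np.array([n - g + 1] + [1] * (g - 1))
    d, d_max, d_min = _d(sizes), _d(most_even), _d(least_even)
    return (d - d_min) / (d_max - d_min)


def pareto_beta(clone_sizes: list[int]
                ) -> tuple[float, float, np.ndarray]:
    """Power-law exponent of the clone-size spectrum.

    Ordinary least squares of log(fraction of clones of size >= x) on
    log(x) over the distinct observed sizes; beta = -slope.  Returns
    (beta, r_squared, points) with points as (x, cumulative fraction) rows.
    Steep slopes (large beta) mean many small clones; shallow slopes a few
    dominant ones.
    """
    sizes = np.asarray(clone_sizes, dtype=int)
    if sizes.size == 0 or np.any(sizes < 1):
        raise DiversityError("clone sizes must be positive integers")
    xs = np.unique(sizes)
    if xs.size < 2:
        raise DiversityError(
            "Pareto slope undefined with a single distinct clone size")
    frac = np.array([(sizes >= x).mean() for x in xs])
    lx, ly = np.log(xs.astype(float)), np.log(frac)
    design = np.column_stack([lx, np.ones_like(lx)])
    coef, *_ = np.linalg.lstsq(design, ly, rcond=None)
    slope, intercept = coef
    fitted = design @ coef
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return -float(slope), r2, np.column_stack([xs, frac])


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)


def allelic_richness(allele_counts: dict[str, dict[int, int]],
                     g: int) -> float:
    """Rarefied allelic richness: expected alleles per locus in g genes.

    Hypergeometric rarefaction: per locus sum over alleles of
    1 - C(2n - n_a, g)/C(2n, g), averaged across loci.  ``allele_counts``
    maps locus -> allele size -> copy count (2n copies per locus).
    """
    per_locus = []
    for locus, counts in allele_counts.items():
        total = sum(counts.values())
        if g > total:
            raise DiversityError(
                f"rarefaction size {g} exceeds {total} genes at {locus}")
        na = np.array(list(counts.values()), dtype=int)
        # P(allele absent from a sample of g genes) = C(2n-na, g)/C(2n, g)
        with np.errstate(invalid="ignore"):
            log_absent = _log_comb(total - na, g) - _log_comb(total, g)
        p_absent = np.where(total - na < g, 0.0, np.exp(log_absent))
        per_locus.append(float(np.sum(1.0 - p_absent)))
    if not per_locus:
        raise DiversityError("no loci provided")
    return float(np.mean(per_locus))


def allele_count_table(table: GenotypeTable) -> dict[str, dict[int, int]]:
    """Allele copy counts per locus over all samples in the table."""
    out: dict[str, dict[int, int]] = {l.name: {} for l in table.loci}
    for s in table.samples:
        for k, locus in enumerate(table.loci):
            pair = s.genotype[k]
            if pair is MISSING:
                continue
            for a in pair:
                out[locus.name][a] = out[locus.name].get(a, 0) + 1
    return out


def heterozygosities(table: GenotypeTable
                     ) -> tuple[float, float, dict[str, tuple[float, float]]]:
    """(mean H_O, mean H_E, per-locus {name: (H_O, H_E)}).

    H_O is the observed heterozygote fraction; H_E the unbiased Nei gene
    diversity (2n/(2n-1)) * (1 - sum p_i^2).  Run on the genet-level table
    so clonal replication does not weight genotypes.
    """
    if len(table.samples) < 2:
        raise DiversityError("heterozygosities: need >= 2 genets")
    per_locus: dict[str, tuple[float, float]] = {}
    for k, locus in enumerate(table.loci):
        pairs = [s.genotype[k] for s in table.samples
                 if s.genotype[k] is not MISSING]
        if not pairs:
            continue
        n = len(pairs)
        h_o = sum(1 for a, b in pairs if a != b) / n
        counts: dict[int, int] = {}
        for a, b in pairs:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        p = np.array(list(counts.values()), dtype=float) / (2 * n)
        h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p ** 2)))
        per_locus[locus.name] = (h_o, h_e)
    h_o_mean = float(np.mean([v[0] for v in per_locus.values()]))
    h_e_mean = float(np.mean([v[1] for v in per_locus.values()]))
    return h_o_mean, h_e_mean, per_locus


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class PopulationDiversity:
    population: str
    n: int
    n_mlg: int
    r: float
    g_o: float
    g: float
    ed_star: float | None
    beta: float | None
    beta_r2: float | None
    a_hat: float | None
    h_o: float
    h_e: float
    per_locus_h: dict[str, tuple[float, float]] = field(default_factory=dict)
    pareto_points: np.ndarray | None = None


@dataclass
class DiversityReport:
    populations: list[PopulationDiversity]

    def by_population(self) -> dict[str, PopulationDiversity]:
        return {p.population: p for p in self.populations}


def diversity_report(table: GenotypeTable, partition: ClonalPartition,
                     rarefaction_g: int | None = None) -> DiversityReport:
    """Full per-population diversity summary from a complete-case table.

    Degenerate indices (ED* in monoclonal or all-singleton populations,
    Pareto slope with a single distinct clone size) are reported as None
    rather than erroring the whole run.  Rarefied allelic richness uses
    ``rarefaction_g`` genes (default: twice the smallest per-population
    genet count, the smallest-sample convention).
    """
    pops = []
    truncated_counts: dict[str, int] = {}
    for site in table.sites:
        mlgs = {partition.mlg_of[s.id] for s in table.samples
                if s.site == site}
        truncated_counts[site] = len(mlgs)
    if rarefaction_g is None and truncated_counts:
        rarefaction_g = 2 * min(truncated_counts.values())

    for site in table.sites:
        sub = table.for_site(site)
        sizes_map: dict[str, int] = {}
        first_rep: dict[str, str] = {}
        for s in sub.samples:
            m = partition.mlg_of[s.id]
            sizes_map[m] = sizes_map.get(m, 0) + 1
            first_rep.setdefault(m, s.id)
        sizes = sorted(sizes_map.values(), reverse=True)
        n, n_mlg = len(sub), len(sizes)
        g_o, g = genotypic_diversity(sizes)
        try:
            ed = simpson_evenness(sizes)
        except DiversityError:
            ed = None
        try:
            beta, r2, points = pareto_beta(sizes)
        except DiversityError:
            beta = r2 = points = None
        genet_table = sub.subset(first_rep.values())
        try:
            a_hat = allelic_richness(allele_count_table(genet_table),
                                     rarefaction_g)
        except DiversityError:
            a_hat = None
        h_o, h_e, per_locus = heterozygosities(genet_table)
        pops.append(PopulationDiversity(
            population=site, n=n, n_mlg=n_mlg,
            r=clonal_richness(n, n_mlg), g_o=g_o, g=g, ed_star=ed,
            beta=beta, beta_r2=r2, a_hat=a_hat, h_o=h_o, h_e=h_e,
            per_locus_h=per_locus, pareto_points=points))
    return DiversityReport(populations=pops)
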