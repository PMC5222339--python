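"""F-statistics and differentiation on entire and clone-censored datasets.

In a partly clonal population every statistic can be computed two ways:
on the *entire* dataset (all ramets, so a prolific clone weights its
genotype by its ecological success) or on the *truncated* dataset (one
representative per MLG per population, weighting all genets equally).  The
truth usually lies between, so both are reported.

Estimators: Weir & Cockerham (1984) variance-component f (F_IS) and theta
(F_ST), ratio-of-sums across alleles and loci; Jost's D_est with the
unbiased within-population heterozygosity correction; likelihood-ratio G
tests of genotypic disequilibrium between locus pairs.  All significance
testing is by permutation with the (b + 1)/(m + 1) estimator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeTable, GenotypeError, MISSING
from .discrimination import ClonalPartition

logger = logging.getLogger("clonestruct")


class StructureError(ValueError):
    pass


def truncate_dataset(table: GenotypeTable,
                     partition: ClonalPartition) -> GenotypeTable:
    """Keep one representative per (population, MLG): the first complete one.

    A clone spanning two populations keeps one representative in each, so
    the output size is the sum of per-population MLG counts.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for s in table.samples:
        if not s.is_complete:
            continue
        key = (s.site, partition.mlg_of[s.id])
        if key not in seen:
            seen.add(key)
            kept.append(s)
    return GenotypeTable(loci=list(table.loci), samples=kept,
                         provenance=table.provenance)


# ---------------------------------------------------------------------------
# Per-locus encodings
# ---------------------------------------------------------------------------

@dataclass
class _LocusCoding:
    """One-hot allele dosages for one locus across a set of samples."""

    alleles: np.ndarray          # allele sizes, shape (A,)
    dosage: np.ndarray           # copies per sample, shape (n, A) in {0,1,2}
    het: np.ndarray              # dosage == 1, shape (n, A)
    valid: np.ndarray            # sample scored at this locus, shape (n,)


def _encode_loci(table: GenotypeTable) -> list[_LocusCoding]:
    n = len(table.samples)
    out = []
    for k in range(len(table.loci)):
        pairs = [s.genotype[k] for s in table.samples]
        alleles = sorted({a for p in pairs if p is not MISSING for a in p})
        a_index = {a: j for j, a in enumerate(alleles)}
        dosage = np.zeros((n, len(alleles)), dtype=np.int8)
        valid = np.zeros(n, dtype=bool)
        for i, p in enumerate(pairs):
            if p is MISSING:
                continue
            valid[i] = True
            dosage[i, a_index[p[0]]] += 1
            dosage[i, a_index[p[1]]] += 1
        out.append(_LocusCoding(alleles=np.array(alleles), dosage=dosage,
                                het=(dosage == 1), valid=valid))
    return out


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham f, single population)
# ---------------------------------------------------------------------------

def _fis_components(n: int, p: np.ndarray, h: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Single-population W&C variance components per allele.

    b = (n/(n-1)) (p(1-p) - h(2n-1)/(4n)); c = h/2;  f = 1 - sum c /
    sum(b+c).  ``h`` is the observed heterozygote frequency per allele.
    """
    b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
    c = h / 2.0
    return b, c


@dataclass
class FisResult:
    population: str
    multilocus: float
    per_locus: dict[str, float]
    p_value: float
    n_permutations: int
    seed: int


def fis(table: GenotypeTable, n_perm: int = 10_000, seed: int = 0,
        population: str = "") -> FisResult:
    """Multilocus F_IS with a two-sided within-population permutation test.

    The null redraws genotypes by shuffling the observed allele copies
    among individuals at each locus (Hardy-Weinberg given the allele
    counts); the doubled smaller tail of the permuted f distribution is
    reported.
    """
    if len(table.samples) < 2:
        raise StructureError("fis: need >= 2 individuals")
    codings = _encode_loci(table)
    rng = np.random.default_rng(seed)

    sum_c = 0.0
    sum_bc = 0.0
    per_locus: dict[str, float] = {}
    null_c = np.zeros(n_perm)
    null_bc = np.zeros(n_perm)
    for locus, cod in zip(table.loci, codings):
        nv = int(cod.valid.sum())
        if nv < 2 or cod.alleles.size < 2:
            continue
        dos = cod.dosage[cod.valid]
        p = dos.sum(axis=0) / (2 * nv)
        h = (dos == 1).mean(axis=0)
        b, c = _fis_components(nv, p, h)
        lc, lbc = float(c.sum()), float((b + c).sum())
        sum_c += lc
        sum_bc += lbc
        if lbc != 0:
            per_locus[locus.name] = 1.0 - lc / lbc
        # permutations: shuffle the 2*nv allele copies and re-pair
        pool = np.repeat(np.arange(cod.alleles.size),
                         dos.sum(axis=0))
        order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
        shuffled = pool[order].reshape(n_perm, nv, 2)
        for j in range(cod.alleles.size):
            cnt = (shuffled == j).sum(axis=2)
            h_perm = (cnt == 1).mean(axis=1)
            b_p, c_p = _fis_components(nv, p[j], h_perm)
            null_c += c_p
            null_bc += b_p + c_p
    if sum_bc == 0:
        raise StructureError("fis: all loci monomorphic")
    observed = 1.0 - sum_c / sum_bc
    with np.errstate(divide="ignore", invalid="ignore"):
        null = 1.0 - null_c / null_bc
    null = null[np.isfinite(null)]
    m = null.size
    p_hi = (int(np.sum(null >= observed)) + 1) / (m + 1)
    p_lo = (int(np.sum(null <= observed)) + 1) / (m + 1)
    p_val = min(1.0, 2.0 * min(p_hi, p_lo))
    return FisResult(population=population, multilocus=float(observed),
                     per_locus=per_locus, p_value=p_val,
                     n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (F_ST)
# ---------------------------------------------------------------------------

def _theta_sums(codings: list[_LocusCoding],
                membership: np.ndarray) -> tuple[float, float]:
    """(sum a, sum a+b+c) over loci and alleles for the given pop labels.

    Standard W&C (1984) components for r populations of n_i individuals
    with allele frequencies p_i and heterozygote frequencies h_i.
    """
    pops = np.unique(membership)
    r = pops.size
    sum_a = 0.0
    sum_abc = 0.0
    for cod in codings:
        ns, ps, hs = [], [], []
        for pop in pops:
            rows = (membership == pop) & cod.valid
            ni = int(rows.sum())
            if ni == 0:
                continue
            dos = cod.dosage[rows]
            ns.append(ni)
            ps.append(dos.sum(axis=0) / (2 * ni))
            hs.append((dos == 1).mean(axis=0))
        if len(ns) < 2:
            continue
        n_i = np.array(ns, dtype=float)            # (r,)
        p_i = np.array(ps)                          # (r, A)
        h_i = np.array(hs)                          # (r, A)
        ri = n_i.size
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (ri * nbar - np.sum(n_i ** 2) / (ri * nbar)) / (ri - 1)
        pbar = (n_i[:, None] * p_i).sum(axis=0) / (ri * nbar)
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / \
            ((ri - 1) * nbar)
        hbar = (n_i[:, None] * h_i).sum(axis=0) / (ri * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (ri - 1) / ri
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (ri - 1) / ri
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
        sum_a += float(a.sum())
        sum_abc += float((a + b + c).sum())
    return sum_a, sum_abc


def multilocus_theta(table: GenotypeTable) -> float:
    """Weir-Cockerham theta over all populations (sites) in the table."""
    codings = _encode_loci(table)
    membership = np.array([s.site for s in table.samples])
    sum_a, sum_abc = _theta_sums(codings, membership)
    if sum_abc == 0:
        raise StructureError("theta undefined: no polymorphic loci")
    return sum_a / sum_abc


@dataclass
class PairwiseMatrix:
    populations: list[str]
    values: np.ndarray           # square, nan diagonal
    p_values: np.ndarray | None = None

    def get(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])


def pairwise_fst(table: GenotypeTable, populations: list[str] | None = None,
                 n_perm: int = 1000, seed: int = 0) -> PairwiseMatrix:
    """Pairwise multilocus theta with one-sided permutation p-values.

    The null swaps whole multilocus individuals between the two
    populations; p = fraction of permutations with theta >= observed
    (+1/+1 corrected).
    """
    pops = populations if populations is not None else table.sites
    for pop in pops:
        if sum(1 for s in table.samples if s.site == pop) < 2:
            raise StructureError(f"population {pop!r} has < 2 individuals")
    k = len(pops)
    values = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    membership_all = np.array([s.site for s in table.samples])
    codings = _encode_loci(table)
    for i, j in itertools.combinations(range(k), 2):
        rows = np.flatnonzero((membership_all == pops[i]) |
                              (membership_all == pops[j]))
        sub = [_LocusCoding(c.alleles, c.dosage[rows], c.het[rows],
                            c.valid[rows]) for c in codings]
        member = membership_all[rows]
        sa, sabc = _theta_sums(sub, member)
        if sabc == 0:
            continue
        obs = sa / sabc
        b_count = 0
        for _ in range(n_perm):
            sa_p, sabc_p = _theta_sums(sub, rng.permutation(member))
            if sabc_p != 0 and sa_p / sabc_p >= obs:
                b_count += 1
        values[i, j] = values[j, i] = obs
        pvals[i, j] = pvals[j, i] = (b_count + 1) / (n_perm + 1)
    return PairwiseMatrix(populations=list(pops), values=values,
                          p_values=pvals)


# ---------------------------------------------------------------------------
# Jost's D_est
# ---------------------------------------------------------------------------

def pairwise_dest(table: GenotypeTable,
                  populations: list[str] | None = None) -> PairwiseMatrix:
    """Pairwise Jost's D_est (multilocus arithmetic mean over loci).

    Per locus, with harmonic-mean sample size n~ and r = 2 populations:
    H_S^ = (2n~/(2n~-1)) * (1 - mean_i sum_a p_ia^2),
    H_T = 1 - sum_a pbar_a^2 (pbar the unweighted mean frequency),
    D = (H_T - H_S^)/(1 - H_S^) * r/(r-1).
    Loci monomorphic across both populations are dropped.
    """
    pops = populations if populations is not None else table.sites
    for pop in pops:
        if sum(1 for s in table.samples if s.site == pop) < 2:
            raise StructureError(f"population {pop!r} has < 2 individuals")
    codings = _encode_loci(table)
    membership = np.array([s.site for s in table.samples])
    k = len(pops)
    values = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        per_locus = []
        for cod in codings:
            stats = []
            for pop in (pops[i], pops[j]):
                rows = (membership == pop) & cod.valid
                ni = int(rows.sum())
                if ni < 2:
                    break
                p = cod.dosage[rows].sum(axis=0) / (2 * ni)
                stats.append((ni, p))
            if len(stats) < 2:
                continue
            (n1, p1), (n2, p2) = stats
            if np.all((p1 == p2) & ((p1 == 0) | (p1 == 1))):
                continue  # monomorphic for the same allele in both pops
            n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
            h_s = 1.0 - 0.5 * (float(np.sum(p1 ** 2)) +
                               float(np.sum(p2 ** 2)))
            h_s_hat = (2 * n_harm / (2 * n_harm - 1)) * h_s
            pbar = (p1 + p2) / 2.0
            h_t = 1.0 - float(np.sum(pbar ** 2))
            if h_s_hat >= 1.0:
                continue
            per_locus.append((h_t - h_s_hat) / (1.0 - h_s_hat) * 2.0)
        if not per_locus:
            raise StructureError(
                f"D_est undefined between {pops[i]} and {pops[j]}: "
                f"all loci monomorphic")
        values[i, j] = values[j, i] = float(np.mean(per_locus))
    return PairwiseMatrix(populations=list(pops), values=values)


# ---------------------------------------------------------------------------
# Genotypic disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDTest:
    locus_a: str
    locus_b: str
    g_statistic: float
    p_value: float
    significant_bonferroni: bool


def _g_stat(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    table = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] *
                              np.log(table[mask] / expected[mask])))


def genotypic_ld(table: GenotypeTable,
                 pairs: list[tuple[str, str]] | None = None,
                 n_perm: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> list[LDTest]:
    """G tests of association between single-locus genotypes, per locus pair.

    The null permutes one locus's genotype column among individuals;
    Bonferroni significance uses alpha / number of tested pairs.  Run on
    the genet-level (truncated) table so clonal copies do not manufacture
    disequilibrium.
    """
    if len(table.samples) < 10:
        logger.warning("genotypic_ld: fewer than 10 genets; tests will "
                       "have little power")
    names = [l.name for l in table.loci]
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    # categorical genotype codes per locus
    codes: dict[str, np.ndarray] = {}
    ncats: dict[str, int] = {}
    for k, locus in enumerate(table.loci):
        gts = [s.genotype[k] for s in table.samples]
        cats = sorted({g for g in gts if g is not MISSING})
        if len(cats) < 2:
            codes[locus.name] = None  # monomorphic: skipped
            continue
        lookup = {g: c for c, g in enumerate(cats)}
        codes[locus.name] = np.array(
            [-1 if g is MISSING else lookup[g] for g in gts])
        ncats[locus.name] = len(cats)
    rng = np.random.default_rng(seed)
    results = []
    tested = [(a, b) for a, b in pairs
              if codes.get(a) is not None and codes.get(b) is not None]
    skipped = len(pairs) - len(tested)
    if skipped:
        logger.info("genotypic_ld: %d pairs skipped (monomorphic locus)",
                    skipped)
    threshold = alpha / len(tested) if tested else alpha
    for a, b in tested:
        ca, cb = codes[a], codes[b]
        valid = (ca >= 0) & (cb >= 0)
        va, vb = ca[valid], cb[valid]
        obs = _g_stat(va, vb, ncats[a], ncats[b])
        count = 0
        for _ in range(n_perm):
            if _g_stat(va, rng.permutation(vb), ncats[a], ncats[b]) >= obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        results.append(LDTest(a, b, obs, p, p <= threshold))
    return results


# ---------------------------------------------------------------------------
# Dual (entire vs truncated) analysis
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationReport:
    dataset_tag: str             # "entire" | "truncated"
    fst: PairwiseMatrix | None
    dest: PairwiseMatrix | None
    fis_by_pop: dict[str, FisResult] = field(default_factory=dict)
    ld_tests: list[LDTest] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)


def _analyze(table: GenotypeTable, tag: str, n_perm_fis: int,
             n_perm_fst: int, seed: int,
             ld: bool) -> DifferentiationReport:
    report = DifferentiationReport(dataset_tag=tag, fst=None, dest=None)
    try:
        report.fst = pairwise_fst(table, n_perm=n_perm_fst, seed=seed)
    except StructureError as e:
        report.failures["fst"] = str(e)
    try:
        report.dest = pairwise_dest(table)
    except StructureError as e:
        report.failures["dest"] = str(e)
    for site in table.sites:
        sub = table.for_site(site)
        try:
            report.fis_by_pop[site] = fis(sub, n_perm=n_perm_fis,
                                          seed=seed, population=site)
        except StructureError as e:
            report.failures[f"fis:{site}"] = str(e)
    if ld:
        try:
            report.ld_tests = genotypic_ld(table, n_perm=n_perm_fst,
                                           seed=seed)
        except StructureError as e:
            report.failures["ld"] = str(e)
    return report


def dual_analysis(table: GenotypeTable, partition: ClonalPartition,
                  n_perm_fis: int = 10_000, n_perm_fst: int = 1000,
                  seed: int = 0
                  ) -> tuple[DifferentiationReport, DifferentiationReport]:
    """Run F_IS / F_ST / D_est on entire and truncated datasets.

    Loci flagged ``excluded`` in the panel (e.g. null-allele loci) are
    removed from both analyses; genotypic disequilibrium is tested on the
    truncated dataset only.  Per-stage failures (e.g. a monoclonal
    population truncating to size 1) are collected, not raised.
    """
    filtered = table.drop_excluded_loci()
    entire = _analyze(filtered, "entire", n_perm_fis, n_perm_fst, seed,
                      ld=False)
    truncated_table = truncate_dataset(filtered, partition)
    truncated = _analyze(truncated_table, "truncated", n_perm_fis,
                         n_perm_fst, seed, ld=True)
    return entire, truncated
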