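"""Clone discrimination from multi-locus microsatellite genotypes.

Colonies sharing an identical multi-locus genotype (MLG) across all loci
are putative clonemates.  Whether repeated MLGs could instead arise from
distinct sexual events is judged with P_gen / P_SEX(F_IS); the loci panel's
discriminatory power with the probability of identity P_ID.  Genetically
near-identical MLGs (somatic mutation, scoring error) are merged into
multi-locus lineages (MLLs) by single-linkage at a small threshold of
stepwise-mutation-model (SMM) distance, the threshold being read off the
first gap of the pairwise-distance distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import (GenotypeTable, GenotypeError, LocusDef, MISSING,
                          AllelePair)

logger = logging.getLogger("clonestruct")


@dataclass
class ClonalPartition:
    """Sample -> MLG and MLG -> MLL maps plus the collapse threshold used.

    MLG ids are "MLG01", "MLG02", ... ordered by decreasing abundance then
    first occurrence, so MLG01 is the most abundant clone.  Before MLL
    collapsing, ``mll_of`` is the identity map.
    """

    mlg_of: dict[str, str]
    mlg_genotype: dict[str, tuple[AllelePair, ...]]
    mll_of: dict[str, str] = field(default_factory=dict)
    threshold_used: int = 0

    def __post_init__(self) -> None:
        if not self.mll_of:
            self.mll_of = {m: m for m in self.mlg_genotype}

    @property
    def mlg_ids(self) -> list[str]:
        return sorted(self.mlg_genotype)

    @property
    def n_mlg(self) -> int:
        return len(self.mlg_genotype)

    @property
    def n_mll(self) -> int:
        return len(set(self.mll_of.values()))

    def mlg_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {m: 0 for m in self.mlg_genotype}
        for m in self.mlg_of.values():
            sizes[m] += 1
        return sizes

    def mll_of_sample(self, sample_id: str) -> str:
        return self.mll_of[self.mlg_of[sample_id]]


def identify_mlgs(table: GenotypeTable) -> ClonalPartition:
    """Group samples into MLGs by exact identity of all unordered allele pairs.

    Requires a complete-case table: a missing call leaves identity
    undecidable and would silently split or merge clones.
    """
    if not table.samples:
        raise GenotypeError("identify_mlgs: empty table")
    incomplete = [s.id for s in table.samples if not s.is_complete]
    if incomplete:
        raise GenotypeError(
            f"identify_mlgs: {len(incomplete)} samples have missing calls "
            f"(first: {incomplete[0]!r}); apply complete_cases first")
    groups: dict[tuple, list[str]] = {}
    order: dict[tuple, int] = {}
    for i, s in enumerate(table.samples):
        key = s.genotype
        groups.setdefault(key, []).append(s.id)
        order.setdefault(key, i)
    ranked = sorted(groups, key=lambda k: (-len(groups[k]), order[k]))
    width = max(2, len(str(len(ranked))))
    mlg_of, mlg_genotype = {}, {}
    for rank, key in enumerate(ranked, start=1):
        mid = f"MLG{rank:0{width}d}"
        mlg_genotype[mid] = key
        for sid in groups[key]:
            mlg_of[sid] = mid
    return ClonalPartition(mlg_of=mlg_of, mlg_genotype=mlg_genotype)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-population, per-locus allele frequencies.

    ``freqs[pop][locus_name]`` maps allele size -> frequency;
    ``sample_size_genes[pop][locus_name]`` is the number of gene copies
    counted.  ``scheme`` records whether all ramets were counted
    ("ramet-level") or one representative per MLG per population
    ("genet-level"); the genet-level scheme avoids clonal inflation of
    frequencies and is the default input to P_gen / P_ID.
    """

    freqs: dict[str, dict[str, dict[int, float]]]
    sample_size_genes: dict[str, dict[str, int]]
    scheme: str

    def __post_init__(self) -> None:
        for pop, by_locus in self.freqs.items():
            for locus, f in by_locus.items():
                if f and abs(sum(f.values()) - 1.0) > 1e-9:
                    raise GenotypeError(
                        f"frequencies at {pop}/{locus} do not sum to 1")

    def pooled(self) -> dict[str, dict[int, float]]:
        """Frequencies pooled over populations, weighted by gene counts."""
        out: dict[str, dict[int, float]] = {}
        for locus in next(iter(self.freqs.values())):
            counts: dict[int, float] = {}
            total = 0
            for pop in self.freqs:
                n = self.sample_size_genes[pop][locus]
                total += n
                for a, f in self.freqs[pop][locus].items():
                    counts[a] = counts.get(a, 0.0) + f * n
            out[locus] = {a: c / total for a, c in counts.items()}
        return out


def allele_frequencies(table: GenotypeTable,
                       partition: ClonalPartition | None = None,
                       scheme: str = "genet-level") -> AlleleFrequencyTable:
    """Count allele frequencies per population and locus.

    "genet-level" keeps one representative per MLG per population (requires
    ``partition``); "ramet-level" counts every sample.
    """
    if not table.samples:
        raise GenotypeError("allele_frequencies: empty table")
    if scheme not in ("genet-level", "ramet-level"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "genet-level":
        if partition is None:
            raise ValueError("genet-level scheme requires a ClonalPartition")
        seen: set[tuple[str, str]] = set()
        counted = []
        for s in table.samples:
            key = (s.site, partition.mlg_of[s.id])
            if key not in seen:
                seen.add(key)
                counted.append(s)
    else:
        counted = list(table.samples)

    freqs: dict[str, dict[str, dict[int, float]]] = {}
    sizes: dict[str, dict[str, int]] = {}
    for site in table.sites:
        freqs[site] = {}
        sizes[site] = {}
        members = [s for s in counted if s.site == site]
        for k, locus in enumerate(table.loci):
            counts: dict[int, int] = {}
            n_genes = 0
            for s in members:
                pair = s.genotype[k]
                if pair is MISSING:
                    continue
                for a in pair:
                    counts[a] = counts.get(a, 0) + 1
                    n_genes += 1
            freqs[site][locus.name] = (
                {a: c / n_genes for a, c in counts.items()} if n_genes else {})
            sizes[site][locus.name] = n_genes
    return AlleleFrequencyTable(freqs=freqs, sample_size_genes=sizes,
                                scheme=scheme)


# ---------------------------------------------------------------------------
# P_gen / P_SEX / P_ID
# ---------------------------------------------------------------------------

def p_gen(genotype: tuple[AllelePair, ...],
          freqs: dict[str, dict[int, float]],
          loci: list[LocusDef],
          f_is: float = 0.0) -> float:
    """Probability of drawing this multi-locus genotype in one sexual event.

    Under inbreeding coefficient F_IS the per-locus genotype probabilities
    are 2*fA*fB*(1-F) for heterozygotes and fA^2 + fA*(1-fA)*F for
    homozygotes; the multi-locus value is their product (loci independent).
    """
    if not -1.0 <= f_is < 1.0:
        raise ValueError(f"f_is must be in [-1, 1), got {f_is}")
    prob = 1.0
    for k, locus in enumerate(loci):
        pair = genotype[k]
        if pair is MISSING:
            raise GenotypeError(f"p_gen: missing call at {locus.name}")
        f = freqs[locus.name]
        a, b = pair
        for allele in set(pair):
            if allele not in f:
                raise GenotypeError(
                    f"p_gen: allele {allele} absent from frequency table "
                    f"at {locus.name}")
        if a == b:
            term = f[a] ** 2 + f[a] * (1.0 - f[a]) * f_is
        else:
            term = 2.0 * f[a] * f[b] * (1.0 - f_is)
        if term < 0:
            raise ValueError(
                f"p_gen: negative genotype probability at {locus.name} "
                f"(f_is={f_is})")
        prob *= term
    return prob


def p_sex(n_obs: int, n_samples: int, pgen: float) -> float:
    """Probability that an MLG seen n_obs times arose >= n_obs-1 more times
    by independent sexual events among the other n_samples-1 units.

    Binomial upper tail: sum_{j>=n_obs-1} C(n_samples-1, j) pgen^j
    (1-pgen)^(n_samples-1-j).  Small values reject the repeated-sexual-
    origin hypothesis, i.e. support clonality.
    """
    if not 1 <= n_obs <= n_samples:
        raise ValueError(f"need 1 <= n_obs <= n_samples, got "
                         f"({n_obs}, {n_samples})")
    if not 0.0 <= pgen <= 1.0:
        raise ValueError(f"pgen must be in [0, 1], got {pgen}")
    if n_obs == 1:
        return 1.0
    # P(X >= n_obs-1) with X ~ Binomial(n_samples-1, pgen)
    return float(binom.sf(n_obs - 2, n_samples - 1, pgen))


def p_id(freqs: dict[str, dict[int, float]],
         loci: list[str] | None = None) -> float:
    """Probability two random sexual products share the same MLG by chance.

    Per locus 2*(sum p_i^2)^2 - sum p_i^4; product over loci.
    """
    names = list(loci) if loci is not None else list(freqs)
    if not names:
        raise ValueError("p_id: need at least one locus")
    prob = 1.0
    for name in names:
        p = np.array(list(freqs[name].values()))
        if p.size == 0:
            raise GenotypeError(f"p_id: locus {name} has no alleles")
        s2 = float(np.sum(p ** 2))
        s4 = float(np.sum(p ** 4))
        prob *= 2.0 * s2 ** 2 - s4
    return prob


# ---------------------------------------------------------------------------
# SMM distances and MLL collapsing
# ---------------------------------------------------------------------------

def smm_distance(g1: tuple[AllelePair, ...], g2: tuple[AllelePair, ...],
                 loci: list[LocusDef]) -> int:
    """Mutation steps between two genotypes under the stepwise model.

    Per locus the two possible pairings of the allele pairs are tried and
    the cheaper one kept: min(|a1-b1| + |a2-b2|, |a1-b2| + |a2-b1|) divided
    by the motif length.  Size differences must be whole repeat units.
    """
    total = 0
    for k, locus in enumerate(loci):
        p1, p2 = g1[k], g2[k]
        if p1 is MISSING or p2 is MISSING:
            raise GenotypeError(f"smm_distance: missing call at {locus.name}")
        m = locus.motif_length
        a1, a2 = p1
        b1, b2 = p2
        if any((x - a1) % m for x in (a2, b1, b2)):
            raise GenotypeError(
                f"smm_distance: allele-size difference at {locus.name} not "
                f"divisible by motif length {m}")
        d = min(abs(a1 - b1) + abs(a2 - b2), abs(a1 - b2) + abs(a2 - b1))
        total += d // m
    return total


@dataclass
class MLGDistanceMatrix:
    """Symmetric integer matrix of SMM steps between MLGs.

    Per-locus minimum pairing may violate the triangle inequality; only the
    zero diagonal and symmetry are guaranteed.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if np.any(np.diag(m) != 0) or np.any(m != m.T):
            raise ValueError("distance matrix must be symmetric, zero diag")

    def pairwise_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


def mlg_distance_matrix(partition: ClonalPartition,
                        loci: list[LocusDef]) -> MLGDistanceMatrix:
    """All pairwise SMM distances among the partition's MLGs."""
    ids = partition.mlg_ids
    n = len(ids)
    mat = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d = smm_distance(partition.mlg_genotype[ids[i]],
                         partition.mlg_genotype[ids[j]], loci)
        mat[i, j] = mat[j, i] = d
    return MLGDistanceMatrix(ids=ids, matrix=mat)


def find_collapse_threshold(dist: MLGDistanceMatrix) -> int:
    """MLL threshold from the first gap of the pairwise-distance spectrum.

    The threshold is the first empty integer bin of the observed inter-MLG
    distances — distinct clones are expected to differ by many steps, so a
    leading gap separates somatic/scoring noise from true genotypic
    differences.  If the minimum observed distance is 1 there is no leading
    gap and the threshold is 0 (no collapsing is defensible).
    """
    if len(dist.ids) < 2:
        raise ValueError("find_collapse_threshold: need >= 2 MLGs")
    observed = set(int(v) for v in dist.pairwise_values())
    if min(observed) == 1:
        return 0
    d = 1
    while d in observed:
        d += 1
    return d


def collapse_mll(partition: ClonalPartition, dist: MLGDistanceMatrix,
                 threshold: int) -> ClonalPartition:
    """Merge MLGs into MLLs by single linkage at the given step threshold.

    Connected components of the graph joining MLG pairs at distance <=
    threshold; each component's MLL takes the id of its most abundant
    member MLG.  Threshold 0 leaves every MLG its own MLL.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids = dist.ids
    adj = (dist.matrix <= threshold)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = partition.mlg_sizes()
    mll_of: dict[str, str] = {}
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == comp)]
        # most abundant member; ties break toward the lowest-ranked id
        rep = min(members, key=lambda m: (-sizes.get(m, 0), m))
        for m in members:
            mll_of[m] = rep
    return ClonalPartition(mlg_of=dict(partition.mlg_of),
                           mlg_genotype=dict(partition.mlg_genotype),
                           mll_of=mll_of, threshold_used=threshold)
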