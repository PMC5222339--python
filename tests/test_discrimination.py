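"""Clone discrimination: MLG identity, P_gen/P_SEX/P_ID, SMM distances,
MLL collapsing."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from clonestruct import (GenotypeTable, GenotypeError, LocusDef, SampleUnit,
                         allele_frequencies, collapse_mll, complete_cases,
                         find_collapse_threshold, identify_mlgs,
                         mlg_distance_matrix, p_gen, p_id, p_sex,
                         smm_distance)
from clonestruct.discrimination import MLGDistanceMatrix
from clonestruct.simulate import (SimulationConfig, simulate_allele_freqs,
                                  simulate_genets)


def _table(genotypes, loci=None, sites=None):
    if loci is None:
        n_loci = len(genotypes[0])
        loci = [LocusDef(f"L{k}") for k in range(n_loci)]
    sites = sites or ["P1"] * len(genotypes)
    return GenotypeTable(loci=loci, samples=[
        SampleUnit(id=f"s{i}", site=sites[i], genotype=g)
        for i, g in enumerate(genotypes)])


# ---------------------------------------------------------------- MLGs ----

def test_identify_mlgs_groups_identical_rows():
    g1 = ((100, 102), (200, 200))
    g2 = ((100, 104), (200, 200))
    table = _table([g1, g1, g1, g2])
    part = identify_mlgs(table)
    assert part.n_mlg == 2
    assert sorted(part.mlg_sizes().values()) == [1, 3]
    assert part.mlg_of["s0"] == "MLG01"      # most abundant ranked first


def test_identify_mlgs_all_distinct():
    table = _table([((100 + 2 * i, 100 + 2 * i),) for i in range(6)])
    assert identify_mlgs(table).n_mlg == 6


def test_identify_mlgs_rejects_empty_and_incomplete():
    with pytest.raises(GenotypeError, match="empty"):
        identify_mlgs(GenotypeTable(loci=[LocusDef("L")], samples=[]))
    with pytest.raises(GenotypeError, match="missing"):
        identify_mlgs(_table([(None,)]))


def test_mlg_partition_matches_simulation_truth(clean_sim):
    table, truth = clean_sim
    part = identify_mlgs(complete_cases(table))
    by_genet, by_mlg = {}, {}
    for s in table.samples:
        by_genet.setdefault(truth.genet_of[s.id], set()).add(s.id)
        by_mlg.setdefault(part.mlg_of[s.id], set()).add(s.id)
    assert sorted(map(sorted, by_genet.values())) == \
        sorted(map(sorted, by_mlg.values()))


# ----------------------------------------------------- allele freqs -------

def test_allele_frequency_counting():
    table = _table([((100, 100),), ((100, 102),)])
    part = identify_mlgs(table)
    af = allele_frequencies(table, part, scheme="ramet-level")
    assert af.freqs["P1"]["L0"] == {100: 0.75, 102: 0.25}


def test_genet_level_counts_one_representative_per_mlg():
    g = ((100, 102),)
    table = _table([g, g, g, ((104, 104),)])
    part = identify_mlgs(table)
    af = allele_frequencies(table, part, scheme="genet-level")
    # one representative each: alleles {100, 102, 104, 104}
    assert af.freqs["P1"]["L0"] == {100: 0.25, 102: 0.25, 104: 0.5}
    assert af.sample_size_genes["P1"]["L0"] == 4


def test_frequency_estimates_converge_to_truth():
    cfg = SimulationConfig(seed=3)
    rng = np.random.default_rng(3)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    loci = cfg.locus_defs()
    genotypes = simulate_genets(freqs, 500, 0.0, rng, loci)
    table = _table(genotypes, loci=loci)
    part = identify_mlgs(table)
    af = allele_frequencies(table, part, scheme="genet-level")
    worst = 0.0
    for locus in freqs:
        for allele, p in freqs[locus].items():
            worst = max(worst, abs(af.freqs["P1"][locus].get(allele, 0.0)
                                   - p))
    assert worst < 0.05


# ------------------------------------------------------------- p_gen ------

def test_p_gen_single_locus_cases():
    loci = [LocusDef("L")]
    f = {"L": {100: 0.5, 102: 0.5}}
    assert p_gen(((100, 102),), f, loci, 0.0) == pytest.approx(0.5)
    assert p_gen(((100, 100),), f, loci, 1.0 - 1e-12) == pytest.approx(0.5)


def test_p_gen_two_locus_hand_value():
    # hom f=0.4 and het 0.3/0.2, both at F_IS = 0.2:
    # (0.16 + 0.4*0.6*0.2) * (2*0.3*0.2*0.8) = 0.208 * 0.096
    loci = [LocusDef("A"), LocusDef("B")]
    f = {"A": {100: 0.4, 102: 0.6}, "B": {100: 0.3, 102: 0.2, 104: 0.5}}
    got = p_gen(((100, 100), (100, 102)), f, loci, 0.2)
    assert got == pytest.approx(0.019968, abs=1e-12)


def test_p_gen_zero_inbreeding_product_form():
    """With F_IS = 0, p_gen = (prod of allele freqs) * 2^heterozygous."""
    rng = np.random.default_rng(12)
    loci = [LocusDef(f"L{k}") for k in range(5)]
    freqs = {}
    genotype = []
    expected = 1.0
    h = 0
    for locus in loci:
        alleles = [100, 102, 104]
        p = rng.dirichlet(np.ones(3))
        freqs[locus.name] = dict(zip(alleles, p))
        a, b = rng.choice(alleles, size=2)
        genotype.append((min(a, b), max(a, b)))
        expected *= freqs[locus.name][a] * freqs[locus.name][b]
        if a != b:
            h += 1
    got = p_gen(tuple(genotype), freqs, loci, 0.0)
    assert got == pytest.approx(expected * 2 ** h, rel=1e-12)


def test_p_gen_errors():
    loci = [LocusDef("L")]
    f = {"L": {100: 1.0}}
    with pytest.raises(GenotypeError, match="absent"):
        p_gen(((102, 102),), f, loci, 0.0)
    with pytest.raises(ValueError, match="f_is"):
        p_gen(((100, 100),), f, loci, 1.5)


# ------------------------------------------------------------- p_sex ------

def _p_sex_oracle(n_obs, n_samples, pgen):
    """Exact rational binomial upper tail, independent of scipy."""
    p = Fraction(pgen).limit_denominator(10 ** 12)
    n = n_samples - 1
    total = Fraction(0)
    for j in range(n_obs - 1, n + 1):
        total += (Fraction(math.comb(n, j)) * p ** j *
                  (1 - p) ** (n - j))
    return float(total)


def test_p_sex_boundaries():
    assert p_sex(1, 10, 0.7) == 1.0
    assert p_sex(2, 10, 0.0) == 0.0


def test_p_sex_enumeration_case():
    # 2 Bernoulli trials at p = 1/2: P(at least one success) = 3/4
    assert p_sex(2, 3, 0.5) == pytest.approx(0.75)


@pytest.mark.parametrize("n_obs,n_samples,pgen", [
    (2, 10, 0.3), (5, 20, 0.05), (3, 7, 0.9), (10, 10, 0.5),
])
def test_p_sex_matches_exact_oracle(n_obs, n_samples, pgen):
    assert p_sex(n_obs, n_samples, pgen) == pytest.approx(
        _p_sex_oracle(n_obs, n_samples, pgen), rel=1e-10)


def test_p_sex_monotonicity():
    vals_n = [p_sex(k, 20, 0.3) for k in range(1, 21)]
    assert all(a >= b for a, b in zip(vals_n, vals_n[1:]))
    vals_p = [p_sex(4, 20, p) for p in np.linspace(0.01, 0.99, 25)]
    assert all(a <= b + 1e-15 for a, b in zip(vals_p, vals_p[1:]))


# -------------------------------------------------------------- p_id ------

def test_p_id_closed_forms():
    assert p_id({"L": {100: 0.5, 102: 0.5}}) == pytest.approx(0.375)
    assert p_id({"L": {100: 1.0}}) == pytest.approx(1.0)
    two = {"A": {1: 0.5, 2: 0.5}, "B": {1: 0.5, 2: 0.5}}
    assert p_id(two) == pytest.approx(0.140625)


# ------------------------------------------------------ SMM distance ------

def test_smm_identity_and_pairing():
    loci = [LocusDef("L", motif_length=2)]
    assert smm_distance(((100, 104),), ((100, 104),), loci) == 0
    assert smm_distance(((100, 104),), ((100, 106),), loci) == 1


def test_smm_non_divisible_difference_errors():
    loci = [LocusDef("L", motif_length=2)]
    with pytest.raises(GenotypeError, match="L"):
        smm_distance(((100, 100),), ((101, 101),), loci)


def _smm_brute_force(g1, g2, loci):
    """Enumerate all 2^L per-locus pairing choices; minimum total steps."""
    per_locus = []
    for k, locus in enumerate(loci):
        (a1, a2), (b1, b2) = g1[k], g2[k]
        m = locus.motif_length
        per_locus.append(((abs(a1 - b1) + abs(a2 - b2)) // m,
                          (abs(a1 - b2) + abs(a2 - b1)) // m))
    best = None
    for choice in itertools.product([0, 1], repeat=len(loci)):
        tot = sum(pl[c] for pl, c in zip(per_locus, choice))
        best = tot if best is None else min(best, tot)
    return best


def test_smm_matches_exhaustive_pairing_enumeration():
    rng = np.random.default_rng(77)
    loci = [LocusDef(f"L{k}", motif_length=int(m))
            for k, m in enumerate(rng.choice([2, 3, 4], size=13))]

    def rand_g():
        g = []
        for l in loci:
            a, b = 100 + l.motif_length * rng.integers(0, 8, size=2)
            g.append((min(a, b), max(a, b)))
        return tuple(g)

    for _ in range(50):
        g1, g2 = rand_g(), rand_g()
        assert smm_distance(g1, g2, loci) == _smm_brute_force(g1, g2, loci)
        assert smm_distance(g1, g2, loci) == smm_distance(g2, g1, loci)


# ----------------------------------------------- threshold & collapse -----

def _dist(ids, pairs):
    n = len(ids)
    m = np.zeros((n, n), dtype=int)
    for (i, j), d in pairs.items():
        m[i, j] = m[j, i] = d
    return MLGDistanceMatrix(ids=list(ids), matrix=m)


def test_collapse_threshold_first_gap():
    d = _dist("abc", {(0, 1): 2, (0, 2): 3, (1, 2): 5})
    assert find_collapse_threshold(d) == 1
    d = _dist("abc", {(0, 1): 1, (0, 2): 2, (1, 2): 4})
    assert find_collapse_threshold(d) == 0
    d = _dist("abc", {(0, 1): 3, (0, 2): 3, (1, 2): 7})
    assert find_collapse_threshold(d) == 1


def test_collapse_mll_identity_below_min_distance():
    table = _table([((100, 100),), ((100, 104),), ((100, 108),)],
                   loci=[LocusDef("L", 2)])
    part = identify_mlgs(table)
    dist = mlg_distance_matrix(part, table.loci)
    assert int(dist.pairwise_values().min()) == 2
    out = collapse_mll(part, dist, 1)
    assert out.n_mll == out.n_mlg            # nothing merges


def test_collapse_mll_single_linkage_chain():
    d = _dist("abc", {(0, 1): 1, (1, 2): 1, (0, 2): 2})
    part_stub = identify_mlgs(_table(
        [((100, 100),), ((101, 101),), ((102, 102),)]))
    # rename to match ids a,b,c
    part_stub.mlg_genotype = {i: g for i, g in
                              zip("abc", part_stub.mlg_genotype.values())}
    part_stub.mlg_of = {s: i for s, i in zip(
        ["s0", "s1", "s2"], "abc")}
    part_stub.mll_of = {i: i for i in "abc"}
    out = collapse_mll(part_stub, d, 1)
    assert out.n_mll == 1
    out_all = collapse_mll(part_stub, d, 2)
    assert out_all.n_mll == 1
    out_none = collapse_mll(part_stub, d, 0)
    assert out_none.n_mll == 3
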