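"""F_IS, pairwise F_ST (Weir-Cockerham), Jost's D_est, genotypic LD,
and the entire-vs-truncated dual analysis."""

import itertools

import numpy as np
import pytest

from clonestruct import (GenotypeTable, LocusDef, SampleUnit,
                         dual_analysis, fis, genotypic_ld, identify_mlgs,
                         multilocus_theta, pairwise_dest, pairwise_fst,
                         truncate_dataset)
from clonestruct.structure import StructureError
from clonestruct.simulate import (SimulationConfig, simulate_allele_freqs,
                                  simulate_genets)
from conftest import make_population


def _table(rows, loci=None):
    """rows: (id, site, genotype)."""
    if loci is None:
        loci = [LocusDef(f"L{k}") for k in range(len(rows[0][2]))]
    return GenotypeTable(loci=loci, samples=[
        SampleUnit(id=i, site=s, genotype=g) for i, s, g in rows])


# ------------------------------------------------------- truncation -------

def test_truncate_reproduces_per_site_mlg_counts():
    """A dataset shaped like the published per-site MLG counts
    {44, 25, 13, 27} truncates to 109 samples."""
    rng = np.random.default_rng(0)
    rows = []
    counts = {"P1": 44, "P2": 25, "P3": 13, "P4": 27}
    copies = {"P1": 158, "P2": 264, "P3": 42, "P4": 46}
    uid = 0
    for si, (site, n_mlg) in enumerate(counts.items()):
        genotypes = [((100 + 2 * j, 100 + 2 * j), (200 + 2 * si, 300))
                     for j in range(n_mlg)]
        # replicate MLGs up to the site total
        reps = list(np.sort(rng.choice(n_mlg, size=copies[site] - n_mlg)))
        pool = list(range(n_mlg)) + reps
        for j in pool:
            rows.append((f"c{uid}", site, genotypes[j]))
            uid += 1
    table = _table(rows)
    part = identify_mlgs(table)
    out = truncate_dataset(table, part)
    assert len(out) == 109
    assert len(table) == sum(copies.values())


def test_truncate_identity_on_all_unique():
    rows = [(f"c{i}", "P1", ((100 + 2 * i, 100),)) for i in range(6)]
    table = _table(rows)
    out = truncate_dataset(table, identify_mlgs(table))
    assert [s.id for s in out.samples] == [s.id for s in table.samples]


def test_truncate_keeps_one_rep_per_population():
    g = ((100, 102),)
    rows = [("a", "P1", g), ("b", "P1", g), ("c", "P2", g)]
    table = _table(rows)
    out = truncate_dataset(table, identify_mlgs(table))
    assert [s.id for s in out.samples] == ["a", "c"]


# ------------------------------------------------------------ F_IS --------

def test_fis_boundary_full_heterozygote_excess():
    rows = [(f"c{i}", "P", ((100, 102),)) for i in range(10)]
    res = fis(_table(rows), n_perm=100, seed=1)
    assert res.multilocus == pytest.approx(-1.0)


def test_fis_boundary_fixed_homozygote_classes():
    rows = [(f"a{i}", "P", ((100, 100),)) for i in range(5)] + \
           [(f"b{i}", "P", ((102, 102),)) for i in range(5)]
    res = fis(_table(rows), n_perm=100, seed=1)
    assert res.multilocus == pytest.approx(1.0)


def test_fis_near_zero_under_hwe():
    cfg = SimulationConfig(seed=21)
    rng = np.random.default_rng(21)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    table = make_population(freqs, 500, 0.0, 22, cfg.locus_defs())
    res = fis(table, n_perm=100, seed=23)
    assert abs(res.multilocus) < 0.05


def test_fis_monomorphic_errors():
    rows = [(f"c{i}", "P", ((100, 100),)) for i in range(5)]
    with pytest.raises(StructureError, match="monomorphic"):
        fis(_table(rows), n_perm=100, seed=1)


# ------------------------------------------------------------ theta -------

def test_theta_fixed_differences_is_one():
    rows = [(f"a{i}", "P1", ((100, 100), (200, 200))) for i in range(5)] + \
           [(f"b{i}", "P2", ((102, 102), (203, 203))) for i in range(5)]
    loci = [LocusDef("A", 2), LocusDef("B", 3)]
    assert multilocus_theta(_table(rows, loci)) == pytest.approx(1.0)


def _wc_theta_brute(pop_genotypes):
    """Independent implementation of Weir-Cockerham theta, written from
    the published component formulas for r populations, one allele at a
    time, no shared code with the package."""
    alleles = sorted({a for pop in pop_genotypes for g in pop for a in g})
    r = len(pop_genotypes)
    sum_a = sum_abc = 0.0
    for allele in alleles:
        n = [len(pop) for pop in pop_genotypes]
        p = [sum(g.count(allele) for g in pop) / (2 * len(pop))
             for pop in pop_genotypes]
        h = [sum(1 for g in pop if g.count(allele) == 1) / len(pop)
             for pop in pop_genotypes]
        nbar = sum(n) / r
        nc = (r * nbar - sum(x ** 2 for x in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2
                 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def test_theta_matches_independent_hand_implementation():
    pop1 = [(100, 100), (100, 102), (102, 102), (100, 102)]
    pop2 = [(100, 102), (102, 102), (102, 104), (104, 104)]
    rows = [(f"a{i}", "P1", (g,)) for i, g in enumerate(pop1)] + \
           [(f"b{i}", "P2", (g,)) for i, g in enumerate(pop2)]
    got = multilocus_theta(_table(rows))
    assert got == pytest.approx(_wc_theta_brute([pop1, pop2]), abs=1e-12)


def test_theta_invariant_under_relabeling_and_locus_order():
    rng = np.random.default_rng(31)
    g1 = [tuple(sorted(rng.choice([100, 102, 104], 2))) for _ in range(12)]
    g2 = [tuple(sorted(rng.choice([100, 102, 104], 2))) for _ in range(12)]
    h1 = [tuple(sorted(rng.choice([200, 205], 2))) for _ in range(12)]
    h2 = [tuple(sorted(rng.choice([200, 205], 2))) for _ in range(12)]
    rows = [(f"a{i}", "P1", (x, y)) for i, (x, y) in
            enumerate(zip(g1, h1))] + \
           [(f"b{i}", "P2", (x, y)) for i, (x, y) in enumerate(zip(g2, h2))]
    base = multilocus_theta(_table(rows))
    swap = {100: 300, 102: 308, 104: 296, 200: 150, 205: 142}
    rows_re = [(i, s, tuple(tuple(sorted((swap[a], swap[b]))) for a, b in g))
               for i, s, g in rows]
    assert multilocus_theta(_table(rows_re)) == pytest.approx(base)
    rows_swapped = [(i, s, g[::-1]) for i, s, g in rows]
    assert multilocus_theta(_table(rows_swapped)) == pytest.approx(base)


def test_pairwise_fst_null_split():
    cfg = SimulationConfig(seed=33)
    rng = np.random.default_rng(33)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    loci = cfg.locus_defs()
    genotypes = simulate_genets(freqs, 100, 0.0, rng, loci)
    rows = [(f"c{i}", "P1" if i < 50 else "P2", g)
            for i, g in enumerate(genotypes)]
    mat = pairwise_fst(_table(rows, loci), n_perm=200, seed=34)
    assert abs(mat.get("P1", "P2")) < 0.03
    assert mat.p_values[0, 1] > 0.05


def test_pairwise_fst_small_population_errors():
    rows = [("a", "P1", ((100, 102),)), ("b", "P2", ((100, 100),))]
    with pytest.raises(StructureError, match="< 2"):
        pairwise_fst(_table(rows), n_perm=100, seed=0)


# ------------------------------------------------------------ D_est -------

def test_dest_fixed_differences_is_one():
    rows = [(f"a{i}", "P1", ((100, 100),)) for i in range(6)] + \
           [(f"b{i}", "P2", ((102, 102),)) for i in range(6)]
    mat = pairwise_dest(_table(rows))
    assert mat.get("P1", "P2") == pytest.approx(1.0)


def test_dest_hand_value_two_alleles():
    """freqs (0.9, 0.1) vs (0.1, 0.9), 50 diploids each; hand arithmetic:
    H_S = 0.18 -> H_S^ = (100/99)*0.18; H_T = 0.5; D = 2(H_T-H_S^)/(1-H_S^).
    """
    g_a = [(100, 100)] * 40 + [(100, 102)] * 10
    g_b = [(102, 102)] * 40 + [(100, 102)] * 10
    rows = [(f"a{i}", "P1", (g,)) for i, g in enumerate(g_a)] + \
           [(f"b{i}", "P2", (g,)) for i, g in enumerate(g_b)]
    h_s_hat = (100 / 99) * 0.18
    want = 2 * (0.5 - h_s_hat) / (1 - h_s_hat)
    assert pairwise_dest(_table(rows)).get("P1", "P2") == \
        pytest.approx(want, abs=1e-12)


def test_dest_null_near_zero():
    cfg = SimulationConfig(seed=35)
    rng = np.random.default_rng(35)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    loci = cfg.locus_defs()
    genotypes = simulate_genets(freqs, 400, 0.0, rng, loci)
    rows = [(f"c{i}", "P1" if i < 200 else "P2", g)
            for i, g in enumerate(genotypes)]
    assert abs(pairwise_dest(_table(rows, loci)).get("P1", "P2")) < 0.02


# --------------------------------------------------------------- LD -------

def test_ld_pair_count_for_13_loci():
    cfg = SimulationConfig(seed=36)
    rng = np.random.default_rng(36)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    table = make_population(freqs, 30, 0.0, 37, cfg.locus_defs())
    tests = genotypic_ld(table, n_perm=100, seed=38)
    assert len(tests) == 78


def test_ld_detects_duplicated_locus():
    cfg = SimulationConfig(seed=39, n_loci=1, alleles_per_locus=4)
    rng = np.random.default_rng(39)
    freqs = simulate_allele_freqs(cfg, rng)["north"]
    loci = [LocusDef("L01"), LocusDef("L02")]
    rngg = np.random.default_rng(40)
    singles = simulate_genets(freqs, 100, 0.0, rngg,
                              [LocusDef("L01")])
    rows = [(f"c{i}", "P", (g[0], g[0])) for i, g in enumerate(singles)]
    tests = genotypic_ld(_table(rows, loci), n_perm=999, seed=41)
    assert tests[0].p_value <= 0.001


def test_ld_skips_monomorphic_locus():
    rows = [(f"c{i}", "P", ((100, 100), tuple(sorted((100 + 2 * (i % 2),
                                                      102)))))
            for i in range(20)]
    tests = genotypic_ld(_table(rows), n_perm=100, seed=0)
    assert tests == []


# -------------------------------------------------------- dual analysis ---

def test_dual_analysis_monoclonal_truncation_failure_is_recorded():
    g = ((100, 102), (200, 203))
    rows = [(f"a{i}", "P1", g) for i in range(5)] + \
           [(f"b{i}", "P2", g) for i in range(5)]
    table = _table(rows)
    entire, truncated = dual_analysis(table, identify_mlgs(table),
                                      n_perm_fis=100, n_perm_fst=100,
                                      seed=1)
    assert entire.fst is not None            # entire dataset analysable
    assert truncated.failures                # truncation leaves 1 per pop


def test_dual_analysis_identical_when_all_unique():
    rng = np.random.default_rng(42)
    cfg = SimulationConfig(seed=42)
    freqs = simulate_allele_freqs(cfg, rng)
    loci = cfg.locus_defs()
    rows = []
    for pop, cl in (("P1", "north"), ("P2", "south")):
        for i, g in enumerate(simulate_genets(freqs[cl], 20, 0.0, rng,
                                              loci)):
            rows.append((f"{pop}_{i}", pop, g))
    table = _table(rows, loci)
    entire, truncated = dual_analysis(table, identify_mlgs(table),
                                      n_perm_fis=100, n_perm_fst=100,
                                      seed=2)
    assert entire.fst.get("P1", "P2") == \
        pytest.approx(truncated.fst.get("P1", "P2"))
    assert entire.dest.get("P1", "P2") == \
        pytest.approx(truncated.dest.get("P1", "P2"))


def test_dual_analysis_superclone_inflates_differentiation(clean_sim):
    """Keeping all ramets of a dominant clone shifts F_ST relative to the
    clone-censored dataset (the published qualitative contrast)."""
    from clonestruct import complete_cases

    table, _ = clean_sim
    cc = complete_cases(table)
    entire, truncated = dual_analysis(cc, identify_mlgs(cc),
                                      n_perm_fis=100, n_perm_fst=100,
                                      seed=3)
    iu = np.triu_indices(len(entire.fst.populations), k=1)
    diff = np.nanmean(np.abs(entire.fst.values[iu]) -
                      np.abs(truncated.fst.values[iu]))
    assert np.isfinite(diff)
    assert np.nanmean(np.abs(entire.fst.values[iu])) >= \
        np.nanmean(np.abs(truncated.fst.values[iu])) - 0.02


def test_excluded_loci_are_dropped_from_structure():
    loci = [LocusDef("A", excluded=True), LocusDef("B")]
    rng = np.random.default_rng(50)
    rows = []
    for pop in ("P1", "P2"):
        for i in range(10):
            g = (tuple(sorted(rng.choice([100, 102], 2))),
                 tuple(sorted(rng.choice([200, 203], 2))))
            rows.append((f"{pop}_{i}", pop, g))
    table = _table(rows, loci)
    entire, _ = dual_analysis(table, identify_mlgs(table),
                              n_perm_fis=100, n_perm_fst=100, seed=4)
    for res in entire.fis_by_pop.values():
        assert "A" not in res.per_locus
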