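"""Forward generator of partially clonal, spatially structured populations.

The generator emulates the statistical structure of a multi-site
microsatellite survey of a partially clonal coral: a handful of sites of
unequal size sampled inside fixed-radius discs, two divergent genetic
clusters (Balding-Nichols divergence around a common ancestral frequency
ladder) with one site mixing both, a heavily skewed clone-size spectrum
with a single dominant superclone spilling across sites, spatial
aggregation of clonemates (Gaussian ramet dispersal around each genet's
origin), rare long-distance clonal migration, stepwise somatic mutation
and missing genotype calls.

Every run emits the sampled :class:`~clonestruct.genotype_io.GenotypeTable`
together with a :class:`SimulationTruth` (genet membership, cluster labels,
true frequencies) so that downstream estimators can be tested against
ground truth.  All randomness flows through one seeded generator in a
documented draw order, so a seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genotype_io import GenotypeTable, LocusDef, SampleUnit, AllelePair

NORTH, SOUTH, MIXED = "north", "south", "mixed"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated survey design:
    four lagoon sites of 158/264/42/46 colonies genotyped at 13 loci,
    a superclone near 47% of all ramets, two clusters at F ~ 0.2 with the
    third site mixed, 12 m sampling discs and meter-scale clonal spread."""

    seed: int
    n_loci: int = 13
    alleles_per_locus: int = 6
    motif_lengths: tuple[int, ...] | None = None   # default: cycle 2,3,4
    site_names: tuple[str, ...] = ("site1", "site2", "site3", "site4")
    site_sizes: tuple[int, ...] = (158, 264, 42, 46)
    cluster_of_site: tuple[str, ...] = (NORTH, NORTH, MIXED, SOUTH)
    divergence_f: float = 0.2
    f_is: float = 0.15
    pareto_beta: float = 1.5
    superclone_fraction: float | None = 0.47
    ramet_dispersal_sigma: float = 1.5
    site_radius: float = 12.0
    clonal_migration_rate: float = 0.01
    somatic_mu: float = 0.0005
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.motif_lengths is None:
            self.motif_lengths = tuple(
                (2, 3, 4)[k % 3] for k in range(self.n_loci))
        if len(self.motif_lengths) != self.n_loci:
            raise SimulationError("motif_lengths length != n_loci")
        if not (len(self.site_names) == len(self.site_sizes)
                == len(self.cluster_of_site)):
            raise SimulationError("site metadata lengths disagree")
        for p in (self.divergence_f, self.clonal_migration_rate,
                  self.somatic_mu, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability out of [0,1]: {p}")
        if self.pareto_beta <= 0:
            raise SimulationError("pareto_beta must be > 0")

    @property
    def n_ramets(self) -> int:
        return int(sum(self.site_sizes))

    def locus_defs(self) -> list[LocusDef]:
        return [LocusDef(name=f"L{k+1:02d}", motif_length=m)
                for k, m in enumerate(self.motif_lengths)]


@dataclass
class SimulationTruth:
    genet_of: dict[str, str]                 # sample id -> genet id
    cluster_of_genet: dict[str, str]
    founder_genotype: dict[str, tuple[AllelePair, ...]]
    allele_freqs: dict[str, dict[str, dict[int, float]]]  # cluster->locus->
    config: SimulationConfig

    def genet_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genet_of.values():
            out[g] = out.get(g, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Allele frequencies (Balding-Nichols two-cluster model)
# ---------------------------------------------------------------------------

def simulate_allele_freqs(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> dict[str, dict[str, dict[int, float]]]:
    """Ancestral Dirichlet-uniform frequencies per locus; per-cluster
    frequencies Dirichlet(p * (1-F)/F) around them (Balding-Nichols).

    Allele sizes sit on a motif-spaced ladder starting at 100 bp.  With
    divergence_f = 0 both clusters share the ancestral frequencies exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: dict[str, dict[str, dict[int, float]]] = {NORTH: {}, SOUTH: {}}
    f = config.divergence_f
    for k, locus in enumerate(config.locus_defs()):
        sizes = [100 + config.motif_lengths[k] * j
                 for j in range(config.alleles_per_locus)]
        ancestral = rng.dirichlet(np.ones(len(sizes)))
        for cluster in (NORTH, SOUTH):
            if f == 0:
                p = ancestral
            else:
                p = rng.dirichlet(ancestral * (1.0 - f) / f)
            out[cluster][locus.name] = dict(zip(sizes, p))
    return out


def simulate_genets(freqs: dict[str, dict[int, float]],
                    n: int, f_is: float,
                    rng: np.random.Generator,
                    loci: list[LocusDef]) -> list[tuple[AllelePair, ...]]:
    """Draw n diploid multi-locus genotypes with inbreeding f_is.

    Per locus, with probability f_is one allele is drawn and duplicated
    (identical by descent); otherwise two independent draws.  Expected
    homozygosity is f_is + (1 - f_is) * sum p^2.
    """
    genotypes = []
    per_locus = []
    for locus in loci:
        items = sorted(freqs[locus.name].items())
        sizes = np.array([a for a, _ in items])
        probs = np.array([p for _, p in items])
        per_locus.append((sizes, probs / probs.sum()))
    for _ in range(n):
        g: list[AllelePair] = []
        for sizes, probs in per_locus:
            if rng.random() < f_is:
                a = int(rng.choice(sizes, p=probs))
                g.append((a, a))
            else:
                a, b = (int(rng.choice(sizes, p=probs)) for _ in range(2))
                g.append((min(a, b), max(a, b)))
        genotypes.append(tuple(g))
    return genotypes


# ---------------------------------------------------------------------------
# Clone sizes and spatial placement
# ---------------------------------------------------------------------------

def assign_clone_sizes(n_ramets_target: int, config: SimulationConfig,
                       rng: np.random.Generator) -> list[int]:
    """Clone-size spectrum: optional superclone plus discrete-Pareto tail.

    The superclone takes round(fraction * n) ramets; the remainder is
    filled with sizes drawn from the discrete Pareto law
    P(X >= x) = x^(-beta) (inverse-transform floor(u^(-1/beta))), the last
    draw truncated so the sizes sum exactly to the target.  Sizes are
    returned in decreasing order.
    """
    if n_ramets_target < 1:
        raise SimulationError("n_ramets_target must be >= 1")
    sizes: list[int] = []
    remaining = n_ramets_target
    if config.superclone_fraction is not None:
        sc = round(config.superclone_fraction * n_ramets_target)
        if not 1 <= sc <= n_ramets_target:
            raise SimulationError(
                f"infeasible superclone fraction "
                f"{config.superclone_fraction}")
        sizes.append(sc)
        remaining -= sc
    beta = config.pareto_beta
    while remaining > 0:
        u = rng.random()
        x = int(np.floor(u ** (-1.0 / beta)))
        x = max(1, min(x, remaining))
        sizes.append(x)
        remaining -= x
    return sorted(sizes, reverse=True)


def _uniform_in_disc(rng: np.random.Generator, radius: float
                     ) -> np.ndarray:
    r = radius * np.sqrt(rng.random())
    th = 2 * np.pi * rng.random()
    return np.array([r * np.cos(th), r * np.sin(th)])


def _reflect_into_disc(p: np.ndarray, radius: float) -> np.ndarray:
    r = float(np.linalg.norm(p))
    if r <= radius or r == 0:
        return p
    r_new = 2 * radius - r
    if r_new < 0:
        r_new = radius * 0.99
    return p * (r_new / r)


def place_ramets(ramet_sites: list[str], ramet_genets: list[str],
                 config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, list[str]]:
    """Site-local coordinates for each ramet, plus (possibly migrated) sites.

    Each (genet, site) group gets a uniform origin inside the 12 m disc;
    its ramets scatter around the origin with isotropic Gaussian sigma and
    are reflected back into the disc.  Independently, each ramet migrates
    to a random other site (fresh origin) with the clonal migration rate —
    the mechanism behind clonemates tens of kilometres apart.
    """
    n = len(ramet_sites)
    sites = list(ramet_sites)
    # migration first, so migrants get their own origin at the new site
    for i in range(n):
        if config.clonal_migration_rate > 0 and \
                rng.random() < config.clonal_migration_rate:
            others = [s for s in config.site_names if s != sites[i]]
            sites[i] = others[int(rng.integers(len(others)))]
    coords = np.zeros((n, 2))
    origins: dict[tuple[str, str], np.ndarray] = {}
    for i in range(n):
        key = (ramet_genets[i], sites[i])
        if key not in origins:
            origins[key] = _uniform_in_disc(rng, config.site_radius)
        p = origins[key] + rng.normal(0.0, config.ramet_dispersal_sigma,
                                      size=2)
        coords[i] = _reflect_into_disc(p, config.site_radius)
    return coords, sites


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _allocate_to_sites(sizes: list[int], config: SimulationConfig,
                       rng: np.random.Generator
                       ) -> tuple[list[str], list[str]]:
    """Assign each clone's ramets to sites, respecting site quotas.

    Clones are placed whole (largest first) in a single home site drawn
    with probability proportional to the remaining quota among sites that
    can hold them — so without migration every MLG is confined to one
    site, and the superclone lands in the largest site.  A clone that fits
    no single remaining quota (rare, late in allocation) spills across
    sites to conserve the total ramet count.  Returns parallel per-ramet
    lists (site, genet id).
    """
    capacity = {s: int(c) for s, c in zip(config.site_names,
                                          config.site_sizes)}
    width = max(3, len(str(len(sizes))))
    ramet_sites: list[str] = []
    ramet_genets: list[str] = []
    for gi, size in enumerate(sizes):
        gid = f"G{gi+1:0{width}d}"
        fitting = [s for s in config.site_names if capacity[s] >= size]
        if fitting:
            weights = np.array([capacity[s] for s in fitting], dtype=float)
            home = fitting[int(rng.choice(len(fitting),
                                          p=weights / weights.sum()))]
            capacity[home] -= size
            ramet_sites.extend([home] * size)
            ramet_genets.extend([gid] * size)
            continue
        left = size  # spillover fallback: conservation over confinement
        for s in sorted(config.site_names, key=lambda s: -capacity[s]):
            take = min(left, capacity[s])
            capacity[s] -= take
            left -= take
            ramet_sites.extend([s] * take)
            ramet_genets.extend([gid] * take)
            if left == 0:
                break
        if left:
            raise SimulationError("clone sizes exceed total site capacity")
    return ramet_sites, ramet_genets


def _somatic_mutate(genotype: tuple[AllelePair, ...],
                    config: SimulationConfig,
                    rng: np.random.Generator) -> tuple[AllelePair, ...]:
    g = list(genotype)
    for k in range(config.n_loci):
        if rng.random() < config.somatic_mu:
            a, b = g[k]
            motif = config.motif_lengths[k]
            step = motif if rng.random() < 0.5 else -motif
            if rng.random() < 0.5:
                a = max(motif, a + step)
            else:
                b = max(motif, b + step)
            g[k] = (min(a, b), max(a, b))
    return tuple(g)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[GenotypeTable, SimulationTruth]:
    """Run the full generator; see the module docstring for the model.

    Draw order (single RNG stream): allele frequencies, clone sizes, site
    allocation, cluster labels, founder genotypes, migration + placement,
    somatic mutation, missing-data masking.  With somatic_mu = 0 and
    missing_rate = 0 the MLG partition of the emitted table equals the
    genet partition in the truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    loci = config.locus_defs()
    freqs = simulate_allele_freqs(config, rng)
    sizes = assign_clone_sizes(config.n_ramets, config, rng)
    ramet_sites, ramet_genets = _allocate_to_sites(sizes, config, rng)

    # cluster per genet from its first (home) site
    cluster_site = dict(zip(config.site_names, config.cluster_of_site))
    cluster_of_genet: dict[str, str] = {}
    for site, gid in zip(ramet_sites, ramet_genets):
        if gid not in cluster_of_genet:
            c = cluster_site[site]
            if c == MIXED:
                c = NORTH if rng.random() < 0.5 else SOUTH
            cluster_of_genet[gid] = c

    genet_ids = sorted(cluster_of_genet)
    founder: dict[str, tuple[AllelePair, ...]] = {}
    for gid in genet_ids:
        founder[gid] = simulate_genets(freqs[cluster_of_genet[gid]], 1,
                                       config.f_is, rng, loci)[0]

    coords, final_sites = place_ramets(ramet_sites, ramet_genets, config,
                                       rng)

    samples: list[SampleUnit] = []
    genet_of: dict[str, str] = {}
    color_of_genet = {gid: ("pink" if rng.random() < 0.5 else "cream")
                      for gid in genet_ids}
    for i, (site, gid) in enumerate(zip(final_sites, ramet_genets)):
        sid = f"C{i+1:04d}"
        g = _somatic_mutate(founder[gid], config, rng)
        if config.missing_rate > 0:
            g = tuple(None if rng.random() < config.missing_rate else pair
                      for pair in g)
        samples.append(SampleUnit(
            id=sid, site=site, x=float(coords[i, 0]),
            y=float(coords[i, 1]), color=color_of_genet[gid],
            genotype=g))
        genet_of[sid] = gid
    table = GenotypeTable(loci=loci, samples=samples,
                          provenance=f"simulated(seed={config.seed})")
    truth = SimulationTruth(genet_of=genet_of,
                            cluster_of_genet=cluster_of_genet,
                            founder_genotype=founder,
                            allele_freqs=freqs, config=config)
    return table, truth


# ---------------------------------------------------------------------------
# Temperature series (phenology support)
# ---------------------------------------------------------------------------

def simulate_temperature_series(n_days: int, mean: float = 25.0,
                                amplitude: float = 2.0,
                                daily_offset: float = 0.0,
                                noise_sd: float = 0.3,
                                seed: int = 0) -> np.ndarray:
    """Daily sea temperature: annual sinusoid + constant offset + noise.

    Two series generated with the same parameters but different
    ``daily_offset`` differ by the offset difference in expectation —
    emulating a warmer and a cooler lagoon.
    """
    if n_days < 1:
        raise SimulationError("n_days must be >= 1")
    t = np.arange(n_days)
    rng = np.random.default_rng(seed)
    series = (mean + daily_offset
              + amplitude * np.sin(2 * np.pi * t / 365.25))
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=n_days)
    return series
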