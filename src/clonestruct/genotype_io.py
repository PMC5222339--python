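"""Genotype tables: domain types, validation, and file round-tripping.

A genotype table holds one row per sampled colony (ramet) with a sample id,
a site (population) label, optional planar coordinates in meters, an
optional color phenotype, and an unordered pair of allele sizes (bp) per
microsatellite locus.  Missing locus calls are encoded as ``None``; on disk
they are ``0`` or blank cells.  The CSV dialect uses two columns per locus,
named ``<locus>.1`` and ``<locus>.2`` (GenAlEx-like).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("clonestruct")

#: Sentinel for a missing locus call (a locus is either None or a 2-tuple).
MISSING = None

#: Unordered diploid call: a sorted pair of allele sizes in bp, or MISSING.
AllelePair = Optional[tuple[int, int]]


class GenotypeError(ValueError):
    """Raised on malformed genotype inputs."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name, repeat-motif length (bp), exclusion flag.

    ``excluded`` marks loci dropped from population-structure analyses
    (e.g. loci with evidence for null alleles) while still being used for
    clone discrimination and clonal-diversity statistics.
    """

    name: str
    motif_length: int = 1
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise GenotypeError(
                f"locus {self.name!r}: motif_length must be >= 1, "
                f"got {self.motif_length}"
            )


@dataclass(frozen=True)
class SampleUnit:
    """One sampled colony: id, site, optional coordinates/color, genotype."""

    id: str
    site: str
    genotype: tuple[AllelePair, ...]
    x: Optional[float] = None
    y: Optional[float] = None
    color: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.site:
            raise GenotypeError(f"sample {self.id!r}: empty site label")
        for k, pair in enumerate(self.genotype):
            if pair is MISSING:
                continue
            if len(pair) != 2:
                raise GenotypeError(
                    f"sample {self.id!r}, locus index {k}: a call is either "
                    f"MISSING or exactly two alleles, got {pair!r}"
                )
            if any(int(a) <= 0 for a in pair):
                raise GenotypeError(
                    f"sample {self.id!r}, locus index {k}: allele sizes must "
                    f"be positive integers, got {pair!r}"
                )

    @property
    def has_coords(self) -> bool:
        return self.x is not None and self.y is not None

    @property
    def n_missing(self) -> int:
        return sum(1 for p in self.genotype if p is MISSING)

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0


@dataclass
class GenotypeTable:
    """Samples x loci matrix of unordered allele pairs plus metadata."""

    loci: list[LocusDef]
    samples: list[SampleUnit]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeError("locus names must be unique within a panel")
        seen: set[str] = set()
        for s in self.samples:
            if s.id in seen:
                raise GenotypeError(f"duplicate sample id {s.id!r}")
            seen.add(s.id)
            if len(s.genotype) != len(self.loci):
                raise GenotypeError(
                    f"sample {s.id!r}: {len(s.genotype)} locus calls for a "
                    f"{len(self.loci)}-locus panel"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sites(self) -> list[str]:
        """Site labels in order of first appearance."""
        out: list[str] = []
        for s in self.samples:
            if s.site not in out:
                out.append(s.site)
        return out

    def subset(self, ids: Iterable[str]) -> "GenotypeTable":
        wanted = set(ids)
        return GenotypeTable(
            loci=list(self.loci),
            samples=[s for s in self.samples if s.id in wanted],
            provenance=self.provenance,
        )

    def for_site(self, site: str) -> "GenotypeTable":
        return GenotypeTable(
            loci=list(self.loci),
            samples=[s for s in self.samples if s.site == site],
            provenance=self.provenance,
        )

    def drop_loci(self, names: Iterable[str]) -> "GenotypeTable":
        """Return a table without the named loci (e.g. null-allele loci)."""
        drop = set(names)
        keep = [i for i, l in enumerate(self.loci) if l.name not in drop]
        return GenotypeTable(
            loci=[self.loci[i] for i in keep],
            samples=[
                replace(s, genotype=tuple(s.genotype[i] for i in keep))
                for s in self.samples
            ],
            provenance=self.provenance,
        )

    def drop_excluded_loci(self) -> "GenotypeTable":
        return self.drop_loci(l.name for l in self.loci if l.excluded)


def complete_cases(table: GenotypeTable) -> GenotypeTable:
    """Samples with no missing locus call, in original order.

    Clone discrimination operates on complete multi-locus genotypes only;
    a single missing call makes identity-by-state undecidable.
    """
    kept = [s for s in table.samples if s.is_complete]
    if not kept:
        logger.warning("complete_cases: no sample is complete at all loci")
    return GenotypeTable(loci=list(table.loci), samples=kept,
                         provenance=table.provenance)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_COLS = ("id", "site", "x", "y", "color")


def _parse_allele(cell: str, warn: list[int]) -> Optional[int]:
    cell = cell.strip()
    if cell in ("", "0", "0.0", "NA", "na", "nan"):
        return None
    try:
        v = int(float(cell))
    except ValueError:
        warn[0] += 1
        return None
    return v if v > 0 else None


def read_genotype_table(path: str | Path,
                        panel: Optional[Sequence[LocusDef]] = None
                        ) -> GenotypeTable:
    """Read a paired-allele-column CSV genotype table.

    Header: ``id,site[,x][,y][,color],<locus>.1,<locus>.2,...``.  Missing
    alleles are ``0`` or blank; a half-missing pair makes the whole locus
    call MISSING.  Unparseable cells become MISSING with a logged warning
    count.  If ``panel`` is given, its locus names must match the file's
    and its motif lengths / exclusion flags are attached.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise GenotypeError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    meta_idx = {c: header.index(c) for c in _META_COLS if c in header}
    if "id" not in meta_idx or "site" not in meta_idx:
        raise GenotypeError(f"{path}: header must declare 'id' and 'site'")
    locus_cols = [i for i, h in enumerate(header) if i not in meta_idx.values()]
    if len(locus_cols) % 2:
        raise GenotypeError(f"{path}: odd number of allele columns")
    locus_names: list[str] = []
    for j in range(0, len(locus_cols), 2):
        h1 = header[locus_cols[j]]
        h2 = header[locus_cols[j + 1]]
        base1, _, suf1 = h1.rpartition(".")
        base2, _, suf2 = h2.rpartition(".")
        if not (base1 and base1 == base2 and {suf1, suf2} == {"1", "2"}):
            raise GenotypeError(
                f"{path}: allele columns must pair as <locus>.1/<locus>.2, "
                f"got {h1!r}/{h2!r}"
            )
        locus_names.append(base1)

    if panel is not None:
        by_name = {l.name: l for l in panel}
        missing = [n for n in locus_names if n not in by_name]
        if missing:
            raise GenotypeError(f"{path}: loci absent from panel: {missing}")
        loci = [by_name[n] for n in locus_names]
    else:
        loci = [LocusDef(n) for n in locus_names]

    warn = [0]
    samples: list[SampleUnit] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        sid = row[meta_idx["id"]].strip()
        site = row[meta_idx["site"]].strip()
        x = y = None
        if "x" in meta_idx and row[meta_idx["x"]].strip():
            x = float(row[meta_idx["x"]])
        if "y" in meta_idx and row[meta_idx["y"]].strip():
            y = float(row[meta_idx["y"]])
        color = (row[meta_idx["color"]].strip() or None) \
            if "color" in meta_idx else None
        genotype: list[AllelePair] = []
        for j in range(0, len(locus_cols), 2):
            a = _parse_allele(row[locus_cols[j]], warn)
            b = _parse_allele(row[locus_cols[j + 1]], warn)
            if a is None or b is None:
                genotype.append(MISSING)
            else:
                genotype.append((min(a, b), max(a, b)))
        samples.append(SampleUnit(id=sid, site=site, x=x, y=y, color=color,
                                  genotype=tuple(genotype)))
    if warn[0]:
        logger.warning("read_genotype_table: %d unparseable allele cells "
                       "treated as MISSING", warn[0])
    return GenotypeTable(loci=loci, samples=samples, provenance=str(path))


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write the paired-allele-column CSV (inverse of read_genotype_table)."""
    path = Path(path)
    have_xy = any(s.has_coords for s in table.samples)
    have_color = any(s.color is not None for s in table.samples)
    header = ["id", "site"]
    if have_xy:
        header += ["x", "y"]
    if have_color:
        header.append("color")
    for l in table.loci:
        header += [f"{l.name}.1", f"{l.name}.2"]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in table.samples:
            row: list[object] = [s.id, s.site]
            if have_xy:
                row += ["" if s.x is None else repr(s.x),
                        "" if s.y is None else repr(s.y)]
            if have_color:
                row.append(s.color or "")
            for pair in s.genotype:
                row += ["0", "0"] if pair is MISSING else list(pair)
            w.writerow(row)


def read_structure_table(path: str | Path,
                         panel: Optional[Sequence[LocusDef]] = None
                         ) -> GenotypeTable:
    """Read a two-row-per-individual STRUCTURE-format file (read-only dialect).

    Whitespace-delimited; first line is locus names; each individual spans
    two rows of ``id pop a1 a2 ...`` with one allele per locus per row;
    missing is ``-9`` or ``0``.
    """
    path = Path(path)
    lines = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise GenotypeError(f"{path}: too short for STRUCTURE format")
    locus_names = lines[0]
    body = lines[1:]
    if len(body) % 2:
        raise GenotypeError(f"{path}: odd number of individual rows")
    loci = list(panel) if panel is not None else [LocusDef(n) for n in locus_names]
    samples = []
    for r1, r2 in zip(body[::2], body[1::2]):
        if r1[0] != r2[0]:
            raise GenotypeError(f"{path}: row pair id mismatch {r1[0]}/{r2[0]}")
        genotype: list[AllelePair] = []
        for a_s, b_s in zip(r1[2:], r2[2:]):
            a, b = int(a_s), int(b_s)
            if a <= 0 or b <= 0:
                genotype.append(MISSING)
            else:
                genotype.append((min(a, b), max(a, b)))
        samples.append(SampleUnit(id=r1[0], site=r1[1],
                                  genotype=tuple(genotype)))
    return GenotypeTable(loci=loci, samples=samples, provenance=str(path))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as ``{id: uppercase sequence}``; duplicate ids error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise GenotypeError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise GenotypeError(f"{path}: no FASTA records")
    return out
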