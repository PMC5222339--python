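"""Mitochondrial-ORF lineage gating.

Colonies sampled on gross morphology may belong to cryptic sister lineages;
each colony's mtDNA open-reading-frame amplicon is compared against labelled
reference haplotypes and the genotype table is filtered to the target
lineage before any population-genetic analysis.  Matching is plain Hamming
distance over the shared leading window of query and reference — the ORF
amplicon is a fixed-length marker, so alignment is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

from .genotype_io import GenotypeTable

logger = logging.getLogger("clonestruct")

MIN_SEQ_LEN = 200


class LineageError(ValueError):
    pass


@dataclass(frozen=True)
class LineageAssignment:
    sample_id: str
    best_lineage: str
    hamming_distance: int
    ambiguous: bool


def hamming(a: str, b: str) -> int:
    """Mismatches over the shared leading window (min length)."""
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a[:n], b[:n]) if x != y)


def parse_reference_labels(references: dict[str, str]) -> dict[str, str]:
    """Map reference id -> lineage label.

    Labels ride in the FASTA header after a ``|`` separator
    (``>KT879932|damicornis-beta``); headers without one use the full id.
    """
    out = {}
    for rid in references:
        _, sep, label = rid.partition("|")
        out[rid] = label if sep else rid
    return out


def assign_lineage(queries: dict[str, str],
                   references: dict[str, str]) -> list[LineageAssignment]:
    """Assign each query to the lineage of its nearest reference.

    Per query the minimum Hamming distance to any reference is taken; if two
    or more *distinct lineages* attain that minimum the call is flagged
    ambiguous.  Queries shorter than 200 bp error (truncated amplicons give
    meaningless distances).
    """
    if not references:
        raise LineageError("no reference sequences")
    labels = parse_reference_labels(references)
    out = []
    for qid, qseq in queries.items():
        if len(qseq) < MIN_SEQ_LEN:
            raise LineageError(
                f"query {qid!r}: sequence shorter than {MIN_SEQ_LEN} bp")
        best: dict[str, int] = {}  # lineage -> min distance
        for rid, rseq in references.items():
            d = hamming(qseq, rseq)
            lab = labels[rid]
            if lab not in best or d < best[lab]:
                best[lab] = d
        dmin = min(best.values())
        winners = sorted(l for l, d in best.items() if d == dmin)
        out.append(LineageAssignment(
            sample_id=qid, best_lineage=winners[0],
            hamming_distance=dmin, ambiguous=len(winners) > 1))
    return out


def filter_to_lineage(table: GenotypeTable,
                      assignments: list[LineageAssignment],
                      target: str) -> GenotypeTable:
    """Drop samples assigned to non-target lineages (ambiguous ones too).

    Samples without an assignment (no sequence) pass through with a warning
    — in practice one representative per multi-locus genotype is sequenced
    and the call extended to its clonemates upstream of this gate.
    """
    by_id = {a.sample_id: a for a in assignments}
    kept, removed_by_site, n_ambiguous, n_unsequenced = [], {}, 0, 0
    for s in table.samples:
        a = by_id.get(s.id)
        if a is None:
            n_unsequenced += 1
            kept.append(s)
        elif a.ambiguous:
            n_ambiguous += 1
            removed_by_site[s.site] = removed_by_site.get(s.site, 0) + 1
        elif a.best_lineage != target:
            removed_by_site[s.site] = removed_by_site.get(s.site, 0) + 1
        else:
            kept.append(s)
    if n_unsequenced:
        logger.warning("filter_to_lineage: %d samples without a sequence "
                       "passed through unjudged", n_unsequenced)
    for site, n in sorted(removed_by_site.items()):
        logger.info("filter_to_lineage: removed %d off-target samples "
                    "from %s", n, site)
    if n_ambiguous:
        logger.info("filter_to_lineage: %d ambiguous assignments removed",
                    n_ambiguous)
    return GenotypeTable(loci=list(table.loci), samples=kept,
                         provenance=table.provenance)
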