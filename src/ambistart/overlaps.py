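"""Detection of annotated start codons embedded in AUGUG/GUGUG pentamers.

An overlap pentamer provides two canonical start codons, offset by 2 nt in
different reading frames: AUGUG offers a 5' AUG and a 3' GUG, GUGUG two
GUGs. Four placements of an annotated start codon are possible:

========  ==================================================
class     meaning
========  ==================================================
ATGtg     annotated AUG is the 5' codon of AUGUG
atGTG     annotated GUG is the 3' codon of AUGUG
gtGTG     annotated GUG is the 3' codon of GUGUG
GTGtg     annotated GUG is the 5' codon of GUGUG
========  ==================================================

GTGtg is representable although no such gene was observed in *E. coli*
(the 3' GUG is always the annotated one there); its absence on real data is
a checkable result, not a built-in assumption. The nucleotide immediately
after the pentamer matters twice over: an A there turns the pentamer into
N-UGA, an immediate out-of-frame stop ("start-stop") in the -2 frame of
the 3' codon, the substrate for termination-reinitiation.

Detection is anchored at annotated start codons (the survey is per
annotated gene); :func:`scan_genome_pentamers` provides a separate
exploratory scan over all genomic pentamers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .genome import GeneRecord, GenomeAnnotationSet
from .sequence import revcomp_dna, to_dna

log = logging.getLogger(__name__)

_PENTAMERS = ("ATGTG", "GTGTG")


class OverlapClass(str, Enum):
    ATGtg = "ATGtg"  # annotated ATG, 5' codon of ATGTG
    atGTG = "atGTG"  # annotated GTG, 3' codon of ATGTG
    gtGTG = "gtGTG"  # annotated GTG, 3' codon of GTGTG
    GTGtg = "GTGtg"  # annotated GTG, 5' codon of GTGTG

    @property
    def pentamer(self) -> str:
        """The pentamer (DNA) this class refers to."""
        return "ATGTG" if self in (OverlapClass.ATGtg, OverlapClass.atGTG) else "GTGTG"

    @property
    def pentamer_start(self) -> int:
        """Pentamer first nt relative to the annotated start: 0 (5') or -2 (3')."""
        return 0 if self in (OverlapClass.ATGtg, OverlapClass.GTGtg) else -2

    @property
    def annotated_codon(self) -> str:
        return "ATG" if self is OverlapClass.ATGtg else "GTG"

    @property
    def annotated_is_5prime(self) -> bool:
        return self.pentamer_start == 0


@dataclass(frozen=True)
class StartOverlap:
    """A detected pentamer spanning an annotated start codon.

    ``a4_base`` is the annotated CDS's fourth base (position +3); the
    genome-wide A4-enrichment statistic keys on it. ``post_pentamer_base``
    is the base at ``pentamer_start + 5`` — for 3'-placed codons that *is*
    position +3, for 5'-placed codons it is position +5 — and the
    start-stop flag keys on it: ``has_start_stop`` iff it is A.
    """

    gene_id: str
    overlap_class: OverlapClass
    pentamer_start: int
    competitor_offset: int  # -2 or +2: competing codon's first nt relative to the start
    a4_base: str
    post_pentamer_base: str
    has_start_stop: bool
    strand: str = "+"
    replicon_id: str = ""
    start_anchor: int = 0


def classify_overlap(context: str, annotated_codon: str) -> tuple[OverlapClass, ...]:
    """Overlap classes matched by a start context.

    ``context`` covers positions -2..+5 (8 nt, DNA or RNA) with the
    annotated codon at index 2. Returns every matching placement — a
    context like ``AUGUGUG`` matches both a 3' and a 5' placement — or an
    empty tuple when no pentamer spans the annotated start. Codons other
    than ATG/GTG (e.g. TTG) are never classified.
    """
    ctx = to_dna(context)
    codon = to_dna(annotated_codon)
    if len(ctx) < 7:
        raise ValueError("context must cover at least positions -2..+4")
    if ctx[2:5] != codon:
        raise ValueError("context positions 0..2 do not match the annotated codon")
    found: list[OverlapClass] = []
    if codon == "ATG":
        if ctx[2:7] == "ATGTG":
            found.append(OverlapClass.ATGtg)
    elif codon == "GTG":
        if ctx[0:5] == "ATGTG":
            found.append(OverlapClass.atGTG)
        if ctx[0:5] == "GTGTG":
            found.append(OverlapClass.gtGTG)
        if ctx[2:7] == "GTGTG":
            found.append(OverlapClass.GTGtg)
    return tuple(found)


def _overlap_from_class(gene: GeneRecord, cls: OverlapClass) -> StartOverlap:
    ctx = to_dna(gene.context_seq)  # positions -2..+5, annotated codon at index 2
    pent_start = cls.pentamer_start
    post_idx = 2 + pent_start + 5
    post = ctx[post_idx]
    return StartOverlap(
        gene_id=gene.gene_id,
        overlap_class=cls,
        pentamer_start=pent_start,
        competitor_offset=2 if pent_start == 0 else -2,
        a4_base=ctx[5],
        post_pentamer_base=post,
        has_start_stop=post == "A",
        strand=gene.strand,
        replicon_id=gene.replicon_id,
        start_anchor=gene.start_anchor,
    )


def find_start_overlaps(
    genome: GenomeAnnotationSet, include_pseudo: bool = False
) -> list[StartOverlap]:
    """All pentamer overlaps spanning annotated start codons of a genome.

    One :class:`StartOverlap` per gene and matching placement; genes whose
    context matches both placements yield two records. Pseudogenes are
    excluded unless ``include_pseudo``. Output is sorted by (replicon,
    coordinate) and therefore stable across runs.
    """
    overlaps: list[StartOverlap] = []
    for gene in genome.genes:
        if gene.is_pseudo and not include_pseudo:
            continue
        if gene.context_start != -2 or len(gene.context_seq) < 8:
            log.warning(
                "skipping %s: start context truncated at replicon edge", gene.gene_id
            )
            continue
        for cls in classify_overlap(gene.context_seq, gene.annotated_start_codon):
            overlaps.append(_overlap_from_class(gene, cls))
    overlaps.sort(key=lambda o: (o.replicon_id, o.start_anchor, o.overlap_class.value))
    return overlaps


def pentamer_interval(overlap: StartOverlap) -> tuple[int, int]:
    """Forward-strand 0-based half-open interval of the overlap's pentamer."""
    s, e = overlap.pentamer_start, overlap.pentamer_start + 5
    if overlap.strand == "+":
        return overlap.start_anchor + s, overlap.start_anchor + e
    return overlap.start_anchor - e + 1, overlap.start_anchor - s + 1


def scan_genome_pentamers(genome: GenomeAnnotationSet) -> list[tuple[int, int, str, str]]:
    """Exploratory scan: every ATGTG/GTGTG occurrence on either strand.

    Returns (start, end, pentamer-as-written-on-its-strand, strand) tuples
    in forward-strand coordinates, independent of annotation. Not used for
    the reference outputs, which are anchored at annotated starts.
    """
    hits: list[tuple[int, int, str, str]] = []
    seq = genome.sequence
    for pent in _PENTAMERS:
        for m in re.finditer(f"(?={pent})", seq):
            hits.append((m.start(), m.start() + 5, pent, "+"))
        rc = revcomp_dna(pent)
        for m in re.finditer(f"(?={rc})", seq):
            hits.append((m.start(), m.start() + 5, pent, "-"))
    hits.sort()
    return hits


def a4_fraction(genome: GenomeAnnotationSet, include_pseudo: bool = False) -> float:
    """Fraction of annotated CDSs whose fourth base (position +3) is A.

    About one half of all annotated *E. coli* start codons are immediately
    followed by A4.
    """
    total = 0
    a4 = 0
    for gene in genome.genes:
        if gene.is_pseudo and not include_pseudo:
            continue
        idx = (0 - gene.context_start) + 3  # position +3 within context_seq
        if idx >= len(gene.context_seq):
            continue
        total += 1
        if gene.context_seq[idx] == "A":
            a4 += 1
    return a4 / total if total else float("nan")
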