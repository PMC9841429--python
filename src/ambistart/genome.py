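"""Annotated-genome model: CDS records in mRNA sense with upstream windows.

Reads GenBank flat files (or FASTA + GFF3) and exposes every CDS as a
:class:`GeneRecord` carrying its annotated start codon, a 30-nt upstream
window and the start context, all in mRNA sense regardless of strand.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open on the forward strand of the
replicon; GenBank's 1-based inclusive coordinates are converted only at the
I/O boundary. Relative to a gene, position 0 is the first nucleotide of the
annotated start codon and upstream positions are negative — the convention
all spacing arithmetic in this package relies on.

Circular replicons wrap upstream windows across the origin; linear
replicons truncate them (never pad). CDS features with fuzzy locations are
skipped with a warning, as their start codon is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import ExactPosition, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .sequence import revcomp_dna, validate_dna

log = logging.getLogger(__name__)

#: Upstream window length used by the survey (SD motifs are sought within
#: 30 nt upstream of the CDS).
DEFAULT_UPSTREAM_WINDOW = 30

#: Start-context downstream extent: positions 0..+5, enough to cover an
#: overlap pentamer (0..4) plus the post-pentamer base at +5.
CONTEXT_DOWN = 6


class GenomeParseError(ValueError):
    """The input annotation could not be parsed."""


class WindowError(ValueError):
    """A requested sequence window is invalid (e.g. longer than the replicon)."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS in mRNA sense.

    ``upstream_seq`` covers positions ``[-len, 0)`` immediately 5' of the
    annotated start; ``context_seq`` covers ``[context_start, context_start
    + len)`` and is ``[-2, +6)`` unless truncated at a linear replicon
    edge. Both are DNA, mRNA sense (reverse-complemented for reverse-strand
    genes).
    """

    gene_id: str
    locus_tag: str
    name: str
    strand: str  # '+' or '-'
    cds_interval: tuple[int, int]  # 0-based half-open forward-strand span
    start_anchor: int  # forward-strand coordinate of the start codon's first base
    annotated_start_codon: str
    upstream_seq: str
    context_seq: str
    context_start: int
    is_pseudo: bool
    replicon_id: str


@dataclass
class GenomeAnnotationSet:
    """A replicon with its CDS records and a skip report."""

    replicon_id: str
    topology: str  # 'circular' | 'linear'
    sequence: str  # forward-strand DNA
    genes: list[GeneRecord] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeParseError(f"duplicate gene ids: {', '.join(dup)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _fetch_window(sequence: str, lo: int, hi: int, circular: bool) -> str:
    """Forward-strand slice [lo, hi), wrapping when circular, clamping when linear."""
    L = len(sequence)
    if circular and hi - lo > L:
        raise WindowError(f"window of {hi - lo} nt exceeds circular replicon length {L}")
    if circular:
        lo_m = lo % L
        span = hi - lo
        if lo_m + span <= L:
            return sequence[lo_m : lo_m + span]
        return sequence[lo_m:] + sequence[: lo_m + span - L]
    return sequence[max(lo, 0) : max(hi, 0)]


def window_relative_to_start(
    sequence: str,
    start_anchor: int,
    strand: str,
    up_len: int,
    down_len: int,
    circular: bool,
) -> str:
    """mRNA-sense slice spanning [-up_len, +down_len) around a start anchor."""
    if up_len < 0 or down_len < 0:
        raise WindowError("window lengths must be non-negative")
    if strand == "+":
        return _fetch_window(sequence, start_anchor - up_len, start_anchor + down_len, circular)
    sub = _fetch_window(
        sequence, start_anchor - down_len + 1, start_anchor + up_len + 1, circular
    )
    return revcomp_dna(sub)


def mrna_context(genome: GenomeAnnotationSet, gene: GeneRecord, up_len: int, down_len: int) -> str:
    """mRNA-sense sequence spanning [-up_len, +down_len) around the gene's start.

    Truncated (never padded) at replicon bounds on a linear replicon; wraps
    on a circular one. ``up_len=0, down_len=3`` returns the annotated start
    codon itself.
    """
    return window_relative_to_start(
        genome.sequence,
        gene.start_anchor,
        gene.strand,
        up_len,
        down_len,
        genome.topology == "circular",
    )


def _is_fuzzy(location) -> bool:
    for part in location.parts:
        if not isinstance(part.start, ExactPosition) or not isinstance(part.end, ExactPosition):
            return True
    return False


def _start_anchor(feature, sequence: str, circular: bool) -> int | None:
    """Forward-strand coordinate of the start codon's first base.

    For joined (compound) locations the first codon of the joined mRNA is
    used; the anchor is validated against the spliced mRNA and alternative
    part boundaries are tried if the primary convention disagrees.
    """
    parts = feature.location.parts
    strand = "+" if feature.location.strand == 1 else "-"
    mrna = str(feature.location.extract(Seq(sequence))).upper()
    if len(mrna) < 3:
        return None
    first_codon = mrna[:3]
    if strand == "+":
        candidates = [int(p.start) for p in parts]
    else:
        candidates = [int(p.end) - 1 for p in parts]
    for anchor in candidates:
        codon = window_relative_to_start(sequence, anchor, strand, 0, 3, circular)
        if codon == first_codon:
            return anchor
    return None


def _gene_records_from_features(
    features,
    sequence: str,
    replicon_id: str,
    topology: str,
    upstream_window: int,
) -> tuple[list[GeneRecord], list[tuple[str, str]]]:
    circular = topology == "circular"
    genes: list[GeneRecord] = []
    skipped: list[tuple[str, str]] = []
    seen_ids: set[str] = set()
    for idx, feat in enumerate(features):
        locus = feat.qualifiers.get("locus_tag", [None])[0]
        name = feat.qualifiers.get("gene", [None])[0]
        label = locus or name or f"CDS_{idx}"
        if feat.location is None or feat.location.strand not in (1, -1):
            skipped.append((label, "missing or unstranded location"))
            log.warning("skipping CDS %s: missing or unstranded location", label)
            continue
        if _is_fuzzy(feat.location):
            skipped.append((label, "fuzzy location"))
            log.warning("skipping CDS %s: fuzzy location (start codon undefined)", label)
            continue
        anchor = _start_anchor(feat, sequence, circular)
        if anchor is None:
            skipped.append((label, "start codon could not be anchored"))
            log.warning("skipping CDS %s: start codon could not be anchored", label)
            continue
        strand = "+" if feat.location.strand == 1 else "-"
        upstream = window_relative_to_start(sequence, anchor, strand, upstream_window, 0, circular)
        context = window_relative_to_start(sequence, anchor, strand, 2, CONTEXT_DOWN, circular)
        # On a linear replicon the -2..-1 side may be truncated; record the
        # actual relative start of the context so consumers can tell.
        up2 = window_relative_to_start(sequence, anchor, strand, 2, 0, circular)
        context_start = -len(up2)
        codon = window_relative_to_start(sequence, anchor, strand, 0, 3, circular)
        is_pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        gene_id = locus or name or f"CDS_{idx}"
        if gene_id in seen_ids:
            gene_id = f"{gene_id}.{idx}"
        seen_ids.add(gene_id)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                locus_tag=locus or gene_id,
                name=name or gene_id,
                strand=strand,
                cds_interval=(int(feat.location.start), int(feat.location.end)),
                start_anchor=anchor,
                annotated_start_codon=codon,
                upstream_seq=upstream,
                context_seq=context,
                context_start=context_start,
                is_pseudo=is_pseudo,
                replicon_id=replicon_id,
            )
        )
    genes.sort(key=lambda g: (g.cds_interval[0], g.cds_interval[1], g.gene_id))
    return genes, skipped


def _from_seqrecord(rec: SeqRecord, upstream_window: int) -> GenomeAnnotationSet:
    sequence = validate_dna(str(rec.seq))
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    features = [f for f in rec.features if f.type == "CDS"]
    genes, skipped = _gene_records_from_features(
        features, sequence, rec.id, topology, upstream_window
    )
    return GenomeAnnotationSet(
        replicon_id=rec.id, topology=topology, sequence=sequence, genes=genes, skipped=skipped
    )


def parse_genbank_multi(
    path: str | Path, upstream_window: int = DEFAULT_UPSTREAM_WINDOW
) -> list[GenomeAnnotationSet]:
    """Parse every record of a (possibly multi-record) GenBank flat file."""
    path = Path(path)
    if not path.exists():
        raise GenomeParseError(f"no such file: {path}")
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeParseError(f"could not parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no sequence records in {path}")
    return [_from_seqrecord(rec, upstream_window) for rec in records]


def parse_genbank(
    path: str | Path, upstream_window: int = DEFAULT_UPSTREAM_WINDOW
) -> GenomeAnnotationSet:
    """Parse a single-record GenBank flat file into a :class:`GenomeAnnotationSet`."""
    sets = parse_genbank_multi(path, upstream_window)
    if len(sets) > 1:
        raise GenomeParseError(
            f"{path} contains {len(sets)} records; use parse_genbank_multi()"
        )
    return sets[0]


def parse_fasta_gff(
    fasta_path: str | Path,
    gff_path: str | Path,
    topology: str = "linear",
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> GenomeAnnotationSet:
    """Sequence-only mode: FASTA replicon plus CDS features from a GFF3 file."""
    import gffutils

    fasta_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(fasta_records) != 1:
        raise GenomeParseError(f"expected exactly one FASTA record in {fasta_path}")
    rec = fasta_records[0]
    sequence = validate_dna(str(rec.seq))
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    features = []
    for f in db.features_of_type("CDS", order_by="start"):
        strand = 1 if f.strand == "+" else (-1 if f.strand == "-" else None)
        qualifiers: dict[str, list[str]] = {}
        for key, target in (("locus_tag", "locus_tag"), ("gene", "gene"), ("Name", "gene")):
            if key in f.attributes and target not in qualifiers:
                qualifiers[target] = list(f.attributes[key])
        if "ID" in f.attributes and "locus_tag" not in qualifiers:
            qualifiers["locus_tag"] = list(f.attributes["ID"])
        if f.attributes.get("pseudo") or f.attributes.get("pseudogene"):
            qualifiers["pseudo"] = [""]
        location = SimpleLocation(f.start - 1, f.end, strand=strand)
        features.append(SeqFeature(location=location, type="CDS", qualifiers=qualifiers))
    genes, skipped = _gene_records_from_features(
        features, sequence, rec.id, topology, upstream_window
    )
    return GenomeAnnotationSet(
        replicon_id=rec.id, topology=topology, sequence=sequence, genes=genes, skipped=skipped
    )


def to_seqrecord(genome: GenomeAnnotationSet) -> SeqRecord:
    """Render a genome set as a Biopython SeqRecord with simple CDS locations."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.replicon_id,
        name=genome.replicon_id[:16],
        description="",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    rec.annotations["data_file_division"] = "SYN"
    rec.annotations["date"] = "01-JAN-1980"  # fixed: keeps output byte-stable
    for gene in genome.genes:
        qualifiers = {"gene": [gene.name], "locus_tag": [gene.locus_tag]}
        if gene.is_pseudo:
            qualifiers["pseudo"] = [""]
        start, end = gene.cds_interval
        rec.features.append(
            SeqFeature(
                SimpleLocation(start, end, strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    return rec


def write_genbank(genome: GenomeAnnotationSet, path: str | Path) -> Path:
    """Write a genome set to a GenBank flat file (byte-stable for fixed input)."""
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write([to_seqrecord(genome)], fh, "genbank")
    return path


def write_fasta(genome: GenomeAnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(
            [SeqRecord(Seq(genome.sequence), id=genome.replicon_id, description="")], fh, "fasta"
        )
    return path
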