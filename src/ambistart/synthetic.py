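"""Synthetic annotated genomes with planted start-codon overlaps.

Every pipeline stage is testable without downloads: a plant specification
fixes the overlap class, the SD motif(s) with their spacers, the
post-pentamer base and the strand, and the generator embeds the
corresponding RBS —

    [random pad][SD motif][spacer][pentamer][post-pentamer base][CDS body]

— into a replicon together with decoy genes, emitting a truth manifest of
the expected scan output (class, SD motifs, D_toStart values, ambiguity
label). Free bases are rejection-sampled so that no unintended
aSD-complementary stretch competes with the planted motif and no unintended
pentamer spans the start; an arrangement that cannot satisfy the
constraints (e.g. a motif whose register is extendable into the fixed
pentamer bases) fails with an error after a bounded number of retries
rather than silently shipping an inconsistent fixture.

Defaults mirror the designed reporter RBS used to calibrate the
classification windows: the strong 8-nt SD ``UAAGGAGG`` with a 4-nt spacer
(aligned spacing D_toStart 12/14, the center of the ambiguous window).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import genome as genome_mod
from .ambiguity import AmbiguityWindows, DEFAULT_WINDOWS, classify_ambiguity
from .genome import GenomeAnnotationSet, write_genbank
from .overlaps import OverlapClass, StartOverlap, classify_overlap, find_start_overlaps
from .sd import AntiSD, DEFAULT_ASD, SDMatch, compute_d_to_start, find_sd_matches
from .sequence import revcomp_dna, revcomp_rna, to_dna, to_rna

UPSTREAM_WINDOW = 30
_MAX_TRIES = 200
_STOP_CODONS = {"TAA", "TAG", "TGA"}


class FixtureError(ValueError):
    """A plant specification cannot be realized as a consistent fixture."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted overlap gene.

    ``sd_motif`` (RNA or DNA) must be Watson-Crick complementary to a
    contiguous anti-SD substring, or ``None`` for an SD-less plant.
    ``spacer_to_annotated`` counts nucleotides between the motif's 3' end
    and the annotated start codon; for 3'-placed codons the last two of
    those are the pentamer's first two bases, so the spacer must be >= 2.
    ``extra_sds`` plants additional (motif, spacer) pairs — overlapping
    motifs are merged where their letters agree, the *tamA*-style
    dual-SD arrangement among them.
    """

    gene_id: str
    overlap_class: OverlapClass
    sd_motif: str | None = "UAAGGAGG"
    spacer_to_annotated: int = 4
    post_pentamer_base: str = "C"
    strand: str = "+"
    is_pseudo: bool = False
    cds_len: int = 36
    extra_sds: tuple[tuple[str, int], ...] = ()

    def all_sds(self) -> list[tuple[str, int]]:
        sds = [] if self.sd_motif is None else [(self.sd_motif, self.spacer_to_annotated)]
        sds.extend(self.extra_sds)
        return sds


@dataclass(frozen=True)
class TruthEntry:
    """Expected scan output for one planted gene."""

    gene_id: str
    overlap_class: OverlapClass
    sd_motifs: tuple[str, ...]  # RNA, report order (pairing closest to the 16S 3' end first)
    d_annotated: tuple[int, ...]
    d_competitor: tuple[int, ...]
    label: str
    dual_sd: bool
    tere_dependent: bool
    is_pseudo: bool
    strand: str


def motif_register(motif: str, asd: AntiSD = DEFAULT_ASD) -> tuple[int, int]:
    """(i, e) anti-SD positions paired by ``motif`` (unique for the default aSD)."""
    rna = to_rna(motif)
    hits = []
    for i in range(1, 10):
        for e in range(i, 10):
            if revcomp_rna(asd.substring(i, e)) == rna:
                hits.append((i, e))
    if not hits:
        raise FixtureError(f"{motif} is not complementary to a contiguous anti-SD substring")
    if len(hits) > 1:
        raise FixtureError(f"{motif} has multiple registers in {asd.sequence}")
    return hits[0]


def d_to_start_of_plant(motif: str, spacer: int, asd: AntiSD = DEFAULT_ASD) -> int:
    """D_toStart of the annotated codon implied by a planted motif + spacer."""
    i, e = motif_register(motif, asd)
    k = e - i + 1
    return (9 - e) + k + spacer


def _choose(rng: random.Random, a_fraction: float) -> str:
    """One background base; ``a_fraction`` > 0.25 mimics A-rich 5' UTRs."""
    rest = (1.0 - a_fraction) / 3.0
    return rng.choices("ACGT", weights=[a_fraction, rest, rest, rest])[0]


def _build_upstream(
    spec: PlantSpec, rng: random.Random, asd: AntiSD, a_fraction: float
) -> str:
    """The 30-nt window [-30, 0), with motifs planted and free bases sampled."""
    slots: list[str | None] = [None] * UPSTREAM_WINDOW
    pent = spec.overlap_class.pentamer
    if spec.overlap_class.pentamer_start == -2:
        if any(sp < 2 for _, sp in spec.all_sds()):
            raise FixtureError(f"{spec.gene_id}: spacer must be >= 2 for 3'-placed codons")
        slots[-2], slots[-1] = pent[0], pent[1]
    expected: set[tuple[str, int]] = set()
    for motif, spacer in spec.all_sds():
        dna = to_dna(motif)
        k = len(dna)
        if spacer < 0 or spacer + k > UPSTREAM_WINDOW:
            raise FixtureError(f"{spec.gene_id}: motif {motif} at spacer {spacer} does not fit")
        start = UPSTREAM_WINDOW - spacer - k
        for j, ch in enumerate(dna):
            if slots[start + j] is not None and slots[start + j] != ch:
                raise FixtureError(
                    f"{spec.gene_id}: motif {motif} at spacer {spacer} conflicts with fixed bases"
                )
            slots[start + j] = ch
        expected.add((to_rna(motif), start - UPSTREAM_WINDOW))
    free = [idx for idx, ch in enumerate(slots) if ch is None]
    for _ in range(_MAX_TRIES):
        for idx in free:
            slots[idx] = _choose(rng, a_fraction)
        window = "".join(slots)  # type: ignore[arg-type]
        if expected:
            found = {
                (m.motif, m.mrna_start)
                for m in find_sd_matches(window, asd=asd, longest_only=True)
            }
            if found == expected:
                return window
        else:
            if not find_sd_matches(window, asd=asd, longest_only=False):
                return window
        for idx in free:
            slots[idx] = None
    raise FixtureError(
        f"{spec.gene_id}: could not realize the upstream window in {_MAX_TRIES} tries "
        "(planted motif probably extendable into fixed bases)"
    )


def _build_cds(spec: PlantSpec, rng: random.Random) -> str:
    """The CDS (start through stop), honoring class, post-pentamer base and length."""
    if spec.cds_len % 3 or spec.cds_len < 12:
        raise FixtureError(f"{spec.gene_id}: cds_len must be a multiple of 3, >= 12")
    post = to_dna(spec.post_pentamer_base)
    if len(post) != 1:
        raise FixtureError("post_pentamer_base must be a single nucleotide")
    if spec.overlap_class.pentamer_start == 0:
        prefix = spec.overlap_class.pentamer + post  # positions 0..5
    else:
        prefix = "GTG" + post  # pentamer tail GTG, then +3 = post base
    for _ in range(_MAX_TRIES):
        body_len = spec.cds_len - 3 - len(prefix)
        body = "".join(_choose(rng, 0.25) for _ in range(body_len))
        cds = prefix + body + "TAA"
        internal = any(cds[i : i + 3] in _STOP_CODONS for i in range(3, len(cds) - 3, 3))
        if internal:
            continue
        # no unintended second pentamer placement across the start
        if spec.overlap_class.annotated_codon == "GTG":
            if spec.overlap_class.pentamer_start == -2 and cds[0:5] == "GTGTG":
                continue
        return cds
    raise FixtureError(f"{spec.gene_id}: could not realize a clean CDS body")


def _build_decoy(
    rng: random.Random, idx: int, asd: AntiSD, a_fraction: float, with_sd: bool
) -> tuple[str, str]:
    """(upstream window, CDS) for a decoy gene with no pentamer at its start."""
    codon = rng.choice(["ATG", "ATG", "GTG", "TTG"])
    for _ in range(_MAX_TRIES):
        if with_sd:
            motif = rng.choice(["AGGAGG", "GGAGG", "AGGA", "GAGG", "UAAGG"])
            spacer = rng.randint(4, 9)
            spec = PlantSpec(
                gene_id=f"decoy{idx}",
                overlap_class=OverlapClass.ATGtg,  # placeholder, only sds used
                sd_motif=motif,
                spacer_to_annotated=spacer,
            )
            slots: list[str | None] = [None] * UPSTREAM_WINDOW
            dna = to_dna(motif)
            start = UPSTREAM_WINDOW - spacer - len(dna)
            for j, ch in enumerate(dna):
                slots[start + j] = ch
            for i2, ch in enumerate(slots):
                if ch is None:
                    slots[i2] = _choose(rng, a_fraction)
            window = "".join(slots)  # type: ignore[arg-type]
            found = {
                (m.motif, m.mrna_start)
                for m in find_sd_matches(window, asd=asd, longest_only=True)
            }
            if found != {(to_rna(motif), start - UPSTREAM_WINDOW)}:
                continue
        else:
            window = "".join(_choose(rng, a_fraction) for _ in range(UPSTREAM_WINDOW))
            if find_sd_matches(window, asd=asd, longest_only=False):
                continue
        body = "".join(_choose(rng, 0.25) for _ in range(27))
        cds = codon + body + "TAA"
        if any(cds[i : i + 3] in _STOP_CODONS for i in range(3, len(cds) - 3, 3)):
            continue
        context = window[-2:] + cds[:6]
        if classify_overlap(context, codon) if codon in ("ATG", "GTG") else ():
            continue
        return window, cds
    raise FixtureError(f"decoy{idx}: could not realize a pentamer-free start context")


def _expected_entry(
    spec: PlantSpec, asd: AntiSD, windows: AmbiguityWindows
) -> TruthEntry:
    """Manifest entry from the D formula (independent of the genome scan)."""
    cls = spec.overlap_class
    comp_off = 2 if cls.pentamer_start == 0 else -2
    sds = spec.all_sds()
    regs = [(motif, spacer, *motif_register(motif, asd)) for motif, spacer in sds]
    # report order: pairing closest to the 16S 3' terminus first, then 5'->3'
    regs.sort(key=lambda t: (-t[3], UPSTREAM_WINDOW - t[1] - (t[3] - t[2] + 1)))
    motifs = tuple(to_rna(m) for m, _, _, _ in regs)
    d_ann = tuple((9 - e) + (e - i + 1) + sp for _, sp, i, e in regs)
    d_comp = tuple(d + comp_off for d in d_ann)
    # label via the classifier on a profile rebuilt from the planted geometry
    overlap = StartOverlap(
        gene_id=spec.gene_id,
        overlap_class=cls,
        pentamer_start=cls.pentamer_start,
        competitor_offset=comp_off,
        a4_base="T" if cls.pentamer_start == 0 else to_dna(spec.post_pentamer_base),
        post_pentamer_base=to_dna(spec.post_pentamer_base),
        has_start_stop=to_dna(spec.post_pentamer_base) == "A",
    )
    profile = []
    for motif, spacer, i, e in regs:
        k = e - i + 1
        match = SDMatch(
            motif=to_rna(motif),
            mrna_start=-(spacer + k),
            mrna_end=-spacer,
            asd_start=i,
            asd_end=e,
        )
        for off in (0, comp_off):
            profile.append(compute_d_to_start(match, off))
    call = classify_ambiguity(overlap, profile, windows)
    return TruthEntry(
        gene_id=spec.gene_id,
        overlap_class=cls,
        sd_motifs=motifs,
        d_annotated=d_ann,
        d_competitor=d_comp,
        label=call.label.value,
        dual_sd=call.dual_sd,
        tere_dependent=call.tere_dependent,
        is_pseudo=spec.is_pseudo,
        strand=spec.strand,
    )


@dataclass
class SyntheticGenome:
    genome: GenomeAnnotationSet
    manifest: list[TruthEntry]
    genbank_path: Path | None = None
    manifest_path: Path | None = None


def generate_synthetic_genome(
    specs: list[PlantSpec],
    n_decoys: int = 0,
    seed: int = 0,
    topology: str = "linear",
    origin_in_upstream_of: str | None = None,
    out_dir: str | Path | None = None,
    asd: AntiSD = DEFAULT_ASD,
    windows: AmbiguityWindows = DEFAULT_WINDOWS,
    a_fraction: float = 0.25,
    replicon_id: str = "synth1",
) -> SyntheticGenome:
    """Assemble a replicon from plant specs plus decoys; return it with its manifest.

    Deterministic for a given seed (byte-identical GenBank output).
    Reverse-strand plants are reverse-complemented into the replicon;
    ``origin_in_upstream_of`` rotates a circular replicon so that the named
    gene's upstream window spans the origin.
    """
    if topology not in ("linear", "circular"):
        raise ValueError("topology must be 'linear' or 'circular'")
    if origin_in_upstream_of is not None and topology != "circular":
        raise ValueError("origin_in_upstream_of requires a circular replicon")
    rng = random.Random(seed)
    pieces: list[str] = []
    features: list[tuple[int, int, str, str, str, bool]] = []  # start,end,strand,id,name,pseudo
    pos = 0
    anchors: dict[str, int] = {}

    def _pad(n: int) -> None:
        nonlocal pos
        pad = "".join(_choose(rng, a_fraction) for _ in range(n))
        pieces.append(pad)
        pos += n

    _pad(10)
    entries: list[TruthEntry] = []
    half = n_decoys // 2
    decoy_queue = [(True, i) for i in range(half)] + [(False, i) for i in range(half, n_decoys)]
    for spec in specs:
        entries.append(_expected_entry(spec, asd, windows))
        for _ in range(_MAX_TRIES):
            window = _build_upstream(spec, rng, asd, a_fraction)
            cds = _build_cds(spec, rng)
            # exactly the planted placement, no accidental second pentamer
            context = window[-2:] + cds[:6]
            if classify_overlap(context, spec.overlap_class.annotated_codon) == (
                spec.overlap_class,
            ):
                break
        else:
            raise FixtureError(
                f"{spec.gene_id}: could not avoid an unintended pentamer placement"
            )
        cassette = window + cds
        if spec.strand == "+":
            cds_start = pos + len(window)
            cds_end = cds_start + len(cds)
            anchors[spec.gene_id] = cds_start
        else:
            cassette = revcomp_dna(cassette)
            cds_start = pos
            cds_end = pos + len(cds)
            anchors[spec.gene_id] = cds_end - 1
        features.append((cds_start, cds_end, spec.strand, spec.gene_id, spec.gene_id, spec.is_pseudo))
        pieces.append(cassette)
        pos += len(cassette)
        _pad(12)
    for with_sd, i in decoy_queue:
        window, cds = _build_decoy(rng, i, asd, a_fraction, with_sd)
        cds_start = pos + len(window)
        features.append((cds_start, cds_start + len(cds), "+", f"decoy{i}", f"decoy{i}", False))
        pieces.append(window + cds)
        pos += len(window) + len(cds)
        _pad(12)
    sequence = "".join(pieces)

    if origin_in_upstream_of is not None:
        target = next((s for s in specs if s.gene_id == origin_in_upstream_of), None)
        if target is None:
            raise ValueError(f"unknown gene for origin rotation: {origin_in_upstream_of}")
        if target.strand != "+":
            raise ValueError("origin rotation is supported for forward-strand plants")
        cut = anchors[target.gene_id] - UPSTREAM_WINDOW // 2
        L = len(sequence)
        sequence = sequence[cut:] + sequence[:cut]
        features = [
            ((s - cut) % L, (e - cut) % L, st, gid, nm, ps) for s, e, st, gid, nm, ps in features
        ]

    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(sequence), id=replicon_id, name=replicon_id, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    rec.annotations["data_file_division"] = "SYN"
    rec.annotations["date"] = "01-JAN-1980"
    for s, e, st, gid, nm, ps in features:
        quals = {"gene": [nm], "locus_tag": [gid]}
        if ps:
            quals["pseudo"] = [""]
        rec.features.append(
            SeqFeature(SimpleLocation(s, e, strand=1 if st == "+" else -1), type="CDS", qualifiers=quals)
        )
    genome = genome_mod._from_seqrecord(rec, UPSTREAM_WINDOW)

    result = SyntheticGenome(genome=genome, manifest=entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.genbank_path = write_genbank(genome, out_dir / f"{replicon_id}.gbk")
        result.manifest_path = write_manifest(entries, out_dir / "truth_manifest.tsv")
    return result


def write_manifest(entries: list[TruthEntry], path: str | Path) -> Path:
    path = Path(path)
    cols = [
        "gene_id",
        "overlap_class",
        "sd_motifs",
        "d_annotated",
        "d_competitor",
        "label",
        "dual_sd",
        "tere_dependent",
        "is_pseudo",
        "strand",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in entries:
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.overlap_class.value,
                        ",".join(t.sd_motifs) or "-",
                        ",".join(map(str, t.d_annotated)) or "-",
                        ",".join(map(str, t.d_competitor)) or "-",
                        t.label,
                        str(t.dual_sd),
                        str(t.tere_dependent),
                        str(t.is_pseudo),
                        t.strand,
                    ]
                )
                + "\n"
            )
    return path


def default_plant_suite() -> list[PlantSpec]:
    """Representative plants spanning the classification's regimes.

    The designed-reporter series (strong SD ``UAAGGAGG`` at spacers 2, 4 and
    6: D_toStart 10/12, 12/14 and 14/16) plus native-style arrangements: a
    short-spaced 3'-exclusive site, a dual-SD site, and a start-stop site
    whose annotated 3' codon rides on termination-reinitiation.
    """
    return [
        PlantSpec("rep10", OverlapClass.ATGtg, "UAAGGAGG", 2),
        PlantSpec("rep12", OverlapClass.ATGtg, "UAAGGAGG", 4),
        PlantSpec("rep14", OverlapClass.ATGtg, "UAAGGAGG", 6),
        PlantSpec("hdhA_like", OverlapClass.atGTG, "AGGAGGU", 4),
        PlantSpec("pqiA_like", OverlapClass.ATGtg, "UAAGGAG", 5),
        PlantSpec("tamA_like", OverlapClass.atGTG, "AGGAG", 5, extra_sds=(("AAGGA", 15),)),
        PlantSpec("narQ_like", OverlapClass.gtGTG, "GGAG", 9, post_pentamer_base="A"),
        PlantSpec("rev_plant", OverlapClass.ATGtg, "UAAGGAGG", 4, strand="-"),
        PlantSpec("pseudo_plant", OverlapClass.ATGtg, "UAAGGAGG", 4, is_pseudo=True),
    ]
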