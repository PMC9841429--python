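"""Shine-Dalgarno motif detection and aligned-spacing (D_toStart) arithmetic.

A Shine-Dalgarno (SD) motif is defined here as a maximal stretch of four or
more nucleotides within the upstream window (default 30 nt) that can form
contiguous Watson-Crick base pairs with the anti-SD (aSD), the 3'-terminal
9 nt of the 16S rRNA (``ACCUCCUUA`` in *E. coli*, written 5'->3' and indexed
p1..p9 with p9 the 3'-terminal nucleotide). No G:U wobble pairs are allowed.

Because the SD:aSD duplex is antiparallel, a motif pairing aSD positions
p_i..p_e fixes the register of the 16S 3' end on the mRNA. The aligned
spacing of a candidate start codon is then

    D_toStart = (9 - e) + k + spacer

where ``k = e - i + 1`` is the duplex length and ``spacer`` is the number of
nucleotides between the motif's 3' end and the first nucleotide of the
codon. D_toStart measures the distance from the mRNA position opposite the
16S 3'-terminal nucleotide to the start codon; initiation is experimentally
optimal around D_toStart 13-14.

Coordinates throughout are relative to the annotated start codon: position
0 is its first nucleotide, upstream positions are negative, and an upstream
window of length L covers ``[-L, 0)``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .sequence import revcomp_rna, to_rna, validate_rna

#: Aligned spacing experimentally optimal for initiation; used to pick each
#: gene's canonical SD when several maximal motifs tie.
OPTIMAL_D_TO_START = 14

_RNA_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class AntiSD:
    """The anti-SD: the 3'-terminal 9 nt of the 16S rRNA, 5'->3'.

    ``sequence[8]`` (p9) is the 16S 3'-terminal nucleotide. The length-9
    semantics are fixed; the letters are configurable for other species.
    """

    sequence: str = "ACCUCCUUA"

    def __post_init__(self) -> None:
        seq = validate_rna(self.sequence)
        if len(seq) != 9:
            raise ValueError(f"anti-SD must be exactly 9 nt, got {len(seq)}")
        object.__setattr__(self, "sequence", seq)

    def substring(self, i: int, e: int) -> str:
        """aSD positions p_i..p_e (1-based inclusive)."""
        return self.sequence[i - 1 : e]

    def registers_unique(self, min_len: int = 4) -> bool:
        """True when every substring of length >= min_len occurs once.

        Holds for the default *E. coli* sequence, so each motif has exactly
        one pairing register; for custom aSD sequences where it fails, all
        registers of a motif are reported.
        """
        seen = set()
        n = len(self.sequence)
        for k in range(min_len, n + 1):
            for i in range(0, n - k + 1):
                sub = self.sequence[i : i + k]
                if sub in seen:
                    return False
                seen.add(sub)
        return True


DEFAULT_ASD = AntiSD()


@dataclass(frozen=True)
class SDMatch:
    """A maximal Watson-Crick complement between the upstream mRNA and the aSD.

    Attributes
    ----------
    motif:
        The mRNA-side sequence (RNA, 5'->3'), equal to the reverse
        complement of ``asd[p_i..p_e]``.
    mrna_start, mrna_end:
        Half-open interval of the motif relative to the annotated start
        codon (both negative or zero; ``mrna_end <= 0`` for a motif inside
        the upstream window).
    asd_start, asd_end:
        1-based inclusive aSD positions p_i..p_e paired by the motif
        (antiparallel).
    """

    motif: str
    mrna_start: int
    mrna_end: int
    asd_start: int
    asd_end: int

    @property
    def length(self) -> int:
        return self.asd_end - self.asd_start + 1

    def __post_init__(self) -> None:
        if self.mrna_end - self.mrna_start != self.length != len(self.motif):
            raise ValueError("inconsistent SD match geometry")


@dataclass(frozen=True)
class SpacingResult:
    """D_toStart of one candidate start codon under one SD match.

    ``codon_offset`` is the position of the candidate codon's first
    nucleotide relative to the annotated start (-2, 0 or +2 for overlap
    pentamers). ``spacer_len`` may be negative when the SD match overlaps
    the codon; such results are flagged and excluded from ambiguity
    classification.
    """

    sd: SDMatch
    codon_offset: int
    spacer_len: int
    d_to_start: int
    sd_overlaps_codon: bool


def find_sd_matches(
    upstream: str,
    asd: AntiSD = DEFAULT_ASD,
    min_len: int = 4,
    longest_only: bool = True,
) -> list[SDMatch]:
    """Detect SD motifs in an upstream window.

    Parameters
    ----------
    upstream:
        The mRNA-sense window immediately 5' of the annotated start codon
        (DNA or RNA; at most 30 nt by the survey's definition, enforced by
        the caller). The window covers positions ``[-len(upstream), 0)``.
    min_len:
        Minimum duplex length (default 4 nt).
    longest_only:
        When true (the survey's rule), report only matches whose length
        equals the maximum found; ties are all reported.

    Returns
    -------
    Matches sorted 5'->3' by position. Each match is *maximal*: it cannot be
    extended by one nucleotide on either side and remain Watson-Crick
    complementary to the aSD.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    u = to_rna(upstream)
    L = len(u)
    n = len(asd.sequence)
    matches: list[SDMatch] = []
    for i in range(1, n + 1):
        for e in range(i + min_len - 1, n + 1):
            k = e - i + 1
            target = revcomp_rna(asd.substring(i, e))
            start = 0
            while True:
                p = u.find(target, start)
                if p < 0:
                    break
                start = p + 1
                # Extending the motif 5' pairs aSD p_{e+1}; extending it 3'
                # pairs p_{i-1}. Reject extendable occurrences: the longer
                # register reports them.
                ext5 = e < n and p > 0 and u[p - 1] == _RNA_PAIR[asd.sequence[e]]
                ext3 = i > 1 and p + k < L and u[p + k] == _RNA_PAIR[asd.sequence[i - 2]]
                if not ext5 and not ext3:
                    matches.append(
                        SDMatch(
                            motif=target,
                            mrna_start=p - L,
                            mrna_end=p - L + k,
                            asd_start=i,
                            asd_end=e,
                        )
                    )
    if longest_only and matches:
        kmax = max(m.length for m in matches)
        matches = [m for m in matches if m.length == kmax]
    matches.sort(key=lambda m: (m.mrna_start, -m.length, m.asd_start))
    return matches


def compute_d_to_start(sd: SDMatch, codon_offset: int) -> SpacingResult:
    """Aligned spacing of the codon at ``codon_offset`` under ``sd``.

    ``D_toStart = (9 - e) + k + spacer`` with
    ``spacer = codon_offset - sd.mrna_end``. A negative spacer (SD overlaps
    the codon) is computed but flagged.
    """
    spacer = codon_offset - sd.mrna_end
    d = (9 - sd.asd_end) + sd.length + spacer
    return SpacingResult(
        sd=sd,
        codon_offset=codon_offset,
        spacer_len=spacer,
        d_to_start=d,
        sd_overlaps_codon=spacer < 0,
    )


def spacing_profile(
    gene,
    overlap,
    asd: AntiSD = DEFAULT_ASD,
    min_len: int = 4,
    longest_only: bool = True,
) -> list[SpacingResult]:
    """D_toStart of both overlap codons under every reported SD match.

    The cross product of the gene's reported SD matches with the two
    candidate codons of ``overlap`` (the annotated codon at 0 and the
    competitor at ``overlap.competitor_offset``). Empty when the upstream
    window carries no SD motif.
    """
    matches = find_sd_matches(gene.upstream_seq, asd=asd, min_len=min_len, longest_only=longest_only)
    profile: list[SpacingResult] = []
    for m in matches:
        for offset in (0, overlap.competitor_offset):
            profile.append(compute_d_to_start(m, offset))
    return profile


def canonical_spacing(results: Sequence[SpacingResult]) -> SpacingResult | None:
    """The canonical SD's spacing for the annotated codon.

    Among annotated-codon (offset 0) results, picks the one whose D_toStart
    is closest to the experimental optimum (14); ties break toward the
    longer motif, then the more 3' match.
    """
    annotated = [r for r in results if r.codon_offset == 0]
    if not annotated:
        return None
    return min(
        annotated,
        key=lambda r: (abs(r.d_to_start - OPTIMAL_D_TO_START), -r.sd.length, -r.sd.mrna_end),
    )


def genome_spacing_distribution(
    genome,
    asd: AntiSD = DEFAULT_ASD,
    min_len: int = 4,
    start_codons: tuple[str, ...] = ("AUG", "GUG"),
) -> pd.DataFrame:
    """Genome-wide D_toStart histogram for SD-led genes.

    For every non-pseudo gene whose annotated start codon is in
    ``start_codons`` and whose upstream window carries at least one SD
    motif, the canonical SD (closest to D_toStart 14) contributes one count
    at its annotated-codon D_toStart. Genes without an SD are omitted
    (SD-led genes only).

    Returns a DataFrame with columns ``start_codon``, ``d_to_start``,
    ``count`` sorted by codon then spacing.
    """
    counts: collections.Counter = collections.Counter()
    for gene in genome.genes:
        if gene.is_pseudo:
            continue
        codon = to_rna(gene.annotated_start_codon)
        if codon not in start_codons:
            continue
        matches = find_sd_matches(gene.upstream_seq, asd=asd, min_len=min_len, longest_only=True)
        results = [compute_d_to_start(m, 0) for m in matches]
        canon = canonical_spacing(results)
        if canon is None:
            continue
        counts[(codon, canon.d_to_start)] += 1
    rows = [
        {"start_codon": codon, "d_to_start": d, "count": c}
        for (codon, d), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["start_codon", "d_to_start", "count"])
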