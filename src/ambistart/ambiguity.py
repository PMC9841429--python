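"""Initiation-ambiguity classification from aligned spacing.

Reporter experiments with a constant strong SD (UAAGGAGG) and variable
spacers establish how the aligned spacing of the 5' codon (D5 = D_toStart
of the pentamer's 5' codon; the 3' codon sits at D5 + 2) partitions
initiation between the two overlapping start codons:

AUGUG pentamers
    D5 <= 11            initiation exclusively at the 3' GUG
    D5 == 12            both codons used, AUG favored (~3.5x in vitro)
    13 <= D5 <= 16      exclusively the 5' AUG; residual GUG activity only
    D5 >= 17            extrapolated: still 5'-exclusive, low confidence

GUGUG pentamers
    D5 <= 11            exclusively the 3' GUG (short spacing physically
                        excludes the 5' codon from the P site)
    D5 == 12            both used, 3' GUG slightly favored
    13 <= D5 <= 16      both used, preference shifted to the 5' GUG
    D5 >= 17            indeterminate (outside the calibrated range)

The windows ship as editable configuration, not constants. Classification
uses the gene's canonical SD — the maximal match whose annotated-codon
D_toStart is closest to the experimental optimum of 14. A dual-SD rescue
rule covers RBSs where two tied-length SD motifs act in concert: when the
canonical SD alone would pin initiation on the 3' codon (D5 <= 11 with the
3' codon well placed), but a second tied motif positions the 5' codon at
D5 >= 13, both motifs together confer ambiguity. This is the arrangement
shown mutationally for *tamA*, whose two SD motifs were each necessary and
only jointly sufficient for dual initiation. The rescue is deliberately
asymmetric: a canonical SD that already places the annotated codon in the
optimal window dominates recruitment, and a secondary short-spaced motif
does not re-open the 3' codon (e.g. *asnB*, AUG-exclusive despite a second
motif at D 10/12).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .overlaps import StartOverlap
from .sd import SpacingResult, OPTIMAL_D_TO_START


class AmbiguityLabel(str, Enum):
    exclusive_annotated = "exclusive_annotated"
    exclusive_competitor = "exclusive_competitor"
    ambiguous = "ambiguous"
    no_sd = "no_sd"
    indeterminate = "indeterminate"


class FavoredCodon(str, Enum):
    five_prime = "5prime"
    three_prime = "3prime"
    balanced = "balanced"
    not_applicable = "n/a"


@dataclass(frozen=True)
class AmbiguityWindows:
    """Positional breakpoints (on D5) of the classification, per pentamer.

    All integers are D_toStart values of the pentamer's 5' codon in
    nucleotides. The windows must tile the axis: exclusive-3' up to
    ``*_exclusive_3prime_max``, then the ambiguous range, then the
    exclusive-5' (AUGUG) range; every integer D5 maps to exactly one label.
    """

    aug_exclusive_3prime_max: int = 11
    aug_ambiguous_min: int = 12
    aug_ambiguous_max: int = 12
    aug_exclusive_5prime_max: int = 16
    gug_exclusive_3prime_max: int = 11
    gug_ambiguous_min: int = 12
    gug_ambiguous_max: int = 16
    #: 3' codon must itself sit in a workable range for the dual-SD rescue.
    dual_sd_3prime_range: tuple[int, int] = (10, 16)
    #: minimum D5 at which a secondary tied SD can rescue the 5' codon.
    dual_sd_5prime_min: int = 13

    def __post_init__(self) -> None:
        if not (
            self.aug_exclusive_3prime_max + 1
            == self.aug_ambiguous_min
            <= self.aug_ambiguous_max
            < self.aug_exclusive_5prime_max + 1
        ):
            raise ValueError("AUGUG windows must be disjoint and ordered")
        if not (
            self.gug_exclusive_3prime_max + 1 == self.gug_ambiguous_min <= self.gug_ambiguous_max
        ):
            raise ValueError("GUGUG windows must be disjoint and ordered")


DEFAULT_WINDOWS = AmbiguityWindows()


@dataclass(frozen=True)
class AmbiguityCall:
    """Predicted initiation outcome at one overlap site."""

    gene_id: str
    label: AmbiguityLabel
    favored_codon: FavoredCodon
    dual_sd: bool
    tere_dependent: bool
    rationale: str
    d5: int | None = None
    low_confidence: bool = False


def _window_label(pentamer: str, d5: int, w: AmbiguityWindows) -> tuple[str, FavoredCodon, bool]:
    """(base outcome, favored codon, low-confidence flag) for a D5 value.

    Base outcome is one of 'excl3', 'excl5', 'ambiguous', 'indeterminate'.
    """
    if pentamer == "ATGTG":
        if d5 <= w.aug_exclusive_3prime_max:
            return "excl3", FavoredCodon.three_prime, False
        if w.aug_ambiguous_min <= d5 <= w.aug_ambiguous_max:
            return "ambiguous", FavoredCodon.five_prime, False
        if d5 <= w.aug_exclusive_5prime_max:
            return "excl5", FavoredCodon.five_prime, False
        # Beyond the calibrated range the 5' preference is extrapolated.
        return "excl5", FavoredCodon.five_prime, True
    if d5 <= w.gug_exclusive_3prime_max:
        return "excl3", FavoredCodon.three_prime, False
    if w.gug_ambiguous_min <= d5 <= w.gug_ambiguous_max:
        favored = (
            FavoredCodon.three_prime if d5 == w.gug_ambiguous_min else FavoredCodon.five_prime
        )
        return "ambiguous", favored, False
    return "indeterminate", FavoredCodon.not_applicable, False


def classify_ambiguity(
    overlap: StartOverlap,
    profile: Sequence[SpacingResult],
    windows: AmbiguityWindows = DEFAULT_WINDOWS,
) -> AmbiguityCall:
    """Classify one overlap site from its spacing profile.

    ``profile`` is the cross product of the gene's reported SD matches and
    the two candidate codons (offsets 0 and ``overlap.competitor_offset``),
    as produced by :func:`ambistart.sd.spacing_profile`. An empty profile
    yields ``no_sd``; a profile in which every SD overlaps the 5' codon
    yields ``indeterminate``.
    """
    gene_id = overlap.gene_id
    if not profile:
        return AmbiguityCall(
            gene_id=gene_id,
            label=AmbiguityLabel.no_sd,
            favored_codon=FavoredCodon.not_applicable,
            dual_sd=False,
            tere_dependent=False,
            rationale="no SD motif (>=4 nt) within the upstream window",
        )
    five_offset = overlap.pentamer_start  # 0 when annotated codon is 5', else -2
    three_offset = five_offset + 2
    by_sd: dict[tuple, dict[int, SpacingResult]] = {}
    for r in profile:
        key = (r.sd.mrna_start, r.sd.asd_start, r.sd.asd_end)
        by_sd.setdefault(key, {})[r.codon_offset] = r
    # Exclude SDs that overlap the pentamer's 5' codon; their register does
    # not position either codon meaningfully.
    usable = {
        key: offs
        for key, offs in by_sd.items()
        if five_offset in offs and not offs[five_offset].sd_overlaps_codon
    }
    if not usable:
        return AmbiguityCall(
            gene_id=gene_id,
            label=AmbiguityLabel.indeterminate,
            favored_codon=FavoredCodon.not_applicable,
            dual_sd=False,
            tere_dependent=False,
            rationale="all SD matches overlap the start-codon overlap",
        )

    def ann_result(offs: dict[int, SpacingResult]) -> SpacingResult:
        return offs[0]

    canonical_key = min(
        usable,
        key=lambda key: (
            abs(ann_result(usable[key]).d_to_start - OPTIMAL_D_TO_START),
            -usable[key][0].sd.length,
            -usable[key][0].sd.mrna_end,
        ),
    )
    canonical = usable[canonical_key]
    d5 = canonical[five_offset].d_to_start
    pent = overlap.overlap_class.pentamer
    base, favored, low_conf = _window_label(pent, d5, windows)

    dual = False
    rationale = f"canonical SD {canonical[0].sd.motif} places 5' codon at D_toStart {d5}"
    if base == "excl3" and len(usable) >= 2:
        lo, hi = windows.dual_sd_3prime_range
        d3 = d5 + 2
        if lo <= d3 <= hi:
            for key, offs in usable.items():
                if key == canonical_key:
                    continue
                other_d5 = offs[five_offset].d_to_start
                if other_d5 >= windows.dual_sd_5prime_min:
                    dual = True
                    rationale = (
                        f"dual SD: {canonical[0].sd.motif} sets the 3' codon "
                        f"(D_toStart {d3}), {offs[0].sd.motif} rescues the 5' codon "
                        f"(D_toStart {other_d5})"
                    )
                    break

    annotated_is_5p = overlap.pentamer_start == 0
    if dual:
        label = AmbiguityLabel.ambiguous
        favored = FavoredCodon.balanced
        low_conf = False
    elif base == "ambiguous":
        label = AmbiguityLabel.ambiguous
        rationale += f" ({pent} ambiguous window)"
    elif base == "excl3":
        label = (
            AmbiguityLabel.exclusive_competitor
            if annotated_is_5p
            else AmbiguityLabel.exclusive_annotated
        )
        rationale += " (short spacing pins initiation on the 3' codon)"
    elif base == "excl5":
        label = (
            AmbiguityLabel.exclusive_annotated
            if annotated_is_5p
            else AmbiguityLabel.exclusive_competitor
        )
        rationale += " (5'-exclusive window)"
        if low_conf:
            rationale += "; beyond the calibrated range, extrapolated"
    else:
        label = AmbiguityLabel.indeterminate
        favored = FavoredCodon.not_applicable
        rationale += " (outside the calibrated GUGUG range)"

    call = AmbiguityCall(
        gene_id=gene_id,
        label=label,
        favored_codon=favored,
        dual_sd=dual,
        tere_dependent=False,
        rationale=rationale,
        d5=d5,
        low_confidence=low_conf,
    )
    if flag_tere_dependence(overlap, call):
        call = replace(call, tere_dependent=True)
    return call


def flag_tere_dependence(overlap: StartOverlap, call: AmbiguityCall) -> bool:
    """True when translation of the annotated ORF plausibly rides on TeRe.

    The pattern of *narQ*: the annotated codon is the 3' one, the site is
    ambiguous with the 5' codon favored (or balanced), and the pentamer is
    followed by A — so erroneous initiation at the 5' codon terminates
    immediately at the out-of-frame N-UGA stop and can reinitiate at the
    annotated codon (termination-reinitiation).
    """
    return (
        not overlap.overlap_class.annotated_is_5prime
        and call.label is AmbiguityLabel.ambiguous
        and call.favored_codon in (FavoredCodon.five_prime, FavoredCodon.balanced)
        and overlap.has_start_stop
    )


def predict_frame_usage(
    overlap: StartOverlap,
    call: AmbiguityCall,
    windows: AmbiguityWindows = DEFAULT_WINDOWS,
) -> tuple[str, str]:
    """Qualitative usage of the (5' codon, 3' codon) frames.

    Ordinal labels only ({none, residual, minor, major, unknown}): the
    underlying fold-changes are measured quantities, not modeled ones.
    """
    if call.label in (AmbiguityLabel.no_sd, AmbiguityLabel.indeterminate) or call.d5 is None:
        return ("unknown", "unknown")
    if call.dual_sd:
        return ("minor", "major")
    d5 = call.d5
    if overlap.overlap_class.pentamer == "ATGTG":
        if d5 <= windows.aug_exclusive_3prime_max:
            return ("none", "major")
        if d5 <= windows.aug_ambiguous_max:
            return ("major", "minor")
        return ("major", "residual")
    if d5 <= windows.gug_exclusive_3prime_max:
        return ("none", "major")
    if d5 == windows.gug_ambiguous_min:
        return ("minor", "major")
    return ("major", "minor")


def toeprint_offsets(codon_offset: int) -> tuple[int, int]:
    """Expected reverse-transcriptase stop positions for an initiation complex.

    A ribosome positioned on a start codon produces toeprint bands at +16
    and +17 relative to that codon; for a codon at ``codon_offset`` relative
    to the annotated start, the bands fall at ``codon_offset + 16`` and
    ``codon_offset + 17`` in annotated-start coordinates.
    """
    return (codon_offset + 16, codon_offset + 17)
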