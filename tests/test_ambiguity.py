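import pytest

from ambistart.ambiguity import (
    AmbiguityLabel,
    AmbiguityWindows,
    FavoredCodon,
    classify_ambiguity,
    flag_tere_dependence,
    predict_frame_usage,
    toeprint_offsets,
)
from ambistart.overlaps import OverlapClass, StartOverlap
from ambistart.sd import SDMatch, compute_d_to_start


def _overlap(cls: OverlapClass, post: str = "C") -> StartOverlap:
    return StartOverlap(
        gene_id="g",
        overlap_class=cls,
        pentamer_start=cls.pentamer_start,
        competitor_offset=2 if cls.pentamer_start == 0 else -2,
        a4_base="T" if cls.pentamer_start == 0 else post,
        post_pentamer_base=post,
        has_start_stop=post == "A",
    )


def _profile(cls: OverlapClass, sd_specs):
    """Build a spacing profile from (motif, asd_start, asd_end, d_annotated) tuples."""
    comp = 2 if cls.pentamer_start == 0 else -2
    profile = []
    for motif, i, e, d_ann in sd_specs:
        k = e - i + 1
        spacer = d_ann - (9 - e) - k
        match = SDMatch(motif=motif, mrna_start=-(spacer + k), mrna_end=-spacer,
                        asd_start=i, asd_end=e)
        for off in (0, comp):
            profile.append(compute_d_to_start(match, off))
    return profile


@pytest.mark.parametrize(
    "cls, sds, label, favored",
    [
        # ATGtg, single SD at D(AUG)=12: the appC-style ambiguous window
        (OverlapClass.ATGtg, [("AGGAG", 3, 7, 12)], AmbiguityLabel.ambiguous, FavoredCodon.five_prime),
        # ATGtg at D=13: hypB-style exclusive annotated
        (OverlapClass.ATGtg, [("AGGAG", 3, 7, 13)], AmbiguityLabel.exclusive_annotated, FavoredCodon.five_prime),
        # ATGtg at D=10: short spacing pins the 3' GUG (competitor)
        (OverlapClass.ATGtg, [("UAAGGAGG", 2, 9, 10)], AmbiguityLabel.exclusive_competitor, FavoredCodon.three_prime),
        # gtGTG at D(3' GUG)=13 (D5=11): nagZ-style exclusive annotated
        (OverlapClass.gtGTG, [("UAAGGAG", 3, 9, 13)], AmbiguityLabel.exclusive_annotated, FavoredCodon.three_prime),
        # gtGTG at D=16 (D5=14): narQ-style ambiguous, 5' favored
        (OverlapClass.gtGTG, [("GGAG", 3, 6, 16)], AmbiguityLabel.ambiguous, FavoredCodon.five_prime),
        # atGTG at D=13 (D5=11): hdhA-style exclusive annotated
        (OverlapClass.atGTG, [("AGGAGGU", 1, 7, 13)], AmbiguityLabel.exclusive_annotated, FavoredCodon.three_prime),
        # ATGtg at D=21: yobF-style, extrapolated exclusive annotated
        (OverlapClass.ATGtg, [("GAGGU", 1, 5, 21)], AmbiguityLabel.exclusive_annotated, FavoredCodon.five_prime),
    ],
)
def test_window_classification(cls, sds, label, favored):
    call = classify_ambiguity(_overlap(cls), _profile(cls, sds))
    assert call.label is label
    assert call.favored_codon is favored


def test_extrapolated_call_is_flagged_low_confidence():
    call = classify_ambiguity(
        _overlap(OverlapClass.ATGtg), _profile(OverlapClass.ATGtg, [("GAGGU", 1, 5, 21)])
    )
    assert call.low_confidence


def test_dual_sd_rescue_fires_for_tama_arrangement():
    # tied 5-mers: proximal sets the 3' GUG at D 12, distal rescues the 5' AUG at D 19
    sds = [("AAGGA", 4, 8, 21), ("AGGAG", 3, 7, 12)]
    call = classify_ambiguity(_overlap(OverlapClass.atGTG), _profile(OverlapClass.atGTG, sds))
    assert call.label is AmbiguityLabel.ambiguous
    assert call.dual_sd and call.favored_codon is FavoredCodon.balanced


def test_dual_sd_rescue_is_asymmetric():
    # asnB arrangement: canonical SD already 5'-exclusive; a secondary
    # short-spaced motif must NOT re-open the 3' codon
    sds = [("GGAG", 3, 6, 13), ("AGGU", 1, 4, 10)]
    call = classify_ambiguity(_overlap(OverlapClass.ATGtg), _profile(OverlapClass.ATGtg, sds))
    assert call.label is AmbiguityLabel.exclusive_annotated
    assert not call.dual_sd


def test_no_sd_and_overlapping_sd_edge_cases():
    call = classify_ambiguity(_overlap(OverlapClass.ATGtg), [])
    assert call.label is AmbiguityLabel.no_sd
    # SD overlapping the 5' codon of a 3'-annotated gene -> indeterminate
    match = SDMatch(motif="UAAG", mrna_start=-4, mrna_end=0, asd_start=6, asd_end=9)
    profile = [compute_d_to_start(match, off) for off in (0, -2)]
    call = classify_ambiguity(_overlap(OverlapClass.gtGTG), profile)
    assert call.label is AmbiguityLabel.indeterminate


def test_every_d5_maps_to_exactly_one_label():
    """Window totality: fuzz D5 over [0, 40] for both pentamers."""
    from ambistart.ambiguity import DEFAULT_WINDOWS, _window_label

    for pent in ("ATGTG", "GTGTG"):
        for d5 in range(0, 41):
            base, favored, _ = _window_label(pent, d5, DEFAULT_WINDOWS)
            assert base in {"excl3", "excl5", "ambiguous", "indeterminate"}
    # realizable spacing profiles agree with the window map
    for cls in (OverlapClass.ATGtg, OverlapClass.gtGTG):
        for d5 in range(4, 41):
            d_ann = d5 if cls.pentamer_start == 0 else d5 + 2
            call = classify_ambiguity(
                _overlap(cls), _profile(cls, [("UAAG", 6, 9, d_ann)])
            )
            assert call.label in AmbiguityLabel
            assert call.d5 == d5


def test_favored_codon_shift_is_monotone_in_d5():
    """The preference never moves from the 5' codon back to the 3' one."""
    order = {FavoredCodon.three_prime: 0, FavoredCodon.balanced: 1, FavoredCodon.five_prime: 2}
    for cls in (OverlapClass.ATGtg, OverlapClass.gtGTG):
        seen = []
        for d5 in range(9, 17):
            d_ann = d5 if cls.pentamer_start == 0 else d5 + 2
            call = classify_ambiguity(
                _overlap(cls), _profile(cls, [("UAAGGAGGU", 1, 9, d_ann)])
            )
            if call.favored_codon in order:
                seen.append(order[call.favored_codon])
        assert seen == sorted(seen)


@pytest.mark.parametrize(
    "cls, d5, expected",
    [
        (OverlapClass.ATGtg, 11, ("none", "major")),
        (OverlapClass.ATGtg, 12, ("major", "minor")),
        (OverlapClass.ATGtg, 14, ("major", "residual")),
        (OverlapClass.gtGTG, 12, ("minor", "major")),
        (OverlapClass.gtGTG, 14, ("major", "minor")),
    ],
)
def test_frame_usage_is_ordinal_only(cls, d5, expected):
    d_ann = d5 if cls.pentamer_start == 0 else d5 + 2
    overlap = _overlap(cls)
    call = classify_ambiguity(overlap, _profile(cls, [("UAAGGAGGU", 1, 9, d_ann)]))
    assert predict_frame_usage(overlap, call) == expected


def test_frame_usage_unknown_without_sd():
    overlap = _overlap(OverlapClass.ATGtg)
    call = classify_ambiguity(overlap, [])
    assert predict_frame_usage(overlap, call) == ("unknown", "unknown")


def test_tere_dependence_is_the_narq_conjunction():
    # gtGTG, D5=14, post-pentamer A: ambiguous with 5' favored and start-stop
    narq = classify_ambiguity(
        _overlap(OverlapClass.gtGTG, post="A"),
        _profile(OverlapClass.gtGTG, [("GGAG", 3, 6, 16)]),
    )
    assert narq.tere_dependent
    # same geometry without the A4 start-stop: no TeRe dependence
    no_a = classify_ambiguity(
        _overlap(OverlapClass.gtGTG, post="G"),
        _profile(OverlapClass.gtGTG, [("GGAG", 3, 6, 16)]),
    )
    assert not no_a.tere_dependent
    # exclusive site with A4: rule is a conjunction, not a single flag
    excl = classify_ambiguity(
        _overlap(OverlapClass.gtGTG, post="A"),
        _profile(OverlapClass.gtGTG, [("UAAGGAG", 3, 9, 13)]),
    )
    assert not excl.tere_dependent and flag_tere_dependence(_overlap(OverlapClass.gtGTG, post="A"), excl) is False


def test_toeprint_bands_translate_with_the_codon():
    assert toeprint_offsets(0) == (16, 17)
    assert toeprint_offsets(2) == (18, 19)
    assert toeprint_offsets(-2) == (14, 15)


def test_windows_validate_ordering():
    with pytest.raises(ValueError):
        AmbiguityWindows(aug_exclusive_3prime_max=13, aug_ambiguous_min=12)
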