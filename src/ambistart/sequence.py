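"""Strict DNA/RNA string utilities.

All genomic I/O in this package is DNA (``T``); Shine-Dalgarno motifs and
initiation contexts are rendered as RNA (``U``) in reports, mirroring the
dual ``ATGTG``/``AUGUG`` usage in the field. The two alphabets are related
by the bijection ``T <-> U``, so conversion is lossless.

Alphabets are enforced strictly: ambiguous IUPAC codes are rejected with an
error naming the offending character and position, rather than silently
propagated into spacing arithmetic.
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_COMP = str.maketrans("ACGU", "UGCA")
_T_TO_U = str.maketrans("T", "U")
_U_TO_T = str.maketrans("U", "T")


class AlphabetError(ValueError):
    """A sequence contains characters outside the strict DNA/RNA alphabet."""


def _validate(seq: str, alphabet: frozenset, kind: str) -> str:
    s = seq.upper()
    for pos, ch in enumerate(s):
        if ch not in alphabet:
            raise AlphabetError(
                f"invalid {kind} character {ch!r} at position {pos} "
                f"(strict alphabet {''.join(sorted(alphabet))}; ambiguity codes are rejected)"
            )
    return s


def validate_dna(seq: str) -> str:
    """Uppercase and validate a DNA string; raise :class:`AlphabetError` otherwise."""
    return _validate(seq, DNA_ALPHABET, "DNA")


def validate_rna(seq: str) -> str:
    """Uppercase and validate an RNA string; raise :class:`AlphabetError` otherwise."""
    return _validate(seq, RNA_ALPHABET, "RNA")


def to_rna(seq: str) -> str:
    """Render a DNA or RNA string as RNA (T -> U)."""
    s = seq.upper()
    if "T" in s and "U" in s:
        raise AlphabetError("sequence mixes T and U; cannot infer alphabet")
    return validate_rna(s.translate(_T_TO_U))


def to_dna(seq: str) -> str:
    """Render a DNA or RNA string as DNA (U -> T)."""
    s = seq.upper()
    if "T" in s and "U" in s:
        raise AlphabetError("sequence mixes T and U; cannot infer alphabet")
    return validate_dna(s.translate(_U_TO_T))


def complement_dna(seq: str) -> str:
    return validate_dna(seq).translate(_DNA_COMP)


def complement_rna(seq: str) -> str:
    return validate_rna(seq).translate(_RNA_COMP)


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (an involution)."""
    return complement_dna(seq)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (an involution)."""
    return complement_rna(seq)[::-1]
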