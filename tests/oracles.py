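"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning code paths: complementary
stretches are found by exhaustive substring enumeration and maximality is
decided by containment between occurrences, not by the extension test the
implementation uses.
"""

from __future__ import annotations

_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_PAIR[c] for c in reversed(s))


def brute_force_sd(upstream_rna: str, asd: str = "ACCUCCUUA", min_len: int = 4):
    """All maximal complementary stretches as sorted (p, k, i, e) tuples.

    p is the 0-based window offset, k the length, [i, e] the 1-based aSD
    positions paired (antiparallel). Enumerates every window substring
    against every aSD substring, then discards occurrences contained in a
    longer occurrence with the same pairing register.
    """
    u = upstream_rna.upper().replace("T", "U")
    L = len(u)
    occ = []
    for p in range(L):
        for k in range(2, min(L - p, len(asd)) + 1):
            sub = u[p : p + k]
            for i in range(1, len(asd) + 1):
                e = i + k - 1
                if e <= len(asd) and _revcomp(asd[i - 1 : e]) == sub:
                    occ.append((p, k, i, e))

    def contained(a, b):
        p1, k1, i1, e1 = a
        p2, k2, i2, e2 = b
        if a == b or p2 > p1 or p2 + k2 < p1 + k1:
            return False
        # antiparallel: u[p] pairs aSD position e; register must align
        return e2 - (p1 - p2) == e1 and i2 + ((p2 + k2) - (p1 + k1)) == i1

    maximal = [a for a in occ if not any(contained(a, b) for b in occ)]
    return sorted(t for t in maximal if t[1] >= min_len)


def anchored_pentamer_scan(context: str, annotated_codon: str):
    """Regex-free exhaustive pentamer placements for a start context.

    ``context`` covers positions -2..+5 with the annotated codon at index
    2. Returns the set of (pentamer, pentamer_start) pairs in which the
    annotated codon is one of the pentamer's two start codons.
    """
    ctx = context.upper().replace("U", "T")
    codon = annotated_codon.upper().replace("U", "T")
    hits = set()
    for pent in ("ATGTG", "GTGTG"):
        for rel in (-2, 0):
            idx = 2 + rel
            if ctx[idx : idx + 5] != pent:
                continue
            # annotated codon must be the 5' (rel 0) or 3' (rel -2) codon
            inner = pent[0:3] if rel == 0 else pent[2:5]
            if inner == codon:
                hits.add((pent, rel))
    return hits
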