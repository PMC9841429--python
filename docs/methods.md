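# Methods

## Scope and model

`ambistart` treats bacterial translation-initiation sites whose annotated
start codon lies inside an AUGUG or GUGUG pentamer — two canonical start
codons 2 nt apart in different frames — and asks which codon(s) an
initiating 30S complex will select. The decision model is purely
positional: it scores how the Shine-Dalgarno (SD) interaction places each
codon relative to the ribosomal P site, and contains no thermodynamic
(ΔG) duplex scoring, no mRNA secondary-structure term and no kinetic model
of 30S binding. Those are deliberate exclusions, not omissions: the
classification windows below were calibrated on reporter measurements in
which position was the manipulated variable, and the package predicts only
what that calibration supports — ordinal outcomes, never expression levels
or fold-changes.

## Sequence conventions

All genomic I/O is DNA; motifs and contexts are reported as RNA (T↔U is a
lossless bijection). Alphabets are strict — IUPAC ambiguity codes are
rejected at parse time rather than silently matched. Internal coordinates
are 0-based half-open on the forward strand; GenBank's 1-based inclusive
intervals are converted only at the I/O boundary. Relative to a gene,
position 0 is the first nucleotide of the annotated start codon and
upstream positions are negative, which makes spacer arithmetic and the
"fourth CDS position" (A4 = position +3) conventions direct. Circular
replicons wrap upstream windows across the origin; linear replicons
truncate them (never pad). CDS features with fuzzy locations are skipped
with a logged reason, since their start codon is undefined; joined
locations use the first codon of the spliced mRNA, validated against the
extracted sequence.

## SD detection

An SD motif is any maximal stretch of ≥ 4 nt within the 30-nt window
upstream of the CDS that is Watson-Crick complementary to a contiguous
substring of the anti-SD, the 3′-terminal 9 nt of the 16S rRNA
(`ACCUCCUUA`, p1..p9 with p9 the 3′ terminus). Choices that matter:

- **No G:U wobble.** Every motif in the reference survey is a strict WC
  complement of an aSD substring; admitting wobble would extend several of
  them and shift their registers. A shipped self-test verifies the strict
  rule against all 17 reported motifs.
- **Maximality.** A match that can be extended by one nucleotide on either
  side (mRNA side and aSD side moving together, antiparallel) is not
  reported; the longer register is. The test suite checks this against an
  independent brute-force enumeration with containment-based maximality.
- **Longest-only with ties.** By default only matches of the maximum
  length found are reported, and *all* ties are kept (e.g. two tied 4-mers
  from a single GAGGA stretch). An option exposes every ≥ 4-nt match.
- **Registers.** All length-≥ 4 substrings of the default aSD are distinct,
  so each motif has exactly one pairing register; this is asserted. For a
  custom aSD where the assertion fails, every register is reported.

The aSD letters, window length, minimum duplex length and longest-only
behavior are configuration keys (`asd_sequence`, `upstream_window`,
`min_sd_len`, `longest_only`).

## Aligned spacing

For a motif pairing aSD p_i..p_e (length k = e − i + 1) and a codon
*spacer* nt downstream of the motif's 3′ end,

    D_toStart = (9 − e) + k + spacer.

(9 − e) is the overhang of the 16S 3′ end past the duplex. D_toStart is
measured to the codon's first nucleotide; the pentamer's two codons always
differ by exactly 2. Negative spacers (motif overlapping the codon) are
computed and flagged but excluded from classification. When several
maximal motifs tie, a gene's **canonical SD** is the one whose
annotated-codon D_toStart is closest to 14 (the experimental optimum),
ties broken toward the longer motif, then the more 3′ match. The reference
survey does not state its per-gene choice where motifs tie; this rule is
our documented choice, kept configurable in effect by reporting every tied
motif alongside the canonical call. In survey-style reports, tied motifs
are rendered in descending aSD-pairing position (the motif pairing closest
to the 16S 3′ terminus first), which matches the printed ordering of every
two-motif row we checked.

## Classification windows

Classification keys on D5, the D_toStart of the pentamer's **5′ codon**
(D5 = D_annotated for 5′-annotated genes, D_annotated − 2 otherwise),
using the canonical SD:

- **AUGUG:** D5 ≤ 11 → exclusive 3′ GUG; D5 = 12 → ambiguous, AUG favored;
  13 ≤ D5 ≤ 16 → exclusive 5′ AUG; D5 ≥ 17 → exclusive 5′ with a
  low-confidence flag (beyond the calibrated range; the survey's own D=21
  entry is predicted non-ambiguous, which this reproduces while marking
  the extrapolation).
- **GUGUG:** D5 ≤ 11 → exclusive 3′ GUG; D5 = 12 → ambiguous, 3′ favored;
  13 ≤ D5 ≤ 16 → ambiguous, 5′ favored; D5 ≥ 17 → indeterminate.

The windows tile the integer axis (asserted by construction and fuzzed in
tests) and ship as editable configuration, since they are a reading of
reporter outcomes, not first principles.

**Dual-SD rescue.** Some RBSs carry two tied-length motifs that act in
concert, one recruiting for each codon — shown mutationally for *tamA*,
where either motif alone gave exclusive initiation and only both together
gave dual initiation. The rule: if the canonical SD alone yields an
exclusive-3′ call (D5 ≤ 11) with the 3′ codon in a workable range
(D ∈ [10, 16]), and another tied-length motif places the 5′ codon at
D5 ≥ 13, the site is called ambiguous with `dual_sd` set. The rescue is
deliberately **asymmetric**: when the canonical SD already places the
annotated codon in the optimal window it dominates recruitment, and a
secondary short-spaced motif does not re-open the 3′ codon. The asymmetry
is forced by the data — a symmetric rule would call the *asnB*-type
arrangement (canonical GGAG at D 13/15 plus a second 4-mer at D 10/12)
ambiguous, while both the survey's verdict and the reporter measurement
for it are AUG-exclusive. Scope note: the rule requires tied maximal
lengths; unequal lengths defer entirely to the canonical SD's window.

**Start-stop and TeRe.** An adenine immediately after the pentamer
(position pentamer+5) creates an out-of-frame N-UGA stop, so erroneous
initiation at the 5′ codon terminates after one codon and can reinitiate
locally (termination-reinitiation). A site is flagged `tere_dependent`
when the annotated codon is the 3′ one, the call is ambiguous with the 5′
codon favored or balanced, and the post-pentamer base is A — the exact
conjunction under which the annotated ORF's translation plausibly rides on
the correction mechanism. A4 is recorded twice: as the annotated gene's
fourth base (the genome-wide enrichment statistic) and as the
post-pentamer base (the start-stop trigger); for 3′-placed codons the two
coincide, for 5′-placed AUGUG genes the fourth base is forced to U by the
pentamer itself.

**Frame usage** is emitted as ordinal labels only ({none, residual,
minor, major, unknown} per codon). The underlying preferences were
measured (≈3.5-fold, ≈10-fold, …), not modeled, so emitting numbers would
imply precision the model does not have.

**Toeprint utility.** An initiation complex on a codon at offset *c*
(relative to the annotated start) produces reverse-transcriptase stops at
c + 16 and c + 17 — a two-line arithmetic helper for reading toeprint
gels at overlaps, where the two codons' band pairs differ by 2.

## Synthetic data

The generator plants RBSs of the form
`[pad][SD motif][spacer][pentamer][post base][CDS body]` into a replicon
with decoy genes and emits a truth manifest (expected class, motifs,
D values, label — the D values derived from the formula at generation
time, independently of the scanner). Free bases are rejection-sampled
(capped, erroring out on structurally impossible arrangements) so that the
planted motif set is exactly what a scan should report, no unintended
pentamer spans the start, and CDS bodies contain no in-frame stop.
Reverse-strand plants are reverse-complemented into the replicon; circular
replicons can be rotated so a chosen gene's window spans the origin.
Output is deterministic per seed, byte-identical at the GenBank level.

Defaults mirror the reporter construct used for window calibration: the
strong 8-nt SD `UAAGGAGG` with a 4-nt spacer (D 12/14, the center of the
ambiguous window); background composition is uniform, with an optional
A-rich setting to mimic A-rich 5′ UTRs. What the generator does *not*
emulate — and what passing tests therefore do not show about real data —
includes mRNA secondary structure, expression levels, ribosome-profiling
or toeprint signal, non-canonical start codons, and the gene-density and
compositional biases of real genomes (synthetic upstream windows are inert
by construction, whereas real 5′ UTRs may overlap neighboring CDSs; real
windows are taken from raw genomic sequence regardless of neighbors).

The bundled survey reconstruction (`table_fixture`) rebuilds one gene per
printed row of the reference survey — 53 genes, planting each printed
motif at the spacer its printed D_toStart implies — and is the basis for
the genome-scale concordance checks. It reconstructs the survey's
*output*; scanning a live RefSeq annotation remains the intended use for
real analyses, and counts there may shift slightly between annotation
releases. Post-pentamer bases are not printed in the survey and are
synthetic choices (A for *narQ*, whose site is GUGUGA; C elsewhere, with
*tamA*'s fixed by its printed alternative-frame peptide).

## Numerical and edge-case choices

- Overlap detection is anchored at annotated starts; a context matching
  both a 5′ and a 3′ placement (AUGUGUG-like) yields one record per
  placement, flagged by class. An exploratory all-pentamer scan exists but
  feeds no reference output.
- GTGtg (annotated 5′ GTG of GTGTG) is representable though absent from
  the reference survey; its absence on real data is a checkable result.
- Genes whose start context is truncated by a linear replicon edge are
  skipped with a logged reason and counted in the skip report.
- *marR* in the reference survey prints a verdict without an SD motif;
  the classifier reports `no_sd` for SD-less genes uniformly and the
  discrepancy is documented rather than imitated.
- Report output ordering is fully specified (abundance rank when a table
  is supplied, coordinate otherwise), making runs byte-stable.
- Problem sizes: the test suite runs on windows ≤ 30 nt, replicons of a
  few kb with up to ~210 planted genes, and 1000-window oracle sweeps —
  sizes chosen so the whole suite completes in seconds while every code
  path (strands, origin wrap, ties, rescues) is exercised.

## Known limitations

Positional classification cannot see structure, standby sites or factor
concentrations; sites beyond D5 = 16 are extrapolations; the dual-SD rule
is scoped to tied-length pairs because that is the only arrangement with
mutational evidence; and predictions are per-site priors, not measurements
— ambiguous calls identify candidates for reporter or profiling follow-up,
not confirmed dual-ORF loci.
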