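"""Report writers: survey-style tables, BED tracks, spacing distributions.

``run_scan`` orchestrates the analysis end to end — parse the genome, find
the start-codon overlaps, profile their SD spacing, classify ambiguity —
and renders one report row per overlap in the reference survey's format:
tied SD motifs comma-joined in RNA ("motif1, motif2") with their D_toStart
values joined in matching order, a missing SD rendered as an em-dash, and
rows ranked by protein abundance when an abundance table is supplied (by
coordinate otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ambiguity import AmbiguityCall, AmbiguityLabel, classify_ambiguity, predict_frame_usage
from .config import ScanConfig
from .genome import GenomeAnnotationSet, parse_genbank
from .overlaps import StartOverlap, find_start_overlaps, pentamer_interval
from .sd import compute_d_to_start, find_sd_matches, genome_spacing_distribution
from .sequence import to_rna

log = logging.getLogger(__name__)

EM_DASH = "—"

REPORT_COLUMNS = [
    "gene",
    "locus_tag",
    "overlap_class",
    "sd_motifs",
    "d_to_start_annotated",
    "d_to_start_competitor",
    "predicted_ambiguity",
    "label",
    "favored_codon",
    "dual_sd",
    "a4_base",
    "has_start_stop",
    "tere_dependent",
    "frame_usage_5prime",
    "frame_usage_3prime",
    "abundance_ppm",
]


@dataclass(frozen=True)
class ReportRow:
    gene: str
    locus_tag: str
    overlap_class: str
    sd_motifs: str
    d_to_start_annotated: str
    d_to_start_competitor: str
    predicted_ambiguity: str
    label: str
    favored_codon: str
    dual_sd: bool
    a4_base: str
    has_start_stop: bool
    tere_dependent: bool
    frame_usage_5prime: str
    frame_usage_3prime: str
    abundance_ppm: str = ""


def _verdict(label: AmbiguityLabel) -> str:
    if label is AmbiguityLabel.ambiguous:
        return "yes"
    if label in (AmbiguityLabel.exclusive_annotated, AmbiguityLabel.exclusive_competitor):
        return "no"
    if label is AmbiguityLabel.no_sd:
        return EM_DASH
    return "indeterminate"


def build_report(
    genome: GenomeAnnotationSet, config: ScanConfig | None = None
) -> tuple[list[ReportRow], list[StartOverlap], list[AmbiguityCall]]:
    """One survey-style row per detected overlap, sorted by coordinate."""
    config = config or ScanConfig()
    asd = config.asd
    genes = {g.gene_id: g for g in genome.genes}
    rows: list[ReportRow] = []
    overlaps = find_start_overlaps(genome, include_pseudo=config.include_pseudo)
    calls: list[AmbiguityCall] = []
    for ov in overlaps:
        gene = genes[ov.gene_id]
        matches = find_sd_matches(
            gene.upstream_seq[-config.upstream_window :],
            asd=asd,
            min_len=config.min_sd_len,
            longest_only=config.longest_only,
        )
        # survey rendering order: motifs pairing closest to the 16S 3' end first
        matches = sorted(matches, key=lambda m: (-m.asd_end, m.mrna_start))
        profile = [
            compute_d_to_start(m, off) for m in matches for off in (0, ov.competitor_offset)
        ]
        call = classify_ambiguity(ov, profile, config.windows)
        calls.append(call)
        usage5, usage3 = predict_frame_usage(ov, call, config.windows)
        d_ann = [compute_d_to_start(m, 0).d_to_start for m in matches]
        d_comp = [compute_d_to_start(m, ov.competitor_offset).d_to_start for m in matches]
        rows.append(
            ReportRow(
                gene=gene.name,
                locus_tag=gene.locus_tag,
                overlap_class=ov.overlap_class.value,
                sd_motifs=", ".join(m.motif for m in matches) or EM_DASH,
                d_to_start_annotated=", ".join(map(str, d_ann)) or EM_DASH,
                d_to_start_competitor=", ".join(map(str, d_comp)) or EM_DASH,
                predicted_ambiguity=_verdict(call.label),
                label=call.label.value,
                favored_codon=call.favored_codon.value,
                dual_sd=call.dual_sd,
                a4_base=to_rna(ov.a4_base),
                has_start_stop=ov.has_start_stop,
                tere_dependent=call.tere_dependent,
                frame_usage_5prime=usage5,
                frame_usage_3prime=usage3,
            )
        )
    return rows, overlaps, calls


def rows_to_frame(rows: list[ReportRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows], columns=REPORT_COLUMNS)


def join_abundance(frame: pd.DataFrame, table_path: str | Path) -> pd.DataFrame:
    """Left-join a gene -> ppm abundance table onto report rows.

    The table must have columns ``gene`` and ``ppm`` (tab- or
    comma-delimited, header required). Unmatched genes get a blank
    abundance; duplicate gene ids in the table are an error naming the id.
    Printed values are echoed verbatim (no rescaling), so the ppm column
    may be strings.
    """
    table = pd.read_csv(table_path, sep=None, engine="python", dtype=str)
    missing = {"gene", "ppm"} - set(table.columns)
    if missing:
        raise ValueError(f"abundance table lacks column(s): {', '.join(sorted(missing))}")
    dup = table["gene"][table["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene id in abundance table: {dup.iloc[0]}")
    merged = frame.drop(columns=["abundance_ppm"]).merge(
        table.rename(columns={"ppm": "abundance_ppm"}), on="gene", how="left"
    )
    unmatched = merged["abundance_ppm"].isna().sum()
    if unmatched:
        log.warning("%d report rows have no abundance entry", unmatched)
    merged["abundance_ppm"] = merged["abundance_ppm"].fillna("")
    return merged[REPORT_COLUMNS]


def _abundance_sort(frame: pd.DataFrame) -> pd.DataFrame:
    key = pd.to_numeric(frame["abundance_ppm"], errors="coerce")
    return (
        frame.assign(_key=key)
        .sort_values(["_key"], ascending=False, na_position="last", kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )


@dataclass
class ScanResult:
    report: pd.DataFrame
    overlaps: list[StartOverlap]
    calls: list[AmbiguityCall]
    distribution: pd.DataFrame
    counts: dict[str, int]
    report_path: Path | None = None
    bed_path: Path | None = None
    distribution_path: Path | None = None
    log_path: Path | None = None


def run_scan(
    genome_path: str | Path,
    out_dir: str | Path,
    config: ScanConfig | None = None,
    abundance_path: str | Path | None = None,
    genome: GenomeAnnotationSet | None = None,
) -> ScanResult:
    """Scan a genome and write the survey report, BED track and distribution.

    ``genome`` may be passed directly (e.g. a synthetic set) to skip
    parsing; otherwise ``genome_path`` is read as GenBank.
    """
    config = config or ScanConfig()
    if genome is None:
        genome = parse_genbank(genome_path, upstream_window=config.upstream_window)
    rows, overlaps, calls = build_report(genome, config)
    frame = rows_to_frame(rows)
    if abundance_path is not None:
        frame = join_abundance(frame, abundance_path)
        frame = _abundance_sort(frame)
    dist = genome_spacing_distribution(genome, asd=config.asd, min_len=config.min_sd_len)
    n_pseudo = sum(1 for g in genome.genes if g.is_pseudo)
    counts = {
        "genes_scanned": len(genome.genes),
        "pseudo_excluded": 0 if config.include_pseudo else n_pseudo,
        "features_skipped": len(genome.skipped),
        "overlaps_found": len(overlaps),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "overlap_report.tsv"
    frame.to_csv(report_path, sep="\t", index=False)
    bed_path = out_dir / "pentamers.bed"
    with open(bed_path, "w") as fh:
        for ov in overlaps:
            s, e = pentamer_interval(ov)
            fh.write(
                f"{ov.replicon_id}\t{s}\t{e}\t{ov.gene_id}|{ov.overlap_class.value}\t0\t{ov.strand}\n"
            )
    distribution_path = out_dir / "spacing_distribution.tsv"
    dist.to_csv(distribution_path, sep="\t", index=False)
    log_path = out_dir / "scan_summary.txt"
    with open(log_path, "w") as fh:
        for key, value in counts.items():
            fh.write(f"{key}\t{value}\n")
        for label, reason in genome.skipped:
            fh.write(f"skipped\t{label}\t{reason}\n")
    log.info("scan complete: %s", counts)
    return ScanResult(
        report=frame,
        overlaps=overlaps,
        calls=calls,
        distribution=dist,
        counts=counts,
        report_path=report_path,
        bed_path=bed_path,
        distribution_path=distribution_path,
        log_path=log_path,
    )
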