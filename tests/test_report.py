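import pandas as pd
import pytest
from click.testing import CliRunner

from ambistart.cli import main
from ambistart.config import ConfigError, ScanConfig, load_config
from ambistart.genome import write_genbank
from ambistart.overlaps import OverlapClass
from ambistart.report import EM_DASH, REPORT_COLUMNS, join_abundance, run_scan, rows_to_frame
from ambistart.synthetic import PlantSpec, generate_synthetic_genome


@pytest.fixture(scope="module")
def three_plant_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("scan")
    specs = [
        PlantSpec("alpha", OverlapClass.ATGtg, "UAAGGAGG", 4),
        PlantSpec("beta", OverlapClass.atGTG, "AGGAGGU", 4),
        PlantSpec("gamma", OverlapClass.gtGTG, "GGAG", 9, post_pentamer_base="A"),
    ]
    synth = generate_synthetic_genome(specs, n_decoys=4, seed=17, out_dir=out)
    result = run_scan(synth.genbank_path, out / "report")
    return synth, result


def test_run_scan_writes_all_artifacts(three_plant_result):
    synth, result = three_plant_result
    assert result.report_path.exists()
    assert result.bed_path.exists()
    assert result.distribution_path.exists()
    assert result.log_path.exists()
    assert list(result.report.columns) == REPORT_COLUMNS
    assert len(result.report) == 3
    assert result.counts["overlaps_found"] == 3
    assert result.counts["genes_scanned"] == 7


def test_report_rows_match_manifest(three_plant_result):
    synth, result = three_plant_result
    truth = {t.gene_id: t for t in synth.manifest}
    for _, row in result.report.iterrows():
        t = truth[row["gene"]]
        assert row["overlap_class"] == t.overlap_class.value
        assert row["label"] == t.label


def test_bed_track_is_forward_strand_half_open(three_plant_result):
    synth, result = three_plant_result
    lines = result.bed_path.read_text().splitlines()
    assert len(lines) == 3
    for line in lines:
        chrom, s, e, name, score, strand = line.split("\t")
        assert int(e) - int(s) == 5
        assert strand in "+-"
        pent = name.split("|")[1]
        assert pent in {c.value for c in OverlapClass}


def test_empty_genome_yields_empty_report(tmp_path):
    synth = generate_synthetic_genome([], n_decoys=0, seed=0, out_dir=tmp_path)
    result = run_scan(synth.genbank_path, tmp_path / "rep")
    assert result.report.empty
    assert result.counts["overlaps_found"] == 0


def test_scan_output_is_byte_stable(tmp_path):
    specs = [PlantSpec("alpha", OverlapClass.ATGtg, "UAAGGAGG", 4)]
    synth = generate_synthetic_genome(specs, n_decoys=3, seed=5, out_dir=tmp_path)
    r1 = run_scan(synth.genbank_path, tmp_path / "r1")
    r2 = run_scan(synth.genbank_path, tmp_path / "r2")
    assert r1.report_path.read_bytes() == r2.report_path.read_bytes()
    assert r1.bed_path.read_bytes() == r2.bed_path.read_bytes()


def test_join_abundance_populates_sorts_and_blanks(three_plant_result, tmp_path):
    synth, result = three_plant_result
    table = tmp_path / "abundance.tsv"
    table.write_text("gene\tppm\nalpha\t4.720\ngamma\t329.000\n")
    frame = join_abundance(result.report, table)
    by = frame.set_index("gene")["abundance_ppm"]
    assert by["alpha"] == "4.720" and by["gamma"] == "329.000"
    assert by["beta"] == ""  # unmatched gene stays blank
    # ranked by abundance when supplied
    scan2 = run_scan(synth.genbank_path, tmp_path / "ranked", abundance_path=table)
    assert list(scan2.report["gene"])[:2] == ["gamma", "alpha"]


def test_duplicate_abundance_id_errors_with_name(three_plant_result, tmp_path):
    _, result = three_plant_result
    table = tmp_path / "dup.tsv"
    table.write_text("gene\tppm\nalpha\t1\nalpha\t2\n")
    with pytest.raises(ValueError, match="alpha"):
        join_abundance(result.report, table)


def test_missing_sd_renders_em_dash(tmp_path):
    synth = generate_synthetic_genome(
        [PlantSpec("nosd", OverlapClass.ATGtg, sd_motif=None)], seed=1, out_dir=tmp_path
    )
    result = run_scan(synth.genbank_path, tmp_path / "rep")
    row = result.report.iloc[0]
    assert row["sd_motifs"] == EM_DASH
    assert row["predicted_ambiguity"] == EM_DASH
    assert row["label"] == "no_sd"


def test_config_defaults_round_trip(tmp_path):
    assert load_config(None) == ScanConfig()
    path = tmp_path / "cfg.yaml"
    path.write_text("upstream_window: 25\nwindows:\n  gug_ambiguous_max: 15\n")
    cfg = load_config(path)
    assert cfg.upstream_window == 25
    assert cfg.windows.gug_ambiguous_max == 15


@pytest.mark.parametrize(
    "text", ["unknown_key: 1\n", "asd_sequence: ACCT\n", "windows: {aug_ambiguous_min: 3}\n", ":\n -"]
)
def test_malformed_config_raises(tmp_path, text):
    path = tmp_path / "bad.yaml"
    path.write_text(text)
    with pytest.raises(ConfigError):
        load_config(path)


def test_cli_scan_and_spacing(tmp_path):
    synth = generate_synthetic_genome(
        [PlantSpec("alpha", OverlapClass.ATGtg, "UAAGGAGG", 4)], seed=5, out_dir=tmp_path
    )
    runner = CliRunner()
    res = runner.invoke(
        main, ["scan", str(synth.genbank_path), "--out", str(tmp_path / "cli_out")]
    )
    assert res.exit_code == 0, res.output
    assert "1 overlaps" in res.output
    res = runner.invoke(
        main,
        ["spacing", "--upstream", "CCUAAGGAGGCC", "--codon-offset", "0", "--codon-offset", "2"],
    )
    assert res.exit_code == 0, res.output
    assert "UAAGGAGG" in res.output and "\t10" in res.output and "\t12" in res.output


def test_cli_synth_writes_fixture(tmp_path):
    runner = CliRunner()
    res = runner.invoke(
        main, ["synth", "--out", str(tmp_path / "s"), "--seed", "2", "--n-decoys", "4"]
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "s" / "truth_manifest.tsv").exists()


def test_cli_malformed_config_exits_nonzero(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("unknown_key: 1\n")
    genome = tmp_path / "g.gbk"
    synth = generate_synthetic_genome([], n_decoys=1, seed=0)
    write_genbank(synth.genome, genome)
    runner = CliRunner()
    res = runner.invoke(main, ["scan", str(genome), "--config", str(bad)])
    assert res.exit_code != 0
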