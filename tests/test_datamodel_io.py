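"""Domain types and format readers/writers."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from topomut import io as tio
from topomut.datamodel import (
    Config,
    GenomeSequence,
    IntervalSignal,
    TranscriptSet,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=10000>\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


@pytest.fixture
def genome():
    return GenomeSequence({"1": "ACGTACGTAC" * 1000})


# ----------------------------------------------------------------- mutations


def test_vcf_coordinate_conversion_and_class_inference(tmp_path, genome):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        VCF_HEADER
        + "chr1\t101\t.\tC\tT\t.\t.\t.\n"
        + "chr1\t201\t.\tCA\tTG\t.\t.\t.\n"
        + "chr1\t301\t.\tCGT\tC\t.\t.\t.\n"
    )
    recs = tio.read_mutations(str(vcf), "vcf", genome)
    assert [(m.pos, m.mut_class) for m in recs] == [
        (100, "SBS"),
        (200, "DBS"),
        (300, "ID"),
    ]
    assert recs[0].ref == "C" and recs[0].alt == "T"
    assert recs[0].chrom == "1"  # chr prefix stripped


def test_vcf_unknown_chromosome_skipped(tmp_path, genome):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        VCF_HEADER.replace("chr1", "chrZ") + "chrZ\t11\t.\tC\tT\t.\t.\t.\n"
    )
    assert tio.read_mutations(str(vcf), "vcf", genome) == []


def test_text_round_trip(tmp_path, genome):
    path = tmp_path / "m.txt"
    path.write_text(
        "sample\tchrom\tpos\tref\talt\n"
        "S1\t1\t101\tC\tT\n"
        "S2\tchr1\t202\tG\tGTT\n"
    )
    recs = tio.read_mutations(str(path), "text", genome)
    assert [(m.sample_id, m.pos, m.mut_class) for m in recs] == [
        ("S1", 100, "SBS"),
        ("S2", 201, "ID"),
    ]
    out = tmp_path / "w.txt"
    tio.write_mutations_text(recs, str(out))
    again = tio.read_mutations(str(out), "text", genome)
    assert [(m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.mut_class) for m in recs] == [
        (m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.mut_class) for m in again
    ]


def test_text_parse_error_names_line(tmp_path, genome):
    path = tmp_path / "bad.txt"
    path.write_text("S1\t1\tnotanumber\tC\tT\n")
    with pytest.raises(tio.ParseError, match="line 1"):
        tio.read_mutations(str(path), "text", genome)


def test_maf_read_including_unanchored_indels(tmp_path, genome):
    maf = tmp_path / "m.maf"
    # genome is ACGTACGT...: position 101 (1-based) holds A
    maf.write_text(
        "Tumor_Sample_Barcode\tChromosome\tStart_Position\t"
        "Reference_Allele\tTumor_Seq_Allele2\n"
        "S1\t1\t101\tA\tG\n"
        "S1\t1\t202\tC\t-\n"  # deletion of the base at 202
        "S1\t1\t303\t-\tTT\n"  # insertion between 303 and 304
    )
    recs = tio.read_mutations(str(maf), "maf", genome)
    assert [(m.pos, m.mut_class) for m in recs] == [(100, "SBS"), (200, "ID"), (302, "ID")]
    sbs = recs[0]
    assert genome.fetch("1", sbs.pos, sbs.pos + 1) == sbs.ref == "A"
    dele = recs[1]
    assert dele.ref == genome.fetch("1", dele.pos, dele.pos + 2)
    assert dele.alt == dele.ref[0]


# -------------------------------------------------------------------- tracks


def test_bed_value_column_rules(tmp_path):
    bed = tmp_path / "t.bed"
    bed.write_text(
        "chr1\t0\t10\tpeak\t5.0\n"  # 5-column: score column
        "chr1\t20\t30\t2.5\n"  # 4-column bedGraph dialect
        "chr1\t40\t50\tname\n"  # non-numeric 4th: presence/absence
    )
    sig = tio.read_signal_track(str(bed), "bed")
    assert list(sig.records()) == [
        ("1", 0, 10, 5.0),
        ("1", 20, 30, 2.5),
        ("1", 40, 50, 1.0),
    ]


def test_bed_overlap_mean_merge(tmp_path):
    bed = tmp_path / "t.bed"
    bed.write_text("chr1\t0\t10\tx\t2\nchr1\t0\t10\ty\t4\n")
    sig = tio.read_signal_track(str(bed), "bed")
    assert list(sig.records()) == [("1", 0, 10, 3.0)]


def test_partial_overlap_mean_merge_oracle():
    # [0,10)@2 and [5,15)@4: derived per-base mean
    sig = IntervalSignal.from_intervals({"1": [(0, 10, 2.0), (5, 15, 4.0)]})
    assert list(sig.records()) == [("1", 0, 5, 2.0), ("1", 5, 10, 3.0), ("1", 10, 15, 4.0)]


def test_bed_invalid_interval_rejected(tmp_path):
    bed = tmp_path / "t.bed"
    bed.write_text("chr1\t10\t10\tx\t1\n")
    with pytest.raises(tio.ParseError):
        tio.read_signal_track(str(bed), "bed")


def test_wig_fixed_and_variable_step(tmp_path):
    wig = tmp_path / "t.wig"
    wig.write_text(
        "fixedStep chrom=chr1 start=11 step=1\n1.0\n2.0\n3.0\n"
        "variableStep chrom=chr2 span=5\n101\t7.5\n"
    )
    sig = tio.read_signal_track(str(wig), "wig")
    assert list(sig.records()) == [
        ("1", 10, 11, 1.0),
        ("1", 11, 12, 2.0),
        ("1", 12, 13, 3.0),
        ("2", 100, 105, 7.5),
    ]


def test_bigwig_round_trip(tmp_path):
    pyBigWig = pytest.importorskip("pyBigWig")
    bw_path = tmp_path / "t.bw"
    bw = pyBigWig.open(str(bw_path), "w")
    bw.addHeader([("chr1", 1000)])
    bw.addEntries(["chr1", "chr1"], [0, 100], ends=[50, 200], values=[1.5, 2.5])
    bw.close()
    sig = tio.read_signal_track(str(bw_path), "bigwig")
    assert list(sig.records()) == [("1", 0, 50, 1.5), ("1", 100, 200, 2.5)]


def test_track_loading_idempotent(tmp_path):
    bed = tmp_path / "t.bed"
    bed.write_text("chr1\t0\t10\tx\t2\nchr1\t5\t20\ty\t4\nchr2\t7\t9\tz\t1\n")
    sig = tio.read_signal_track(str(bed), "bed")
    out = tmp_path / "w.bed"
    tio.write_bed(sig, str(out))
    again = tio.read_signal_track(str(out), "bed")
    assert list(sig.records()) == list(again.records())


# ------------------------------------------------------------------ matrices


def _write_profile(path, colsums=(1.0,)):
    channels = [f"ch{i}" for i in range(4)]
    data = {
        f"SIG{j + 1}": [colsums[j] / 4.0] * 4 for j in range(len(colsums))
    }
    pd.DataFrame(data, index=channels).to_csv(path, sep="\t")


def test_read_matrices_valid(tmp_path):
    sig, act = tmp_path / "sig.tsv", tmp_path / "act.tsv"
    _write_profile(sig)
    pd.DataFrame({"SIG1": [10.0, 20.0]}, index=["S1", "S2"]).to_csv(act, sep="\t")
    profile, activities = tio.read_matrices(str(sig), str(act))
    assert profile.signatures == ["SIG1"] and activities.samples == ["S1", "S2"]
    np.testing.assert_allclose(profile.P.sum(axis=0), 1.0)


@pytest.mark.parametrize(
    "bad",
    ["colsum", "negative_activity", "label_mismatch"],
)
def test_read_matrices_validation_errors(tmp_path, bad):
    sig, act = tmp_path / "sig.tsv", tmp_path / "act.tsv"
    if bad == "colsum":
        _write_profile(sig, colsums=(0.5,))
        pd.DataFrame({"SIG1": [10.0]}, index=["S1"]).to_csv(act, sep="\t")
    elif bad == "negative_activity":
        _write_profile(sig)
        pd.DataFrame({"SIG1": [-1.0]}, index=["S1"]).to_csv(act, sep="\t")
    else:
        _write_profile(sig)
        pd.DataFrame({"SIGX": [1.0]}, index=["S1"]).to_csv(act, sep="\t")
    with pytest.raises(ValueError):
        tio.read_matrices(str(sig), str(act))


# --------------------------------------------------------------- transcripts


def test_transcripts_bed6_and_gtf(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("chr1\t100\t200\tgeneA\t0\t+\nchr1\t300\t400\tgeneB\t0\t-\n")
    tx = tio.read_transcripts(str(bed), "bed")
    starts, ends, strands, ids = tx.spans("1")
    assert list(ids) == ["geneA", "geneB"] and list(strands) == [1, -1]

    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        '1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "geneA"; gene_biotype "protein_coding";\n'
        '1\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "rnaX"; gene_biotype "lincRNA";\n'
        '1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "geneA";\n'
    )
    tx2 = tio.read_transcripts(str(gtf), "gtf")
    starts2, ends2, _, ids2 = tx2.spans("1")
    assert list(ids2) == ["geneA"]  # non-coding gene filtered
    assert starts2[0] == 100 and ends2[0] == 200  # 1-based GTF converted


def test_strand_codes():
    tx = TranscriptSet([("1", 10, 20, "+", "a"), ("1", 15, 30, "-", "b")])
    code = tx.strand_codes("1", 40)
    assert code[5] == 0 and code[12] == 1 and code[25] == 2 and code[17] == 3


# ------------------------------------------------------------------- results


def test_write_results_manifest_and_determinism(tmp_path):
    tables = {
        "occupancy": pd.DataFrame({"signature": [], "p": []}),
        "timing": pd.DataFrame({"bin": [1, 2], "norm_density": [0.5, 1.0]}),
    }
    cfg = Config(n_sims=5, rng_seed=42)
    out1, out2 = tmp_path / "a", tmp_path / "b"
    p1 = tio.write_results(tables, str(out1), cfg.to_dict(), cfg.rng_seed)
    p2 = tio.write_results(tables, str(out2), cfg.to_dict(), cfg.rng_seed)
    # empty table -> header-only TSV
    assert (out1 / "occupancy.tsv").read_text() == "signature\tp\n"
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert manifest["rng_seed"] == 42
    for name in ("occupancy.tsv", "timing.tsv", "manifest.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


# ----------------------------------------------------------------- genome


def test_genome_fetch_bounds(genome):
    assert genome.fetch("1", 0, 4) == "ACGT"
    assert len(genome.fetch("1", 10, 10)) == 0
    with pytest.raises(ValueError):
        genome.fetch("1", -1, 5)
    with pytest.raises(ValueError):
        genome.fetch("1", 0, genome.lengths["1"] + 1)
    with pytest.raises(KeyError):
        genome.fetch("nope", 0, 1)


def test_genome_fasta_round_trip(tmp_path, genome):
    path = tmp_path / "g.fa"
    genome.to_fasta(str(path))
    again = GenomeSequence.from_fasta(str(path))
    assert again.lengths == genome.lengths
    assert again.fetch("1", 0, 100) == genome.fetch("1", 0, 100)


def test_config_validation():
    with pytest.raises(ValueError):
        Config(prob_threshold=0.0)
    with pytest.raises(ValueError):
        Config(n_timing_bins=1)
    with pytest.raises(ValueError):
        Config(occupancy_halfwidth_bp=0)
    cfg = Config()
    assert cfg.n_sims == 100 and cfg.prob_threshold == 0.9
    assert cfg.processivity_max_gap_bp == 10_000
    assert Config.from_dict(cfg.to_dict()) == cfg
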