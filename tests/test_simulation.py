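"""Context index construction and context-preserving simulation."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from topomut.classification import classify_cohort, classify_sbs96
from topomut.datamodel import GenomeSequence, IntervalSignal, MutationRecord, revcomp
from topomut.simulation import ContextIndex, simulate


def test_context_index_acgt_enumeration_oracle():
    """genome ACGT: interior positions 1 and 2 both index under ACG."""
    g = GenomeSequence({"c": "ACGT"})
    idx = ContextIndex(g)
    pos, orient = idx.sbs("c", "ACG")
    assert pos.tolist() == [1, 2]
    assert orient.tolist() == [True, False]  # C direct; G via reverse complement
    for key in set("ACGT"):
        pass
    # no other context holds positions
    total = sum(
        len(idx.sbs("c", a + m + b)[0])
        for a in "ACGT"
        for m in "CT"
        for b in "ACGT"
    )
    assert total == 2


def test_context_index_exhaustive_against_string_oracle(tiny_genome):
    """Every interior position appears under exactly its pyrimidine context."""
    idx = ContextIndex(tiny_genome)
    seq = tiny_genome.fetch("t", 0, tiny_genome.lengths["t"])
    oracle = {}
    for p in range(1, len(seq) - 1):
        tri = seq[p - 1 : p + 2]
        key = tri if tri[1] in "CT" else revcomp(tri)
        oracle.setdefault(key, []).append(p)
    for key, positions in oracle.items():
        got, _ = idx.sbs("t", key)
        assert got.tolist() == positions


def test_all_n_chromosome_has_no_entries():
    g = GenomeSequence({"n": "N" * 100, "ok": "ACGTACGTACGT"})
    idx = ContextIndex(g)
    assert all(
        len(idx.sbs("n", a + m + b)[0]) == 0
        for a in "ACGT"
        for m in "CT"
        for b in "ACGT"
    )


def test_empty_usable_genome_is_an_error():
    with pytest.raises(ValueError):
        ContextIndex(GenomeSequence({"n": "N" * 50}))


def test_region_restricted_index_covers_region_plus_flanks(std_genome):
    regions = IntervalSignal.from_intervals({"1": [(50_000, 51_000, 1.0)]})
    idx = ContextIndex(std_genome, regions=regions, flank_bp=10_000)
    for a in "ACGT":
        for m in "CT":
            for b in "ACGT":
                pos, _ = idx.sbs("1", a + m + b)
                if len(pos):
                    assert pos.min() >= 40_000 and pos.max() < 61_000
                assert len(idx.sbs("2", a + m + b)[0]) == 0


def test_region_restricted_simulation_places_inside_flanked_region(std_genome):
    regions = IntervalSignal.from_intervals({"1": [(100_000, 101_000, 1.0)]})
    idx = ContextIndex(std_genome, regions=regions, flank_bp=10_000)
    muts = []
    for p in range(100_100, 100_200):
        ref = std_genome.fetch("1", p, p + 1)
        if ref not in "CT":
            continue
        m = MutationRecord("S1", "1", p, ref, "A" if ref != "A" else "G", "SBS")
        muts.append(m)
    kept, _ = classify_cohort(muts, std_genome)
    sims = simulate(kept, idx, 5, seed=3)
    for rep in sims.replicates:
        for m in rep:
            assert 90_000 <= m.pos < 111_000


def test_simulation_invalid_n():
    g = GenomeSequence({"c": "ACGTACGT"})
    with pytest.raises(ValueError):
        simulate([], ContextIndex(g), 0, seed=1)


@pytest.fixture(scope="module")
def small_cohort(std_genome, std_index):
    rng = np.random.default_rng(42)
    muts = []
    for _ in range(300):
        chrom = "1" if rng.integers(0, 2) else "2"
        p = int(rng.integers(100, std_genome.lengths[chrom] - 100))
        ref = std_genome.fetch(chrom, p, p + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        muts.append(MutationRecord(f"S{rng.integers(1, 4)}", chrom, p, ref, alt, "SBS"))
    kept, _ = classify_cohort(muts, std_genome)
    return kept


def test_per_chromosome_channel_counts_conserved(small_cohort, std_genome, std_index):
    sims = simulate(small_cohort, std_index, 4, seed=5)
    real = Counter((m.chrom, m.channel) for m in small_cohort)
    for rep in sims.replicates:
        assert len(rep) == len(small_cohort)
        reclassified, _ = classify_cohort(list(rep), std_genome)
        assert len(reclassified) == len(rep)
        assert Counter((m.chrom, m.channel) for m in reclassified) == real


def test_simulated_records_reclassify_to_source_channel(
    small_cohort, std_genome, std_index
):
    sims = simulate(small_cohort, std_index, 2, seed=9)
    for rep in sims.replicates:
        for m in rep:
            stored = m.channel
            got, flag = classify_sbs96(m, std_genome)
            assert got == stored and flag == m.pyr_on_plus


def test_simulation_determinism(small_cohort, std_index):
    a = simulate(small_cohort, std_index, 3, seed=11)
    b = simulate(small_cohort, std_index, 3, seed=11)
    for ra, rb in zip(a.replicates, b.replicates):
        assert [(m.chrom, m.pos, m.ref, m.alt) for m in ra] == [
            (m.chrom, m.pos, m.ref, m.alt) for m in rb
        ]
    c = simulate(small_cohort, std_index, 3, seed=12)
    assert any(
        [(m.pos) for m in ra] != [(m.pos) for m in rc]
        for ra, rc in zip(a.replicates, c.replicates)
    )


def test_placement_uniformity_chi_square():
    """Placements across one context's candidate sites are uniform."""
    rng = np.random.default_rng(4)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    g = GenomeSequence({"c": seq})
    idx = ContextIndex(g)
    # pick the most common pyrimidine context
    best = max(
        ((a + m + b) for a in "ACGT" for m in "CT" for b in "ACGT"),
        key=lambda k: len(idx.sbs("c", k)[0]),
    )
    cand, _ = idx.sbs("c", best)
    # 25 distinct-sample source mutations, 400 replicates -> 1e4 draws
    src_pos = int(cand[0])
    ref = g.fetch("c", src_pos, src_pos + 1)
    muts = [
        MutationRecord(f"S{i}", "c", src_pos, ref, "T" if ref != "T" else "G", "SBS")
        for i in range(25)
    ]
    kept, _ = classify_cohort(muts, g)
    sims = simulate(kept, idx, 400, seed=8)
    counts = Counter(m.pos for rep in sims.replicates for m in rep)
    observed = np.array([counts.get(int(p), 0) for p in cand])
    assert observed.sum() == 25 * 400
    p = stats.chisquare(observed).pvalue
    assert p > 0.01


def test_no_candidate_context_reuses_real_position(std_genome):
    # region-restricted index on chromosome 1 only: a chromosome-2 mutation
    # has no candidates, so every replicate keeps its real position
    regions = IntervalSignal.from_intervals({"1": [(50_000, 60_000, 1.0)]})
    idx = ContextIndex(std_genome, regions=regions, flank_bp=1000)
    p = 70_000
    ref = std_genome.fetch("2", p, p + 1)
    alt = "A" if ref != "A" else "G"
    kept, _ = classify_cohort([MutationRecord("S1", "2", p, ref, alt, "SBS")], std_genome)
    sims = simulate(kept, idx, 3, seed=2)
    assert sims.fallback_counts
    for rep in sims.replicates:
        assert rep[0].pos == p and rep[0].chrom == "2"


def test_duplicate_positions_redrawn_within_sample():
    rng = np.random.default_rng(6)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    g = GenomeSequence({"c": seq})
    idx = ContextIndex(g)
    # many same-sample mutations of one context force collisions
    key_positions, _ = idx.sbs("c", "ACA")
    muts = []
    for p in key_positions[:30]:
        ref = g.fetch("c", int(p), int(p) + 1)
        alt = "T" if ref == "C" else "A"
        muts.append(MutationRecord("S1", "c", int(p), ref, alt, "SBS"))
    kept, _ = classify_cohort(muts, g)
    sims = simulate(kept, idx, 10, seed=13)
    for rep in sims.replicates:
        positions = [m.pos for m in rep]
        # duplicates only tolerated if redraw budget was exhausted
        assert len(set(positions)) >= len(positions) - 2


def test_match_tx_strand_preserves_transcription_class(std_genome, std_transcripts):
    from topomut.simulation import _tx_class

    idx = ContextIndex(std_genome)
    codes = {
        c: std_transcripts.strand_codes(c, std_genome.lengths[c])
        for c in std_genome.chrom_names
    }
    rng = np.random.default_rng(3)
    muts = []
    for _ in range(100):
        chrom = "1"
        p = int(rng.integers(100, std_genome.lengths[chrom] - 100))
        ref = std_genome.fetch(chrom, p, p + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        muts.append(MutationRecord("S1", chrom, p, ref, alt, "SBS"))
    kept, _ = classify_cohort(muts, std_genome)
    sims = simulate(
        kept, idx, 2, seed=21, match_tx_strand=True, transcripts=std_transcripts
    )
    src_classes = [_tx_class(int(codes[m.chrom][m.pos]), m.pyr_on_plus) for m in kept]
    for rep in sims.replicates:
        got = [_tx_class(int(codes[m.chrom][m.pos]), m.pyr_on_plus) for m in rep]
        assert got == src_classes
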