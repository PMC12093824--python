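"""Replication timing bins, extrema, strand regions, and strand asymmetry."""

from __future__ import annotations

import numpy as np
import pytest

from topomut.datamodel import Config, GenomeSequence, IntervalSignal, MutationRecord
from topomut.replication import (
    ReplicationExtrema,
    annotate_strand_regions,
    find_extrema,
    replication_strand_counts,
    smooth_signal,
    timing_analysis,
)


def _track_from_values(values, step=1000, chrom="1"):
    triples = [
        (i * step, (i + 1) * step, float(v)) for i, v in enumerate(values)
    ]
    return IntervalSignal.from_intervals({chrom: triples})


# ------------------------------------------------------------------ smoothing


def test_smoothing_constant_track_unchanged():
    track = _track_from_values([5.0] * 256)
    sm = smooth_signal(track, step_bp=1000, window_bp=5000, scale_bp=16_000)
    _, values, valid = sm.data["1"]
    np.testing.assert_allclose(values, 5.0, rtol=1e-9)
    assert valid.all()


def test_smoothing_reduces_white_noise_variance():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(512)
    sm = smooth_signal(_track_from_values(x), step_bp=1000, window_bp=9000,
                       scale_bp=32_000)
    _, values, _ = sm.data["1"]
    assert values.var() < 0.5 * x.var()


def test_smoothing_preserves_triangular_bump_position():
    x = np.concatenate([np.zeros(100), np.linspace(0, 10, 50),
                        np.linspace(10, 0, 50), np.zeros(100)])
    sm = smooth_signal(_track_from_values(x), step_bp=1000, window_bp=5000,
                       scale_bp=8000)
    _, values, _ = sm.data["1"]
    assert abs(int(np.argmax(values)) - int(np.argmax(x))) <= 1


def test_smoothing_empty_track_rejected():
    with pytest.raises(ValueError):
        smooth_signal(IntervalSignal({}))


# -------------------------------------------------------------------- extrema


def test_monotone_ramp_has_no_extrema():
    sm = smooth_signal(_track_from_values(np.arange(300.0)), step_bp=1000,
                       window_bp=3000, scale_bp=4000)
    ex = find_extrema(sm)
    assert ex.peaks("1") == [] and ex.valleys("1") == []


def test_single_period_sinusoid_extrema_positions():
    n, step = 400, 1000
    x = np.sin(2 * np.pi * np.arange(n) / n)  # max at n/4, min at 3n/4
    sm = smooth_signal(_track_from_values(x, step=step), step_bp=step,
                       window_bp=3000, scale_bp=16_000)
    ex = find_extrema(sm)
    assert len(ex.peaks("1")) == 1 and len(ex.valleys("1")) == 1
    assert abs(ex.peaks("1")[0] - (n // 4) * step) <= 2 * step
    assert abs(ex.valleys("1")[0] - (3 * n // 4) * step) <= 2 * step


def test_two_bumps_give_two_peaks_one_interior_valley():
    x = np.concatenate([
        np.zeros(30), np.hanning(60) * 10, np.zeros(40),
        np.hanning(60) * 8, np.zeros(30),
    ])
    sm = smooth_signal(_track_from_values(x), step_bp=1000, window_bp=3000,
                       scale_bp=8000)
    ex = find_extrema(sm)
    peaks, valleys = ex.peaks("1"), ex.valleys("1")
    assert len(peaks) == 2
    interior = [v for v in valleys if peaks[0] < v < peaks[1]]
    assert len(interior) == 1


def test_fixture_wave_extrema_recovered_within_one_step(std_tracks, fixture_config):
    tracks, truth = std_tracks
    sm = smooth_signal(tracks["repliseq"], step_bp=1000, window_bp=20_000,
                       scale_bp=fixture_config.wavelet_scale_bp)
    ex = find_extrema(sm)
    for chrom in ("1", "2"):
        for kind, found in (("peaks", ex.peaks(chrom)), ("valleys", ex.valleys(chrom))):
            found = np.asarray(found)
            for t in truth[kind][chrom]:
                assert np.abs(found - t).min() <= 1000


# ------------------------------------------------------------- strand regions


def _extrema(chrom_points):
    ex = ReplicationExtrema(step=1000)
    ex.data = chrom_points
    return ex


def test_single_valley_to_peak_leading_region_with_trim():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (100_000, "peak")]})
    regions = annotate_strand_regions(ex, cfg)
    assert list(regions.records()) == [("1", 25_000, 100_000, "leading")]


def test_span_below_minimum_dropped():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (8000, "peak")]})
    assert list(annotate_strand_regions(ex, cfg).records()) == []


def test_peak_valley_peak_symmetric():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "peak"), (100_000, "valley"), (200_000, "peak")]})
    recs = list(annotate_strand_regions(ex, cfg).records())
    assert recs == [
        ("1", 0, 75_000, "lagging"),
        ("1", 125_000, 200_000, "leading"),
    ]
    # non-overlapping
    assert recs[0][2] <= recs[1][1]


def test_label_at_lookup():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (100_000, "peak"), (200_000, "valley")]})
    regions = annotate_strand_regions(ex, cfg)
    assert regions.label_at("1", 50_000) == 1  # leading
    assert regions.label_at("1", 120_000) == -1  # lagging
    assert regions.label_at("1", 10_000) == 0  # inside the trim
    assert regions.label_at("2", 1) == 0


# --------------------------------------------------------------------- timing


def test_equal_count_partition_and_earliest_first():
    values = np.arange(100.0)  # distinct values
    sm = smooth_signal(_track_from_values(values), step_bp=1000, window_bp=1000,
                       scale_bp=2000)
    # skip the wavelet distortion: use raw resampled values
    sm.data["1"] = (0, values, np.ones(100, dtype=bool))
    genome = GenomeSequence({"1": "ACGT" * 25_000})
    tb = timing_analysis([], [], sm, genome, 10)
    assert tb.bin_record_counts.tolist() == [10] * 10
    assert np.all(np.diff(tb.bin_mean_signal) < 0)  # bin 1 = highest = earliest


def test_bin_count_balance_for_any_input_size():
    genome = GenomeSequence({"1": "ACGT" * 40_000})
    for n_records in (23, 57, 101):
        values = np.random.default_rng(n_records).random(n_records)
        sm = smooth_signal(_track_from_values(values), step_bp=1000,
                           window_bp=1000, scale_bp=2000)
        sm.data["1"] = (0, values, np.ones(n_records, dtype=bool))
        tb = timing_analysis([], [], sm, genome, 10)
        sizes = tb.bin_record_counts
        assert sizes.sum() == n_records and sizes.max() - sizes.min() <= 1


def test_uniform_mutations_give_flat_normalized_density():
    genome = GenomeSequence({"1": "ACGT" * 25_000})
    values = np.arange(100.0)
    sm = smooth_signal(_track_from_values(values), step_bp=1000, window_bp=1000,
                       scale_bp=2000)
    sm.data["1"] = (0, values, np.ones(100, dtype=bool))
    muts = [MutationRecord("s", "1", p, "C", "T", "SBS")
            for p in range(500, 100_000, 1000)]  # one per record
    tb = timing_analysis(muts, [], sm, genome, 10)
    np.testing.assert_allclose(tb.real_density, 1.0)
    assert tb.real_density.max() == 1.0


def test_mutation_outside_coverage_excluded():
    genome = GenomeSequence({"1": "ACGT" * 25_000, "2": "ACGT" * 1000})
    values = np.arange(50.0)
    sm = smooth_signal(_track_from_values(values), step_bp=1000, window_bp=1000,
                       scale_bp=2000)
    sm.data["1"] = (0, values, np.ones(50, dtype=bool))
    muts = [MutationRecord("s", "1", 500, "C", "T", "SBS"),
            MutationRecord("s", "2", 100, "C", "T", "SBS"),
            MutationRecord("s", "1", 90_000, "C", "T", "SBS")]
    tb = timing_analysis(muts, [], sm, genome, 10)
    assert tb.n_excluded == 2 and tb.real_counts.sum() == 1


def test_max_normalized_density_is_exactly_one_when_nonempty():
    genome = GenomeSequence({"1": "ACGT" * 25_000})
    values = np.random.default_rng(3).random(100)
    sm = smooth_signal(_track_from_values(values), step_bp=1000, window_bp=1000,
                       scale_bp=2000)
    sm.data["1"] = (0, values, np.ones(100, dtype=bool))
    muts = [MutationRecord("s", "1", p, "C", "T", "SBS") for p in (1500, 2500, 77_500)]
    tb = timing_analysis(muts, [], sm, genome, 10)
    assert tb.real_density.max() == 1.0


# -------------------------------------------------------------- strand counts


def _sbs(chrom, pos, sub, pyr_on_plus=True):
    ref, alt = sub[0], sub[2]
    m = MutationRecord("s", chrom, pos, ref, alt, "SBS",
                       channel=f"A[{sub}]A", pyr_on_plus=pyr_on_plus)
    return m


def test_strand_label_involution():
    """Flipping every pyrimidine orientation swaps leading/lagging totals."""
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (100_000, "peak"), (200_000, "valley")]})
    regions = annotate_strand_regions(ex, cfg)
    rng = np.random.default_rng(4)
    muts = [_sbs("1", int(p), "C>T", bool(rng.integers(0, 2)))
            for p in rng.integers(0, 200_000, size=200)]
    flipped = [_sbs(m.chrom, m.pos, "C>T", not m.pyr_on_plus) for m in muts]
    from topomut.replication import _strand_counts

    a = _strand_counts(muts, regions)
    b = _strand_counts(flipped, regions)
    for sub in a:
        assert a[sub] == b[sub][::-1]


def test_replication_strand_null_and_oracle():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (100_000, "peak")]})
    regions = annotate_strand_regions(ex, cfg)
    # all mutations on leading (pyr plus, inside the region)
    real = {"SIG": [_sbs("1", 30_000 + i * 10, "C>T") for i in range(90)]
            + [_sbs("1", 60_000 + i * 10, "C>T", False) for i in range(10)]}
    sims = {"SIG": [
        [_sbs("1", 30_000 + i * 10, "C>T") for i in range(50)]
        + [_sbs("1", 60_000 + i * 10, "C>T", False) for i in range(50)]
    ] * 2}
    df = replication_strand_counts(real, sims, regions, cfg)
    row = df[df.subtype == "C>T"].iloc[0]
    assert row.leading == 90 and row.lagging == 10
    assert row.sim_leading == 50 and row.sim_lagging == 50
    from topomut.stattests import fisher_exact_2x2

    odds, p = fisher_exact_2x2(10, 90, 50, 50)  # lagging-vs-leading orientation
    assert row.odds_ratio == pytest.approx(odds)
    assert row.p == pytest.approx(p)


def test_equal_real_and_sim_counts_not_significant():
    cfg = Config(n_sims=2)
    ex = _extrema({"1": [(0, "valley"), (100_000, "peak")]})
    regions = annotate_strand_regions(ex, cfg)
    ms = [_sbs("1", 30_000 + i * 7, "C>T", bool(i % 2)) for i in range(100)]
    df = replication_strand_counts({"SIG": ms}, {"SIG": [ms, ms]}, regions, cfg)
    row = df[df.subtype == "C>T"].iloc[0]
    assert row.odds_ratio == pytest.approx(1.0)
    assert not row.significant
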