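"""Replication timing and replication strand asymmetry.

The Repli-seq signal (high = early) is resampled onto a fixed step grid,
smoothed by a length-weighted moving average, and reconstructed from a
discrete-wavelet approximation. Local maxima of the smoothed signal are
replication initiation zones (peaks) and local minima are termination zones
(valleys). Timing analysis ranks the smoothed signal records in descending
order and splits them into equal-count bins (deciles by default, bin 1
earliest); per-bin mutation densities are normalized by the valid (A/C/G/T)
base count and then by the maximum density. Strand analysis labels
valley-to-peak spans (positive slope left to right) as leading and
peak-to-valley spans as lagging, trims the last 25 kb next to each
termination zone, and tests per-subtype leading/lagging counts of real
versus simulated mutations with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks

from .datamodel import Config, GenomeSequence, IntervalSignal, MutationRecord
from .stattests import TestResult, fisher_exact_2x2, finalize_results

log = logging.getLogger(__name__)

SBS_SUBTYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


# ------------------------------------------------------------------ smoothing


@dataclass
class SmoothedSignal:
    step: int
    window_bp: int
    wavelet: str
    level: int
    # per chromosome: (grid start, smoothed values per step, had-coverage flag)
    data: Dict[str, Tuple[int, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.data:
            return float("nan")
        start, values, valid = self.data[chrom]
        idx = (pos - start) // self.step
        if idx < 0 or idx >= len(values) or not valid[idx]:
            return float("nan")
        return float(values[idx])

    def step_index(self, chrom: str, pos: int) -> int:
        start, values, valid = self.data[chrom]
        idx = (pos - start) // self.step
        if idx < 0 or idx >= len(values) or not valid[idx]:
            return -1
        return int(idx)


def _resample(track: IntervalSignal, chrom: str, step: int):
    s, e, v = track.intervals(chrom)
    if len(s) == 0:
        return None
    start = (int(s[0]) // step) * step
    nbins = (int(e[-1]) - start + step - 1) // step
    wsum = np.zeros(nbins)
    weight = np.zeros(nbins)
    for a, b, val in zip(s, e, v):
        b0 = (int(a) - start) // step
        b1 = (int(b) - 1 - start) // step
        for bi in range(b0, b1 + 1):
            lo = max(int(a), start + bi * step)
            hi = min(int(b), start + (bi + 1) * step)
            if hi > lo:
                wsum[bi] += val * (hi - lo)
                weight[bi] += hi - lo
    valid = weight > 0
    values = np.zeros(nbins)
    values[valid] = wsum[valid] / weight[valid]
    if not valid.all() and valid.any():
        # fill gaps by interpolation so smoothing sees a continuous series
        idx = np.arange(nbins)
        values[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return start, values, valid


def smooth_signal(
    track: IntervalSignal,
    step_bp: int = 1000,
    window_bp: int = 20_000,
    wavelet: str = "bior3.5",
    scale_bp: int = 100_000,
) -> SmoothedSignal:
    """Weighted-average smoothing followed by a wavelet approximation.

    Values are resampled onto ``step_bp`` bins (overlap-length weighted
    average), smoothed by a moving average spanning ``window_bp``, then
    reconstructed from the wavelet approximation at the level whose scale is
    closest to ``scale_bp``. Chromosomes shorter than the window pass
    through with a warning.
    """
    if track.n_intervals == 0:
        raise ValueError("cannot smooth an empty track")
    target_level = max(1, int(round(np.log2(max(scale_bp / step_bp, 2.0)))))
    out = SmoothedSignal(step=step_bp, window_bp=window_bp, wavelet=wavelet, level=0)
    for chrom in track.chroms():
        res = _resample(track, chrom, step_bp)
        if res is None:
            continue
        start, values, valid = res
        w = max(1, int(round(window_bp / step_bp)))
        if w % 2 == 0:
            w += 1  # odd kernel keeps the moving average phase-neutral
        if w > 1 and len(values) >= w:
            kernel = np.ones(w)
            smoothed = np.convolve(values, kernel, mode="same") / np.convolve(
                np.ones_like(values), kernel, mode="same"
            )
        else:
            if len(values) < w:
                log.warning("%s shorter than smoothing window; passthrough", chrom)
            smoothed = values.copy()
        max_level = pywt.dwt_max_level(len(smoothed), wavelet)
        level = min(target_level, max_level)
        if level >= 1:
            coeffs = pywt.wavedec(smoothed, wavelet, mode="symmetric", level=level)
            coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
            smoothed = pywt.waverec(coeffs, wavelet, mode="symmetric")[
                : len(smoothed)
            ]
            out.level = max(out.level, level)
        out.data[chrom] = (start, smoothed, valid)
    return out


# -------------------------------------------------------------------- extrema


@dataclass
class ReplicationExtrema:
    """Alternating peak (initiation) / valley (termination) positions."""

    step: int
    # per chromosome, a coordinate-sorted list of (position, kind) with
    # kind in {"peak", "valley"}; consecutive entries alternate
    data: Dict[str, List[Tuple[int, str]]] = field(default_factory=dict)

    def peaks(self, chrom: str) -> List[int]:
        return [p for p, k in self.data.get(chrom, []) if k == "peak"]

    def valleys(self, chrom: str) -> List[int]:
        return [p for p, k in self.data.get(chrom, []) if k == "valley"]


def find_extrema(s: SmoothedSignal, min_prominence: float = 0.0) -> ReplicationExtrema:
    """Alternating local maxima/minima of the smoothed signal per chromosome.

    ``min_prominence`` is an absolute signal-unit threshold; when 0, a
    default of 10% of the chromosome's signal range is used so that residual
    wavelet ripples do not register as replication domains.
    """
    out = ReplicationExtrema(step=s.step)
    for chrom, (start, values, _valid) in s.data.items():
        if min_prominence > 0:
            prom = min_prominence
        else:
            rng = float(values.max() - values.min())
            prom = 0.1 * rng if rng > 0 else None
        pk, _ = find_peaks(values, prominence=prom)
        vl, _ = find_peaks(-values, prominence=prom)
        combined = sorted(
            [(int(i), "peak") for i in pk] + [(int(i), "valley") for i in vl]
        )
        # enforce alternation: among consecutive same-kind extrema keep the
        # most extreme one
        cleaned: List[Tuple[int, str]] = []
        for idx, kind in combined:
            if cleaned and cleaned[-1][1] == kind:
                prev_idx = cleaned[-1][0]
                better = (
                    values[idx] > values[prev_idx]
                    if kind == "peak"
                    else values[idx] < values[prev_idx]
                )
                if better:
                    cleaned[-1] = (idx, kind)
            else:
                cleaned.append((idx, kind))
        out.data[chrom] = [
            (start + idx * s.step + s.step // 2, kind) for idx, kind in cleaned
        ]
    return out


# -------------------------------------------------------------------- timing


@dataclass
class TimingBins:
    n_bins: int
    bin_record_counts: np.ndarray  # ranked signal records per bin
    bin_mean_signal: np.ndarray  # mean smoothed signal per bin (1 = earliest)
    valid_bases: np.ndarray
    real_counts: np.ndarray
    real_density: np.ndarray  # normalized to max = 1
    sim_density_mean: np.ndarray
    sim_density_lo: np.ndarray
    sim_density_hi: np.ndarray
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "n_records": self.bin_record_counts,
                "valid_bases": self.valid_bases,
                "real_count": self.real_counts,
                "norm_density": self.real_density,
                "sim_mean": self.sim_density_mean,
                "sim_lo": self.sim_density_lo,
                "sim_hi": self.sim_density_hi,
            }
        )


def _normalized_density(counts: np.ndarray, valid_bases: np.ndarray) -> np.ndarray:
    dens = np.zeros(len(counts))
    nz = valid_bases > 0
    dens[nz] = counts[nz] / valid_bases[nz]
    top = dens.max()
    if top > 0:
        dens = dens / top
    return dens


def timing_analysis(
    mutations: Sequence[MutationRecord],
    sim_replicates: Sequence[Sequence[MutationRecord]],
    s: SmoothedSignal,
    genome: GenomeSequence,
    n_bins: int = 10,
) -> TimingBins:
    """Equal-count timing bins (1 = earliest) and normalized mutation densities."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    # collect ranked signal records: one per covered step
    chroms, idxs, vals = [], [], []
    for chrom, (start, values, valid) in s.data.items():
        ii = np.flatnonzero(valid)
        chroms += [chrom] * len(ii)
        idxs.append(ii)
        vals.append(values[ii])
    if not chroms:
        raise ValueError("smoothed signal covers no positions")
    idxs = np.concatenate(idxs)
    vals = np.concatenate(vals)
    order = np.argsort(-vals, kind="stable")  # descending; bin 1 = highest/earliest
    splits = np.array_split(np.arange(len(order)), n_bins)
    bin_record_counts = np.array([len(sp) for sp in splits])
    bin_mean_signal = np.array([vals[order[sp]].mean() for sp in splits])

    # per-chromosome map step index -> bin
    bin_of_step: Dict[str, np.ndarray] = {
        chrom: np.full(len(values), -1, dtype=np.int64)
        for chrom, (_, values, _v) in s.data.items()
    }
    rank_to_bin = np.empty(len(order), dtype=np.int64)
    for b, sp in enumerate(splits):
        rank_to_bin[sp] = b
    rec_bin = np.empty(len(order), dtype=np.int64)
    rec_bin[np.arange(len(order))] = -1
    for rank, rec in enumerate(order):
        rec_bin[rec] = rank_to_bin[rank]
    for rec, (chrom, idx) in enumerate(zip(chroms, idxs)):
        bin_of_step[chrom][idx] = rec_bin[rec]

    # valid bases per bin
    valid_bases = np.zeros(n_bins)
    for chrom, (start, values, _v) in s.data.items():
        codes = genome.codes(chrom)
        prefix = np.concatenate([[0], np.cumsum(codes < 4)])
        L = len(codes)
        bmap = bin_of_step[chrom]
        for idx in np.flatnonzero(bmap >= 0):
            a = max(0, start + idx * s.step)
            b = min(L, start + (idx + 1) * s.step)
            if b > a:
                valid_bases[bmap[idx]] += prefix[b] - prefix[a]

    def count_bins(muts) -> Tuple[np.ndarray, int]:
        counts = np.zeros(n_bins)
        excluded = 0
        for m in muts:
            if m.chrom not in s.data:
                excluded += 1
                continue
            start, values, _v = s.data[m.chrom]
            idx = (m.pos - start) // s.step
            if idx < 0 or idx >= len(values) or bin_of_step[m.chrom][idx] < 0:
                excluded += 1
                continue
            counts[bin_of_step[m.chrom][idx]] += 1
        return counts, excluded

    real_counts, n_excluded = count_bins(mutations)
    real_density = _normalized_density(real_counts, valid_bases)
    sim_densities = []
    for rep in sim_replicates:
        c, _ = count_bins(rep)
        sim_densities.append(_normalized_density(c, valid_bases))
    if sim_densities:
        sim_arr = np.stack(sim_densities)
        sim_mean = sim_arr.mean(axis=0)
        sim_sd = sim_arr.std(axis=0, ddof=1) if len(sim_densities) > 1 else np.zeros(
            n_bins
        )
        sim_lo = sim_mean - 1.96 * sim_sd
        sim_hi = sim_mean + 1.96 * sim_sd
    else:
        sim_mean = sim_lo = sim_hi = np.full(n_bins, np.nan)
    return TimingBins(
        n_bins=n_bins,
        bin_record_counts=bin_record_counts,
        bin_mean_signal=bin_mean_signal,
        valid_bases=valid_bases,
        real_counts=real_counts,
        real_density=real_density,
        sim_density_mean=sim_mean,
        sim_density_lo=sim_lo,
        sim_density_hi=sim_hi,
        n_excluded=n_excluded,
    )


# ------------------------------------------------------------- strand regions


@dataclass
class StrandRegions:
    """Reference-strand leading/lagging annotation between extrema."""

    # per chromosome: sorted (starts, ends, labels) with label +1 leading,
    # -1 lagging
    data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def label_at(self, chrom: str, pos: int) -> int:
        if chrom not in self.data:
            return 0
        starts, ends, labels = self.data[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return int(labels[i])
        return 0

    def records(self):
        for chrom, (starts, ends, labels) in self.data.items():
            for s, e, l in zip(starts, ends, labels):
                yield chrom, int(s), int(e), "leading" if l > 0 else "lagging"


def annotate_strand_regions(e: ReplicationExtrema, cfg: Config) -> StrandRegions:
    """Label valley-to-peak spans leading and peak-to-valley spans lagging.

    Spans shorter than ``strand_region_min_bp`` are dropped;
    ``termination_trim_bp`` is removed from the valley (termination) end of
    every retained span.
    """
    out = StrandRegions()
    for chrom, extrema in e.data.items():
        starts, ends, labels = [], [], []
        for (p0, k0), (p1, k1) in zip(extrema, extrema[1:]):
            if k0 == k1:
                continue
            if p1 - p0 < cfg.strand_region_min_bp:
                continue
            if k0 == "valley":  # ascending signal: leading
                a, b, lab = p0 + cfg.termination_trim_bp, p1, 1
            else:  # descending: lagging, valley at the right end
                a, b, lab = p0, p1 - cfg.termination_trim_bp, -1
            if b > a:
                starts.append(a)
                ends.append(b)
                labels.append(lab)
        if starts:
            out.data[chrom] = (
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
                np.array(labels, dtype=np.int8),
            )
    return out


# ------------------------------------------------------------- strand counts


def _strand_counts(muts: Sequence[MutationRecord], regions: StrandRegions):
    """Leading/lagging counts per pyrimidine subtype after orientation."""
    counts = {sub: [0, 0] for sub in SBS_SUBTYPES}  # [leading, lagging]
    for m in muts:
        if m.mut_class != "SBS":
            continue
        lab = regions.label_at(m.chrom, m.pos)
        if lab == 0:
            continue
        eff = lab if m.pyr_on_plus else -lab
        sub = m.pyr_subtype
        counts[sub][0 if eff > 0 else 1] += 1
    return counts


def replication_strand_counts(
    real_by_sig: Dict[str, Sequence[MutationRecord]],
    sims_by_sig: Dict[str, Sequence[Sequence[MutationRecord]]],
    regions: StrandRegions,
    cfg: Config,
) -> pd.DataFrame:
    """Per-signature, per-subtype leading/lagging asymmetry tests.

    Simulated counts are pooled across replicates and rescaled to the
    per-replicate expectation (rounded) so Fisher's exact test sees integer
    counts on both rows; BH correction runs across the full signature x
    subtype family, and significance additionally requires the odds ratio
    to exceed ``odds_ratio_threshold`` in either direction.
    """
    rows = []
    results: List[TestResult] = []
    for sig in sorted(real_by_sig):
        real_counts = _strand_counts(real_by_sig[sig], regions)
        reps = sims_by_sig.get(sig, [])
        pooled = {sub: [0, 0] for sub in SBS_SUBTYPES}
        for rep in reps:
            rc = _strand_counts(rep, regions)
            for sub in SBS_SUBTYPES:
                pooled[sub][0] += rc[sub][0]
                pooled[sub][1] += rc[sub][1]
        nrep = max(len(reps), 1)
        for sub in SBS_SUBTYPES:
            lead, lag = real_counts[sub]
            sim_lead = int(round(pooled[sub][0] / nrep))
            sim_lag = int(round(pooled[sub][1] / nrep))
            if lead + lag == 0 and sim_lead + sim_lag == 0:
                continue
            # lagging-vs-leading orientation: OR > 1 means the real cohort is
            # shifted toward the lagging strand relative to the simulations
            odds, p = fisher_exact_2x2(lag, lead, sim_lag, sim_lead)
            res = TestResult(statistic=odds, effect=odds, p=p)
            results.append(res)
            rows.append(
                {
                    "signature": sig,
                    "subtype": sub,
                    "leading": lead,
                    "lagging": lag,
                    "sim_leading": sim_lead,
                    "sim_lagging": sim_lag,
                    "odds_ratio": odds,
                }
            )
    finalize_results(results, cfg.alpha, effect_threshold=cfg.odds_ratio_threshold)
    for row, res in zip(rows, results):
        row.update(p=res.p, q=res.q, significant=res.significant, direction=res.direction)
    return pd.DataFrame(
        rows,
        columns=[
            "signature",
            "subtype",
            "leading",
            "lagging",
            "sim_leading",
            "sim_lagging",
            "odds_ratio",
            "p",
            "q",
            "significant",
            "direction",
        ],
    )
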