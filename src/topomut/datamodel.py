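"""Core domain types shared across the topography analyses.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
formats (VCF, MAF, simple text) are converted at the I/O boundary.
Chromosome names are normalized by stripping a leading ``chr`` so that
mutation files and signal tracks from different providers match.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base codes used for vectorized sequence work: A=0 C=1 G=2 T=3 N=4
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_TO_CODE[_b] = _c
    _BASE_TO_CODE[ord(chr(_b).lower())] = _c
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


def norm_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    if name[:3].lower() == "chr":
        return name[3:]
    return name


class GenomeSequence:
    """An in-memory reference genome with 0-based half-open ``fetch``.

    Sequences are held as upper-case strings; a cached uint8 code array
    (A=0, C=1, G=2, T=3, N=4) per chromosome supports the vectorized
    context scans used by the simulator.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {
            norm_chrom(c): s.upper() for c, s in sequences.items()
        }
        self.chrom_names: List[str] = list(self._seqs)
        self.lengths: Dict[str, int] = {c: len(s) for c, s in self._seqs.items()}
        self._codes: Dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return norm_chrom(chrom) in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        chrom = norm_chrom(chrom)
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"fetch({chrom}, {start}, {end}) outside chromosome bounds "
                f"[0, {self.lengths[chrom]})"
            )
        return self._seqs[chrom][start:end]

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 base-code array for a chromosome (cached)."""
        chrom = norm_chrom(chrom)
        if chrom not in self._codes:
            raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = _BASE_TO_CODE[raw]
        return self._codes[chrom]


@dataclass
class MutationRecord:
    """One somatic mutation.

    ``pos`` is the 0-based coordinate of the first mutated base for SBS/DBS
    and of the anchor base (VCF-style) for indels. ``pyr_on_plus`` is True
    iff the pyrimidine-oriented (SBS) or canonical-doublet (DBS)
    representation reads off the reference plus strand.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_class: str = ""  # SBS / DBS / ID
    channel: str = ""
    pyr_on_plus: bool = True
    probabilities: Dict[str, float] = field(default_factory=dict)
    origin: str = "real"
    replicate_index: int = 0

    def __post_init__(self):
        self.chrom = norm_chrom(self.chrom)

    @property
    def pyr_subtype(self) -> str:
        """Pyrimidine-oriented substitution subtype, e.g. ``C>T`` (SBS only)."""
        if self.mut_class != "SBS":
            raise ValueError("subtype defined for SBS records only")
        if self.channel:
            return self.channel[2:5]
        r, a = (self.ref, self.alt)
        if r in "CT":
            return f"{r}>{a}"
        return f"{r.translate(COMPLEMENT)}>{a.translate(COMPLEMENT)}"

    @property
    def ref_strand_subtype(self) -> str:
        """Reference-strand substitution, e.g. ``G>A`` kept distinct from ``C>T``."""
        sub = self.pyr_subtype
        if self.pyr_on_plus:
            return sub
        return f"{sub[0].translate(COMPLEMENT)}>{sub[2].translate(COMPLEMENT)}"


class IntervalSignal:
    """A per-chromosome set of sorted, non-overlapping (start, end, value) intervals.

    Overlaps in the input are resolved at construction time by averaging the
    values of all intervals covering each elementary segment.
    """

    def __init__(self, data: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {
            norm_chrom(c): (
                np.asarray(s, dtype=np.int64),
                np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=np.float64),
            )
            for c, (s, e, v) in data.items()
        }
        for chrom, (s, e, v) in self._data.items():
            if len(s) and (np.any(e[:-1] > s[1:]) or np.any(s >= e)):
                raise ValueError(f"intervals on {chrom} not sorted/non-overlapping")
            if len(v) and not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal values on {chrom}")

    @classmethod
    def from_intervals(
        cls, triples_by_chrom: Mapping[str, List[Tuple[int, int, float]]]
    ) -> "IntervalSignal":
        """Build from possibly overlapping intervals, mean-merging overlaps."""
        out = {}
        for chrom, triples in triples_by_chrom.items():
            if not triples:
                continue
            arr = np.asarray(triples, dtype=np.float64)
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            values = arr[:, 2]
            if np.any(starts < 0) or np.any(starts >= ends):
                raise ValueError(f"invalid interval coordinates on {chrom}")
            bounds = np.unique(np.concatenate([starts, ends]))
            i0 = np.searchsorted(bounds, starts)
            i1 = np.searchsorted(bounds, ends)
            nseg = len(bounds) - 1
            cover_sum = np.zeros(nseg + 1)
            cover_cnt = np.zeros(nseg + 1)
            np.add.at(cover_sum, i0, values)
            np.add.at(cover_sum, i1, -values)
            np.add.at(cover_cnt, i0, 1.0)
            np.add.at(cover_cnt, i1, -1.0)
            cover_sum = np.cumsum(cover_sum)[:-1]
            cover_cnt = np.cumsum(cover_cnt)[:-1]
            keep = cover_cnt > 0
            seg_s = bounds[:-1][keep]
            seg_e = bounds[1:][keep]
            seg_v = cover_sum[keep] / cover_cnt[keep]
            # merge touching segments with equal value
            if len(seg_s):
                brk = np.concatenate(
                    [[True], (seg_s[1:] != seg_e[:-1]) | (seg_v[1:] != seg_v[:-1])]
                )
                grp = np.cumsum(brk) - 1
                n = grp[-1] + 1
                ms = np.zeros(n, dtype=np.int64)
                me = np.zeros(n, dtype=np.int64)
                mv = np.zeros(n)
                ms[grp[brk]] = seg_s[brk]
                np.maximum.at(me, grp, seg_e)
                mv[grp[brk]] = seg_v[brk]
                out[norm_chrom(chrom)] = (ms, me, mv)
        return cls(out)

    def chroms(self) -> List[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        chrom = norm_chrom(chrom)
        if chrom not in self._data:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._data[chrom]

    def records(self) -> Iterator[Tuple[str, int, int, float]]:
        for chrom in self._data:
            s, e, v = self._data[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())


class SignatureProfile:
    """Channel distribution of each signature: P[channel, signature]."""

    def __init__(self, channels: List[str], signatures: List[str], P: np.ndarray):
        P = np.asarray(P, dtype=np.float64)
        if P.shape != (len(channels), len(signatures)):
            raise ValueError("profile matrix shape mismatch")
        if np.any(P < 0):
            raise ValueError("signature profile has negative entries")
        colsums = P.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > 1e-3)[0]
        if len(bad):
            names = [signatures[i] for i in bad]
            raise ValueError(f"signature columns do not sum to 1: {names}")
        self.channels = list(channels)
        self.signatures = list(signatures)
        self.P = P
        self._row = {c: i for i, c in enumerate(channels)}

    def row(self, channel: str) -> np.ndarray:
        return self.P[self._row[channel]]

    def __contains__(self, channel: str) -> bool:
        return channel in self._row


class ActivityMatrix:
    """Per-sample signature activities: A[sample, signature] = mutation counts."""

    def __init__(self, samples: List[str], signatures: List[str], A: np.ndarray):
        A = np.asarray(A, dtype=np.float64)
        if A.shape != (len(samples), len(signatures)):
            raise ValueError("activity matrix shape mismatch")
        if np.any(A < 0):
            raise ValueError("activity matrix has negative entries")
        self.samples = list(samples)
        self.signatures = list(signatures)
        self.A = A
        self._row = {s: i for i, s in enumerate(samples)}

    def row(self, sample: str) -> np.ndarray:
        return self.A[self._row[sample]]

    def __contains__(self, sample: str) -> bool:
        return sample in self._row


class TranscriptSet:
    """Per-chromosome sorted gene spans with strand, for strand classification."""

    def __init__(self, records: List[Tuple[str, int, int, str, str]]):
        # records: (chrom, start, end, strand, gene_id)
        by_chrom: Dict[str, List[Tuple[int, int, str, str]]] = {}
        for chrom, start, end, strand, gid in records:
            if start >= end:
                raise ValueError(f"transcript {gid}: start >= end")
            if strand not in "+-":
                raise ValueError(f"transcript {gid}: bad strand {strand!r}")
            by_chrom.setdefault(norm_chrom(chrom), []).append((start, end, strand, gid))
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            strands = np.array([1 if r[2] == "+" else -1 for r in recs], dtype=np.int8)
            ids = [r[3] for r in recs]
            self._data[chrom] = (starts, ends, strands, ids)

    def chroms(self) -> List[str]:
        return list(self._data)

    def spans(self, chrom: str):
        chrom = norm_chrom(chrom)
        if chrom not in self._data:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0, dtype=np.int8), []
        return self._data[chrom]

    def strand_codes(self, chrom: str, length: int) -> np.ndarray:
        """Per-base genic code: 0 intergenic, 1 plus-only, 2 minus-only, 3 both."""
        starts, ends, strands, _ = self.spans(chrom)
        plus = np.zeros(length + 1, dtype=np.int32)
        minus = np.zeros(length + 1, dtype=np.int32)
        for s, e, st in zip(starts, ends, strands):
            s = max(0, int(s))
            e = min(length, int(e))
            if s >= e:
                continue
            tgt = plus if st > 0 else minus
            tgt[s] += 1
            tgt[e] -= 1
        code = (np.cumsum(plus)[:-1] > 0).astype(np.int8)
        code |= (np.cumsum(minus)[:-1] > 0).astype(np.int8) << 1
        return code  # 0/1/2/3

    def reverse_strands(self) -> "TranscriptSet":
        recs = []
        for chrom in self.chroms():
            starts, ends, strands, ids = self.spans(chrom)
            for s, e, st, gid in zip(starts, ends, strands, ids):
                recs.append((chrom, int(s), int(e), "-" if st > 0 else "+", gid))
        return TranscriptSet(recs)


@dataclass
class Config:
    """Run parameters. Defaults follow the published analysis settings."""

    n_sims: int = 100
    occupancy_halfwidth_bp: int = 1000
    center_stat_halfwidth_bp: int = 100
    prob_threshold: float = 0.9
    processivity_max_gap_bp: int = 10_000
    strand_region_min_bp: int = 10_000
    termination_trim_bp: int = 25_000
    odds_ratio_threshold: float = 1.10
    alpha: float = 0.05
    n_timing_bins: int = 10
    local_flank_bp: int = 10_000
    rng_seed: int = 0
    # numerical / implementation knobs
    smoothing_step_bp: int = 1000
    smoothing_window_bp: int = 20_000
    wavelet: str = "bior3.5"  # (near-)linear-phase: extrema are not displaced
    wavelet_scale_bp: int = 100_000
    min_peak_prominence: float = 0.0
    min_selected_mutations: int = 100
    match_tx_strand: bool = False
    per_sample_occupancy: bool = False
    processivity_strict_break: bool = False
    processivity_span_bound: bool = False

    def __post_init__(self):
        for name in (
            "occupancy_halfwidth_bp",
            "center_stat_halfwidth_bp",
            "processivity_max_gap_bp",
            "strand_region_min_bp",
            "termination_trim_bp",
            "local_flank_bp",
            "smoothing_step_bp",
            "smoothing_window_bp",
            "wavelet_scale_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.prob_threshold <= 1.0):
            raise ValueError("prob_threshold must be in (0, 1]")
        if self.n_timing_bins < 2:
            raise ValueError("n_timing_bins must be >= 2")
        if self.n_sims <= 0:
            raise ValueError("n_sims must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
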