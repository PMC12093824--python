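"""Context-preserving simulation of somatic mutations.

Each simulated replicate redistributes the real mutations across the genome
(or across user-supplied regions plus their flanks) while preserving, per
chromosome, the number of mutations in every mutational channel: an SBS is
re-placed at a uniformly drawn position sharing its pyrimidine-oriented
trinucleotide context (on either strand), a DBS at a position sharing its
canonical doublet, and an indel at a position that reproduces its ID-83
channel. The resulting replicates are the empirical null for every
downstream statistical comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import classification
from .datamodel import (
    COMPLEMENT,
    GenomeSequence,
    IntervalSignal,
    MutationRecord,
    TranscriptSet,
    revcomp,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"

# transcription classes used when matching simulated placements to the source
TX_INTERGENIC, TX_UNTRANSCRIBED, TX_TRANSCRIBED, TX_BIDIRECTIONAL = 0, 1, 2, 3


def _n_margin_mask(codes: np.ndarray, margin: int = 8) -> np.ndarray:
    """True where a position is at least ``margin`` bp away from any N."""
    ok = np.ones(len(codes), dtype=bool)
    ns = np.flatnonzero(codes == 4)
    if len(ns):
        diff = np.zeros(len(codes) + 1, dtype=np.int32)
        lo = np.maximum(ns - margin, 0)
        hi = np.minimum(ns + margin + 1, len(codes))
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        ok &= np.cumsum(diff)[:-1] == 0
    return ok


def _run_lengths(codes: np.ndarray) -> np.ndarray:
    """Length of the maximal equal-base run containing each position."""
    n = len(codes)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    brk = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [n]])
    lens = ends - starts
    run_id = np.zeros(n, dtype=np.int64)
    run_id[brk] = 1
    run_id = np.cumsum(run_id)
    return lens[run_id]


class ContextIndex:
    """Per-chromosome candidate positions for every mutational context.

    SBS candidates are indexed by pyrimidine-oriented trinucleotide (32 keys),
    DBS by canonical doublet (10 keys), and 1 bp indels lazily by ID-83
    channel. The ``orient`` array flags whether the context reads off the
    plus strand at each candidate. When ``regions`` is given, only positions
    inside the regions or their ``flank_bp`` flanks are indexed.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        regions: Optional[IntervalSignal] = None,
        flank_bp: int = 10_000,
    ):
        self.genome = genome
        self.regions = regions
        self.flank_bp = flank_bp
        self._masks: Dict[str, Optional[np.ndarray]] = {}
        self._sbs: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
        self._dbs: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
        self._id1: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        self._allowed: Dict[str, np.ndarray] = {}
        total = 0
        for chrom in genome.chrom_names:
            self._build_chrom(chrom)
            total += sum(len(p) for p, _ in self._sbs[chrom].values())
        if total == 0:
            raise ValueError("no usable (non-N) genome positions to index")

    def region_mask(self, chrom: str) -> Optional[np.ndarray]:
        if chrom not in self._masks:
            if self.regions is None:
                self._masks[chrom] = None
            else:
                L = self.genome.lengths[chrom]
                mask = np.zeros(L + 1, dtype=np.int32)
                s, e, _ = self.regions.intervals(chrom)
                lo = np.maximum(s - self.flank_bp, 0)
                hi = np.minimum(e + self.flank_bp, L)
                np.add.at(mask, lo, 1)
                np.add.at(mask, hi, -1)
                self._masks[chrom] = np.cumsum(mask)[:-1] > 0
        return self._masks[chrom]

    def _build_chrom(self, chrom: str) -> None:
        c = self.genome.codes(chrom)
        L = len(c)
        self._sbs[chrom] = {}
        self._dbs[chrom] = {}
        if L < 3:
            self._allowed[chrom] = np.zeros(0, dtype=np.int64)
            return
        rmask = self.region_mask(chrom)
        nmask = c < 4

        # --- SBS: interior positions with a clean trinucleotide
        p = np.arange(1, L - 1)
        ok = nmask[:-2] & nmask[1:-1] & nmask[2:]
        if rmask is not None:
            ok &= rmask[1:-1]
        p = p[ok]
        left, mid, right = c[p - 1], c[p], c[p + 1]
        pyr = (mid == 1) | (mid == 3)
        tl = np.where(pyr, left, 3 - right)
        tm = np.where(pyr, mid, 3 - mid)
        tr = np.where(pyr, right, 3 - left)
        key_idx = tl * 16 + tm * 4 + tr
        order = np.argsort(key_idx, kind="stable")
        key_sorted = key_idx[order]
        pos_sorted = p[order]
        orient_sorted = pyr[order]
        bounds = np.searchsorted(key_sorted, np.arange(65))
        for ki in np.unique(key_sorted):
            a, b = bounds[ki], bounds[ki + 1]
            key = _BASES[ki // 16] + _BASES[(ki // 4) % 4] + _BASES[ki % 4]
            self._sbs[chrom][key] = (pos_sorted[a:b], orient_sorted[a:b])

        # --- DBS: positions with a clean doublet
        q = np.arange(0, L - 1)
        okd = nmask[:-1] & nmask[1:]
        if rmask is not None:
            okd &= rmask[:-1]
        q = q[okd]
        d, e = c[q], c[q + 1]
        duo_idx = d * 4 + e
        canon_key = np.empty(16, dtype=np.int64)
        canon_orient = np.empty(16, dtype=bool)
        canonical = list(classification._DBS_CANONICAL)
        canon_pos = {k: i for i, k in enumerate(canonical)}
        for di in range(4):
            for ei in range(4):
                duo = _BASES[di] + _BASES[ei]
                if duo in canon_pos:
                    canon_key[di * 4 + ei] = canon_pos[duo]
                    canon_orient[di * 4 + ei] = True
                else:
                    rc = _BASES[3 - ei] + _BASES[3 - di]
                    canon_key[di * 4 + ei] = canon_pos[rc]
                    canon_orient[di * 4 + ei] = False
        kk = canon_key[duo_idx]
        oo = canon_orient[duo_idx]
        order = np.argsort(kk, kind="stable")
        kk_s, q_s, oo_s = kk[order], q[order], oo[order]
        bounds = np.searchsorted(kk_s, np.arange(11))
        for ki in np.unique(kk_s):
            a, b = bounds[ki], bounds[ki + 1]
            self._dbs[chrom][canonical[ki]] = (q_s[a:b], oo_s[a:b])

        # --- all usable positions (for rejection sampling of long indels)
        allowed = nmask.copy()
        if rmask is not None:
            allowed &= rmask
        self._allowed[chrom] = np.flatnonzero(allowed)

    def sbs(self, chrom: str, tri: str) -> Tuple[np.ndarray, np.ndarray]:
        empty = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool))
        return self._sbs.get(chrom, {}).get(tri, empty)

    def dbs(self, chrom: str, doublet: str) -> Tuple[np.ndarray, np.ndarray]:
        empty = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool))
        return self._dbs.get(chrom, {}).get(doublet, empty)

    def id1(self, chrom: str, channel: str) -> Tuple[np.ndarray, np.ndarray]:
        """Candidate placements for a 1 bp indel channel (lazy, cached)."""
        key = (chrom, channel)
        if key in self._id1:
            return self._id1[key]
        parts = channel.split(":")
        assert parts[0] == "1"
        kind, pyr_base, kbin = parts[1], parts[2], int(parts[3])
        c = self.genome.codes(chrom)
        L = len(c)
        base_code = {"C": 1, "T": 3}[pyr_base]
        comp_code = 3 - base_code
        rmask = self.region_mask(chrom)
        safe = _n_margin_mask(c)
        runlen = _run_lengths(c)
        pos_list, orient_list = [], []
        if kind == "Del":
            for code, orient in ((base_code, True), (comp_code, False)):
                sel = (c == code) & safe
                copies = np.minimum(runlen - 1, 5)
                sel &= copies == kbin
                sel[0] = False  # need an anchor base to the left
                if rmask is not None:
                    sel &= rmask
                pp = np.flatnonzero(sel)
                pos_list.append(pp)
                orient_list.append(np.full(len(pp), orient, dtype=bool))
        else:  # Ins: insertion points p, motif goes in front of position p
            p = np.arange(1, L)
            for code, orient in ((base_code, True), (comp_code, False)):
                copies = np.where(
                    c[p] == code,
                    runlen[p],
                    np.where(c[p - 1] == code, runlen[p - 1], 0),
                )
                sel = np.minimum(copies, 5) == kbin
                sel &= safe[p] & safe[p - 1]
                if rmask is not None:
                    sel &= rmask[p]
                pp = p[sel]
                pos_list.append(pp)
                orient_list.append(np.full(len(pp), orient, dtype=bool))
        pos = np.concatenate(pos_list)
        orient = np.concatenate(orient_list)
        order = np.argsort(pos, kind="stable")
        self._id1[key] = (pos[order], orient[order])
        return self._id1[key]

    def allowed_positions(self, chrom: str) -> np.ndarray:
        return self._allowed.get(chrom, np.zeros(0, dtype=np.int64))


def build_context_index(
    genome: GenomeSequence,
    regions: Optional[IntervalSignal] = None,
    flank_bp: int = 10_000,
) -> ContextIndex:
    return ContextIndex(genome, regions=regions, flank_bp=flank_bp)


@dataclass
class SimulationSet:
    """n context-preserving replicates of a real cohort."""

    replicates: List[List[MutationRecord]]
    fallback_counts: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return len(self.replicates)


def _sampling_key(m: MutationRecord) -> Tuple[str, str]:
    if m.mut_class == "SBS":
        ch = m.channel  # e.g. A[C>T]G
        return "SBS", ch[0] + ch[2] + ch[6]
    if m.mut_class == "DBS":
        return "DBS", m.channel[:2]
    if m.mut_class == "ID":
        if m.channel.startswith("1:"):
            return "ID1", m.channel
        return "IDL", m.channel
    raise ValueError(f"unclassified mutation {m!r}")


def _tx_class(code: int, orient: bool) -> int:
    if code == 0:
        return TX_INTERGENIC
    if code == 3:
        return TX_BIDIRECTIONAL
    if code == 1:  # plus-strand gene: pyrimidine on plus = coding strand
        return TX_UNTRANSCRIBED if orient else TX_TRANSCRIBED
    return TX_TRANSCRIBED if orient else TX_UNTRANSCRIBED


def _make_sbs(src: MutationRecord, pos: int, orient: bool, rep: int) -> MutationRecord:
    ch = src.channel
    ref, alt = ch[2], ch[4]
    if not orient:
        ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    return MutationRecord(
        sample_id=src.sample_id,
        chrom=src.chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        mut_class="SBS",
        channel=ch,
        pyr_on_plus=bool(orient),
        probabilities=src.probabilities,
        origin="simulated",
        replicate_index=rep,
    )


def _make_dbs(src: MutationRecord, pos: int, orient: bool, rep: int) -> MutationRecord:
    ref, alt = src.channel.split(">")
    if not orient:
        ref, alt = revcomp(ref), revcomp(alt)
    return MutationRecord(
        sample_id=src.sample_id,
        chrom=src.chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        mut_class="DBS",
        channel=src.channel,
        pyr_on_plus=bool(orient),
        probabilities=src.probabilities,
        origin="simulated",
        replicate_index=rep,
    )


def _make_id1(
    src: MutationRecord,
    pos: int,
    orient: bool,
    rep: int,
    genome: GenomeSequence,
) -> MutationRecord:
    parts = src.channel.split(":")
    kind, pyr_base = parts[1], parts[2]
    base = pyr_base if orient else pyr_base.translate(COMPLEMENT)
    anchor = genome.fetch(src.chrom, pos - 1, pos)
    if kind == "Del":
        ref, alt = anchor + base, anchor
    else:
        ref, alt = anchor, anchor + base
    return MutationRecord(
        sample_id=src.sample_id,
        chrom=src.chrom,
        pos=int(pos - 1),
        ref=ref,
        alt=alt,
        mut_class="ID",
        channel=src.channel,
        pyr_on_plus=bool(orient),
        probabilities=src.probabilities,
        origin="simulated",
        replicate_index=rep,
    )


def _copy_in_place(src: MutationRecord, rep: int) -> MutationRecord:
    return MutationRecord(
        sample_id=src.sample_id,
        chrom=src.chrom,
        pos=src.pos,
        ref=src.ref,
        alt=src.alt,
        mut_class=src.mut_class,
        channel=src.channel,
        pyr_on_plus=src.pyr_on_plus,
        probabilities=src.probabilities,
        origin="simulated",
        replicate_index=rep,
    )


def simulate(
    mutations: List[MutationRecord],
    index: ContextIndex,
    n: int,
    seed: int,
    match_tx_strand: bool = False,
    transcripts: Optional[TranscriptSet] = None,
) -> SimulationSet:
    """Draw ``n`` context-preserving replicates of the cohort.

    Positions are drawn uniformly from the candidate index of each
    mutation's context on its own chromosome; ref/alt are written in the
    orientation of the sampled site and the source mutation's channel and
    signature probabilities are carried over. Duplicate positions within one
    (sample, replicate, chromosome) are re-drawn up to 10 times. A context
    with no candidates keeps the real position (counted in
    ``fallback_counts``). With ``match_tx_strand`` candidates are further
    restricted to the source mutation's transcription class.

    Replicate r uses an independent stream seeded ``seed + r``, so a fixed
    (cohort, seed, n) always yields an identical SimulationSet.
    """
    if n <= 0:
        raise ValueError("number of replicates must be positive")
    if match_tx_strand and transcripts is None:
        raise ValueError("match_tx_strand requires a TranscriptSet")
    genome = index.genome

    tx_codes: Dict[str, np.ndarray] = {}
    if match_tx_strand:
        for chrom in genome.chrom_names:
            tx_codes[chrom] = transcripts.strand_codes(chrom, genome.lengths[chrom])

    # group source mutation indices by (chrom, kind, key[, tx class]);
    # output replicates preserve the input record order
    groups: Dict[Tuple, List[int]] = {}
    for i, m in enumerate(mutations):
        if not m.channel:
            raise ValueError("all mutations must be classified before simulation")
        kind, key = _sampling_key(m)
        cls = -1
        if match_tx_strand and kind in ("SBS", "DBS", "ID1"):
            cls = _tx_class(int(tx_codes[m.chrom][m.pos]), m.pyr_on_plus)
        groups.setdefault((m.chrom, kind, key, cls), []).append(i)

    # candidate arrays per group, pre-filtered by tx class where requested
    cands: Dict[Tuple, Tuple[np.ndarray, np.ndarray]] = {}
    for gkey in groups:
        chrom, kind, key, cls = gkey
        if kind == "SBS":
            pos, orient = index.sbs(chrom, key)
        elif kind == "DBS":
            pos, orient = index.dbs(chrom, key)
        elif kind == "ID1":
            pos, orient = index.id1(chrom, key)
        else:
            cands[gkey] = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool))
            continue
        if cls >= 0 and len(pos):
            codes = tx_codes[chrom]
            cand_cls = np.fromiter(
                (_tx_class(int(codes[p]), bool(o)) for p, o in zip(pos, orient)),
                dtype=np.int64,
                count=len(pos),
            )
            keep = cand_cls == cls
            pos, orient = pos[keep], orient[keep]
        cands[gkey] = (pos, orient)

    fallback: Counter = Counter()
    replicates: List[List[MutationRecord]] = []
    sorted_groups = sorted(groups.items(), key=lambda kv: repr(kv[0]))
    for rep in range(1, n + 1):
        rng = np.random.default_rng(seed + rep)
        records: List[Optional[MutationRecord]] = [None] * len(mutations)
        record_group: List[Optional[Tuple]] = [None] * len(mutations)
        for gkey, source_idx in sorted_groups:
            chrom, kind, key, _ = gkey
            pos, orient = cands[gkey]
            if kind == "IDL":
                for si in source_idx:
                    src = mutations[si]
                    rec = _rejection_place_indel(src, index, rng, rep)
                    if rec is None:
                        fallback[f"no_candidate:{key}"] += 1
                        rec = _copy_in_place(src, rep)
                    records[si] = rec
                    record_group[si] = gkey
                continue
            if len(pos) == 0:
                for si in source_idx:
                    fallback[f"no_candidate:{key}"] += 1
                    records[si] = _copy_in_place(mutations[si], rep)
                    record_group[si] = gkey
                continue
            draw = rng.integers(0, len(pos), size=len(source_idx))
            for si, i in zip(source_idx, draw):
                src = mutations[si]
                if kind == "SBS":
                    rec = _make_sbs(src, pos[i], orient[i], rep)
                elif kind == "DBS":
                    rec = _make_dbs(src, pos[i], orient[i], rep)
                else:
                    rec = _make_id1(src, pos[i], orient[i], rep, genome)
                records[si] = rec
                record_group[si] = gkey

        _dedup_positions(records, record_group, cands, genome, rng, rep)
        replicates.append(records)
    return SimulationSet(replicates=replicates, fallback_counts=fallback)


def _dedup_positions(records, record_group, cands, genome, rng, rep) -> None:
    """Re-draw duplicate positions within each (sample, chromosome)."""
    seen: Dict[Tuple[str, str], set] = {}
    for k, rec in enumerate(records):
        skey = (rec.sample_id, rec.chrom)
        taken = seen.setdefault(skey, set())
        if rec.pos in taken:
            gkey = record_group[k]
            pos, orient = cands.get(gkey, (np.zeros(0, dtype=np.int64), None))
            kind = gkey[1]
            for _ in range(10):
                if len(pos) == 0:
                    break
                i = int(rng.integers(0, len(pos)))
                if int(pos[i]) in taken or (kind == "ID1" and int(pos[i]) - 1 in taken):
                    continue
                if kind == "SBS":
                    new = _make_sbs(rec, pos[i], orient[i], rep)
                elif kind == "DBS":
                    new = _make_dbs(rec, pos[i], orient[i], rep)
                elif kind == "ID1":
                    new = _make_id1(rec, pos[i], orient[i], rep, genome)
                else:
                    break
                records[k] = new
                rec = new
                break
        taken.add(rec.pos)


def _rejection_place_indel(
    src: MutationRecord, index: ContextIndex, rng, rep: int, tries: int = 200
) -> Optional[MutationRecord]:
    """Place a multi-bp indel by rejection sampling on the target channel.

    Candidate sites are drawn uniformly; the indel (deleting the local
    sequence / inserting the source motif in either orientation) is
    classified in place and accepted when it reproduces the source channel.
    """
    genome = index.genome
    chrom = src.chrom
    allowed = index.allowed_positions(chrom)
    if len(allowed) == 0:
        return None
    kind, motif, _ = classification._indel_parts(src)
    L = len(motif)
    glen = genome.lengths[chrom]
    draws = rng.integers(0, len(allowed), size=tries)
    for di in draws:
        site = int(allowed[di])
        if site < 1 or site + L + 1 >= glen:
            continue
        anchor = genome.fetch(chrom, site - 1, site)
        if kind == "Del":
            deleted = genome.fetch(chrom, site, site + L)
            if "N" in deleted:
                continue
            cand = MutationRecord(
                src.sample_id, chrom, site - 1, anchor + deleted, anchor, "ID"
            )
        else:
            ins = motif if rng.integers(0, 2) == 0 else revcomp(motif)
            cand = MutationRecord(
                src.sample_id, chrom, site - 1, anchor, anchor + ins, "ID"
            )
        try:
            channel = classification.classify_id83(cand, genome)
        except (ValueError, classification.ContextError):
            continue
        if channel == src.channel:
            cand.channel = channel
            cand.probabilities = src.probabilities
            cand.origin = "simulated"
            cand.replicate_index = rep
            cand.pyr_on_plus = True
            return cand
    return None
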