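"""Mutational channel classification.

Assigns every single base substitution, doublet base substitution, and small
indel to its channel in the standard SBS-96, DBS-78, and ID-83 vocabularies,
with the substitution oriented by the pyrimidine base of the reference
Watson-Crick base pair (the canonical-doublet representative for DBS).

Label spellings follow the COSMIC conventions so that outputs interoperate
with published signature matrices:

* SBS-96: ``A[C>T]G`` -- the mutated pyrimidine with its 5' and 3' neighbors.
* DBS-78: ``AC>CA`` -- the canonical doublet representative.
* ID-83:  ``1:Del:C:4`` -- colon-delimited length class (1-5+), Ins/Del,
  C/T (1 bp) or R/M (repeat / microhomology), and a context-size class.
  For deletions the final field counts the repeat copies of the deleted
  motif that remain in the reference (so a 1 bp deletion inside a
  homopolymer of total length k is class ``min(k - 1, 5)``); for insertions
  it counts the pre-existing adjacent copies of the inserted motif; for
  microhomology deletions it is the longest partial flanking homology.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Tuple

from .datamodel import COMPLEMENT, GenomeSequence, MutationRecord, revcomp

PYRIMIDINES = "CT"
PURINES = "AG"


class ContextError(ValueError):
    """Raised when a mutation cannot be classified (N context, bounds, mismatch)."""


# ---------------------------------------------------------------- vocabularies

_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
SBS96_LABELS: List[str] = [
    f"{l}[{sub}]{r}" for sub in _SUBS for l in "ACGT" for r in "ACGT"
]

# canonical reference doublets and their allowed alternate doublets
_DBS_CANONICAL = {
    "AC": ["CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "AT": ["CA", "CC", "CG", "GA", "GC", "TA"],
    "CC": ["AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "CG": ["AT", "GC", "GT", "TA", "TC", "TT"],
    "CT": ["AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"],
    "GC": ["AA", "AG", "AT", "CA", "CG", "TA"],
    "TA": ["AT", "CG", "CT", "GC", "GG", "GT"],
    "TC": ["AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"],
    "TG": ["AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"],
    "TT": ["AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"],
}
DBS78_LABELS: List[str] = [
    f"{ref}>{alt}" for ref, alts in _DBS_CANONICAL.items() for alt in alts
]
_DBS_SET = frozenset(DBS78_LABELS)


def _id83_labels() -> List[str]:
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{k}" for k in range(6)]
    for n in range(2, 6):
        labels += [f"{n}:Del:R:{k}" for k in range(6)]
    for n in range(2, 6):
        labels += [f"{n}:Ins:R:{k}" for k in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{k}" for k in (1, 2)]
    labels += [f"4:Del:M:{k}" for k in (1, 2, 3)]
    labels += [f"5:Del:M:{k}" for k in (1, 2, 3, 4, 5)]
    return labels


ID83_LABELS: List[str] = _id83_labels()
assert len(SBS96_LABELS) == 96 and len(DBS78_LABELS) == 78 and len(ID83_LABELS) == 83


@dataclass(frozen=True)
class ChannelVocabulary:
    mut_class: str
    labels: Tuple[str, ...]

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)


VOCAB = {
    "SBS": ChannelVocabulary("SBS", tuple(SBS96_LABELS)),
    "DBS": ChannelVocabulary("DBS", tuple(DBS78_LABELS)),
    "ID": ChannelVocabulary("ID", tuple(ID83_LABELS)),
}


# ------------------------------------------------------------------------ SBS


def classify_sbs96(m: MutationRecord, genome: GenomeSequence) -> Tuple[str, bool]:
    """SBS-96 channel and pyrimidine-orientation flag for a substitution.

    The channel is the mutated base with its immediate 5' and 3' neighbors;
    purine-reference mutations are reverse-complemented onto the pyrimidine
    representation and flagged ``pyr_on_plus=False``.
    """
    if m.pos < 1 or m.pos + 2 > genome.lengths[m.chrom]:
        raise ContextError(f"{m.chrom}:{m.pos}: trinucleotide context out of bounds")
    tri = genome.fetch(m.chrom, m.pos - 1, m.pos + 2)
    if tri[1] != m.ref:
        raise ValueError(
            f"{m.chrom}:{m.pos}: reference allele {m.ref!r} does not match "
            f"genome base {tri[1]!r}"
        )
    if "N" in tri:
        raise ContextError(f"{m.chrom}:{m.pos}: N in trinucleotide context")
    if m.ref in PYRIMIDINES:
        return f"{tri[0]}[{m.ref}>{m.alt}]{tri[2]}", True
    rtri = revcomp(tri)
    return f"{rtri[0]}[{rtri[1]}>{m.alt.translate(COMPLEMENT)}]{rtri[2]}", False


# ------------------------------------------------------------------------ DBS


def classify_dbs78(m: MutationRecord, genome: GenomeSequence) -> Tuple[str, bool]:
    """DBS-78 channel (canonical doublet representative) and orientation flag."""
    if len(m.ref) != 2 or len(m.alt) != 2:
        raise ValueError("DBS classification requires 2 bp ref and alt")
    if m.ref == m.alt:
        raise ValueError("DBS ref equals alt")
    obs = genome.fetch(m.chrom, m.pos, m.pos + 2)
    if obs != m.ref:
        raise ValueError(
            f"{m.chrom}:{m.pos}: reference doublet {m.ref!r} does not match "
            f"genome {obs!r}"
        )
    if "N" in m.ref or "N" in m.alt:
        raise ContextError(f"{m.chrom}:{m.pos}: N in doublet")
    direct = f"{m.ref}>{m.alt}"
    if direct in _DBS_SET:
        return direct, True
    flipped = f"{revcomp(m.ref)}>{revcomp(m.alt)}"
    if flipped in _DBS_SET:
        return flipped, False
    raise ValueError(f"doublet {direct} not representable in DBS-78")


# ------------------------------------------------------------------------- ID


def _indel_parts(m: MutationRecord) -> Tuple[str, str, int]:
    """Reduce an anchored ref/alt pair to (kind, motif, genomic offset).

    ``kind`` is ``Del`` or ``Ins``; for deletions the offset is the 0-based
    position of the first deleted base, for insertions the insertion point
    (the motif goes in front of that position).
    """
    ref, alt = m.ref, m.alt
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    if len(ref) > len(alt):
        if alt[k:]:
            raise ValueError(f"unsupported complex indel {ref}>{alt}")
        return "Del", ref[k:], m.pos + k
    if len(alt) > len(ref):
        if ref[k:]:
            raise ValueError(f"unsupported complex indel {ref}>{alt}")
        return "Ins", alt[k:], m.pos + k
    raise ValueError(f"not an indel: {ref}>{alt}")


def _count_copies_right(seq: str, start: int, motif: str) -> int:
    n, L = 0, len(motif)
    while seq[start : start + L] == motif:
        n += 1
        start += L
    return n


def _count_copies_left(seq: str, end: int, motif: str) -> int:
    n, L = 0, len(motif)
    while end - L >= 0 and seq[end - L : end] == motif:
        n += 1
        end -= L
    return n


def classify_id83(m: MutationRecord, genome: GenomeSequence) -> str:
    """ID-83 channel of an anchored insertion or deletion.

    1 bp events are typed by the pyrimidine of the affected base and by the
    flanking homopolymer; longer events by the number of flanking repeat
    copies of the motif, falling back to the longest flanking microhomology
    for non-repeat deletions.
    """
    kind, motif, site = _indel_parts(m)
    chrom = m.chrom
    L = len(motif)
    length = genome.lengths[chrom]
    if kind == "Del" and site + L > length:
        raise ContextError(f"{chrom}:{m.pos}: deletion spans chromosome end")
    if site > length:
        raise ContextError(f"{chrom}:{m.pos}: indel beyond chromosome end")
    lo = max(0, site - 6 * L - L)
    hi = min(length, site + 6 * L + 2 * L)
    seq = genome.fetch(chrom, lo, hi)
    off = site - lo
    if kind == "Del":
        obs = seq[off : off + L]
        if obs != motif:
            raise ValueError(
                f"{chrom}:{m.pos}: deleted motif {motif!r} does not match genome {obs!r}"
            )
    if "N" in motif or "N" in seq:
        raise ContextError(f"{chrom}:{m.pos}: N in indel context")

    if kind == "Del":
        copies = _count_copies_right(seq, off + L, motif) + _count_copies_left(
            seq, off, motif
        )
        if L == 1:
            base = motif if motif in PYRIMIDINES else motif.translate(COMPLEMENT)
            return f"1:Del:{base}:{min(copies, 5)}"
        size = min(L, 5)
        if copies >= 1:
            return f"{size}:Del:R:{min(copies, 5)}"
        # microhomology: partial copy of the deleted motif flanking the gap
        right = seq[off + L :]
        h_r = 0
        while h_r < L - 1 and h_r < len(right) and motif[h_r] == right[h_r]:
            h_r += 1
        left = seq[:off]
        h_l = 0
        while h_l < L - 1 and h_l < len(left) and motif[L - 1 - h_l] == left[len(left) - 1 - h_l]:
            h_l += 1
        h = max(h_r, h_l)
        if h == 0:
            return f"{size}:Del:R:0"
        return f"{size}:Del:M:{min(h, 5)}"

    # insertion
    copies = _count_copies_right(seq, off, motif) + _count_copies_left(seq, off, motif)
    if L == 1:
        base = motif if motif in PYRIMIDINES else motif.translate(COMPLEMENT)
        return f"1:Ins:{base}:{min(copies, 5)}"
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


def enumerate_reachable_channels(genome: GenomeSequence, chrom: str | None = None):
    """Channel sets reachable by exhaustive enumeration over one chromosome.

    Tries every substitution, every both-base doublet change, deletions of
    length 1-7, insertions of every local substring (length 1-6), and a
    panel of fixed motifs at every position. On a genome containing the
    necessary repeat structures this reaches the full 96/78/83 universes.
    """
    chrom = chrom or genome.chrom_names[0]
    L = genome.lengths[chrom]
    seq = genome.fetch(chrom, 0, L)
    sbs, dbs, idc = set(), set(), set()
    fixed_ins = ["A", "C", "AG", "CT", "ACG", "TGA", "ACGT", "TTAC", "ACGTA",
                 "TTGCA"]
    for p in range(1, L - 8):
        ref = seq[p]
        for alt in "ACGT":
            if alt != ref:
                ch, _ = classify_sbs96(MutationRecord("s", chrom, p, ref, alt),
                                       genome)
                sbs.add(ch)
        duo = seq[p : p + 2]
        for a0 in "ACGT":
            for a1 in "ACGT":
                if a0 == duo[0] or a1 == duo[1]:
                    continue
                ch, _ = classify_dbs78(
                    MutationRecord("s", chrom, p, duo, a0 + a1, "DBS"), genome
                )
                dbs.add(ch)
        anchor = seq[p - 1]
        for dlen in range(1, 8):
            if p + dlen >= L:
                break
            m = MutationRecord("s", chrom, p - 1, anchor + seq[p : p + dlen],
                               anchor, "ID")
            idc.add(classify_id83(m, genome))
        for ilen in range(1, 7):
            m = MutationRecord("s", chrom, p - 1, anchor,
                               anchor + seq[p : p + ilen], "ID")
            idc.add(classify_id83(m, genome))
    for p in range(1, L - 12, 7):
        anchor = seq[p - 1]
        for motif in fixed_ins:
            m = MutationRecord("s", chrom, p - 1, anchor, anchor + motif, "ID")
            idc.add(classify_id83(m, genome))
    return sbs, dbs, idc


# ------------------------------------------------------------------- cohort


def classify_cohort(
    mutations: List[MutationRecord], genome: GenomeSequence
) -> Tuple[List[MutationRecord], Counter]:
    """Classify every record in place; drop unclassifiable ones.

    Returns the retained records and a QC counter of exclusions (N context,
    out-of-bounds indels) broken down by reason. A reference-allele mismatch
    is a hard error: it indicates the wrong genome build.
    """
    kept: List[MutationRecord] = []
    qc: Counter = Counter()
    for m in mutations:
        try:
            if m.mut_class == "SBS":
                m.channel, m.pyr_on_plus = classify_sbs96(m, genome)
            elif m.mut_class == "DBS":
                m.channel, m.pyr_on_plus = classify_dbs78(m, genome)
            elif m.mut_class == "ID":
                m.channel = classify_id83(m, genome)
                base = m.channel.split(":")
                # orientation only meaningful for 1 bp C/T events
                m.pyr_on_plus = True
                if base[0] == "1":
                    _, motif, _ = _indel_parts(m)
                    m.pyr_on_plus = motif in PYRIMIDINES
            else:
                qc[f"unknown_class:{m.mut_class}"] += 1
                continue
        except ContextError:
            qc["excluded_context"] += 1
            continue
        kept.append(m)
    return kept, qc
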