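"""Fully synthetic genomes, tracks, transcripts, matrices, and cohorts.

Everything the analyses consume can be generated here at desk scale with
planted topographical structure, so every statistical claim the package
makes is testable against a known ground truth without any downloads:

* a random genome at a realistic GC fraction (no N runs);
* a nucleosome-like raised-cosine track (190 bp period), a Repli-seq-like
  long-wavelength wave with analytically known peak/valley positions, and a
  sparse peak feature track;
* tiled protein-coding gene spans of alternating strand;
* a mutation cohort drawn from synthetic signatures with configurable
  planted biases: late-replication enrichment, lagging-strand enrichment
  for one signature, transcribed-strand enrichment, and injected
  same-strand mutation clusters.

Defaults emulate a small whole-genome cohort: two 2 Mb chromosomes, five
samples, 5000 substitutions from two channel-disjoint signatures, plus
small doublet and indel fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classification import SBS96_LABELS, _DBS_CANONICAL
from .datamodel import (
    ActivityMatrix,
    COMPLEMENT,
    GenomeSequence,
    IntervalSignal,
    MutationRecord,
    SignatureProfile,
    TranscriptSet,
)
from .simulation import ContextIndex

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"1": 2_000_000, "2": 2_000_000}
    )
    gc_fraction: float = 0.41
    nucleosome_period_bp: int = 190
    replication_wavelength_bp: int = 200_000
    n_samples: int = 5
    n_mutations: int = 5000
    dbs_fraction: float = 0.03
    id_fraction: float = 0.03
    signature_names: Tuple[str, str] = ("SIG1", "SIG2")
    signature_weights: Tuple[float, float] = (0.5, 0.5)
    late_ratio: float = 1.0  # whole-cohort late-replication placement bias
    lagging_ratio: float = 1.0  # lagging-strand bias, second signature
    tx_ratio: float = 1.0  # transcribed-strand bias, second signature
    clusters: List[Tuple[int, int]] = field(default_factory=list)  # (length, count)
    cluster_gap_bp: Tuple[int, int] = (1000, 5000)
    gene_length_bp: int = 25_000
    gene_gap_bp: int = 25_000

    def __post_init__(self):
        if self.late_ratio <= 0 or self.lagging_ratio <= 0 or self.tx_ratio <= 0:
            raise ValueError("bias ratios must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size < 10 * self.replication_wavelength_bp:
                raise ValueError(
                    f"chromosome {chrom} shorter than 10 replication wavelengths"
                )


# ------------------------------------------------------------------- genome


def make_genome(spec: FixtureSpec) -> GenomeSequence:
    """Reproducible random genome at the requested GC fraction, no Ns."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seqs = {}
    for chrom, size in spec.chrom_sizes.items():
        codes = rng.choice(4, size=size, p=probs).astype(np.uint8)
        seqs[chrom] = codes.tobytes().translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")
        ).decode("ascii")
    return GenomeSequence(seqs)


# ------------------------------------------------------------------- tracks


def _repliseq_value(x: np.ndarray, wavelength: int) -> np.ndarray:
    # high = early; peaks at multiples of the wavelength
    return 50.0 * (1.0 + np.cos(2.0 * np.pi * x / wavelength))


def make_tracks(
    spec: FixtureSpec, genome: GenomeSequence
) -> Tuple[Dict[str, IntervalSignal], Dict[str, Dict[str, List[int]]]]:
    """Nucleosome-like, Repli-seq-like, peak, and constant tracks.

    Returns the tracks and a ground-truth dict with the analytic peak and
    valley positions of the replication wave per chromosome.
    """
    tracks: Dict[str, Dict[str, List[Tuple[int, int, float]]]] = {
        "nucleosome": {},
        "repliseq": {},
        "peaks": {},
        "constant": {},
    }
    truth: Dict[str, Dict[str, List[int]]] = {"peaks": {}, "valleys": {}}
    period = spec.nucleosome_period_bp
    wavelength = spec.replication_wavelength_bp
    for chrom, size in spec.chrom_sizes.items():
        # nucleosome: raised cosine sampled on 10 bp bins
        step = 10
        centers = np.arange(step // 2, size, step)
        nuc = 1.0 + np.cos(2.0 * np.pi * centers / period)
        starts = centers - step // 2
        tracks["nucleosome"][chrom] = list(
            zip(starts.tolist(), (starts + step).tolist(), nuc.tolist())
        )
        # repliseq: long-wavelength wave on 1 kb bins
        step = 1000
        centers = np.arange(step // 2, size, step)
        rep = _repliseq_value(centers.astype(float), wavelength)
        starts = centers - step // 2
        tracks["repliseq"][chrom] = list(
            zip(starts.tolist(), (starts + step).tolist(), rep.tolist())
        )
        truth["peaks"][chrom] = [
            int(k * wavelength) for k in range(0, size // wavelength + 1)
            if 0 < k * wavelength < size
        ]
        truth["valleys"][chrom] = [
            int((k + 0.5) * wavelength)
            for k in range(0, size // wavelength + 1)
            if (k + 0.5) * wavelength < size
        ]
        # sparse feature peaks every 50 kb, width 500 bp
        tracks["peaks"][chrom] = [
            (p, p + 500, 5.0) for p in range(25_000, size - 500, 50_000)
        ]
        tracks["constant"][chrom] = [(0, size, 1.0)]
    signals = {name: IntervalSignal.from_intervals(d) for name, d in tracks.items()}
    return signals, truth


def make_transcripts(spec: FixtureSpec, genome: GenomeSequence) -> TranscriptSet:
    """Tiled protein-coding gene spans with alternating strand."""
    records = []
    i = 0
    for chrom, size in spec.chrom_sizes.items():
        pos = spec.gene_gap_bp
        while pos + spec.gene_length_bp < size:
            strand = "+" if i % 2 == 0 else "-"
            records.append((chrom, pos, pos + spec.gene_length_bp, strand, f"gene{i}"))
            pos += spec.gene_length_bp + spec.gene_gap_bp
            i += 1
    return TranscriptSet(records)


# ---------------------------------------------------------------- signatures


def make_signature_profile(spec: FixtureSpec) -> SignatureProfile:
    """Two channel-disjoint substitution signatures: C>T and T>G uniform."""
    P = np.zeros((96, 2))
    for i, label in enumerate(SBS96_LABELS):
        sub = label[2:5]
        if sub == "C>T":
            P[i, 0] = 1.0 / 16.0
        elif sub == "T>G":
            P[i, 1] = 1.0 / 16.0
    return SignatureProfile(list(SBS96_LABELS), list(spec.signature_names), P)


# -------------------------------------------------------------------- cohort


def _lateness(pos: np.ndarray, wavelength: int) -> np.ndarray:
    """0 at replication initiation zones (early), 1 at termination zones."""
    return (1.0 - np.cos(2.0 * np.pi * pos / wavelength)) / 2.0


def _ascending(pos: np.ndarray, wavelength: int) -> np.ndarray:
    """+1 where the wave rises left-to-right (leading on the reference), else -1."""
    return np.where(np.sin(2.0 * np.pi * pos / wavelength) < 0, 1, -1)


class CohortTruth(dict):
    """Ground-truth labels stored alongside a generated cohort."""


def make_cohort(
    spec: FixtureSpec,
    genome: GenomeSequence,
    transcripts: Optional[TranscriptSet] = None,
    index: Optional[ContextIndex] = None,
) -> Tuple[List[MutationRecord], SignatureProfile, ActivityMatrix, CohortTruth]:
    """Draw a mutation cohort with the configured planted biases.

    Placement probability within a mutation's context candidates is
    proportional to ``1 + (late_ratio - 1) * lateness``; for the second
    signature the weight is additionally multiplied by ``lagging_ratio``
    at placements that orient to the lagging strand and by ``tx_ratio`` at
    placements that orient to the transcribed strand. Clusters are injected
    into the first signature as same-strand C>T runs. Channels and
    probabilities are left unset (the pipeline classifies and attributes).
    """
    rng = np.random.default_rng(spec.seed + 1)
    if index is None:
        index = ContextIndex(genome)
    if transcripts is None:
        transcripts = make_transcripts(spec, genome)
    profile = make_signature_profile(spec)
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    wavelength = spec.replication_wavelength_bp

    tx_codes = {
        chrom: transcripts.strand_codes(chrom, genome.lengths[chrom])
        for chrom in genome.chrom_names
    }

    n_dbs = int(round(spec.n_mutations * spec.dbs_fraction))
    n_id = int(round(spec.n_mutations * spec.id_fraction))
    n_sbs = spec.n_mutations - n_dbs - n_id

    chroms = list(genome.chrom_names)
    chrom_p = np.array([genome.lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    sig_subs = {0: "C>T", 1: "T>G"}
    tri_keys = {
        0: [l + "C" + r for l in _BASES for r in _BASES],
        1: [l + "T" + r for l in _BASES for r in _BASES],
    }

    # cached cumulative placement weights per (signature, chrom, context key)
    wcache: Dict[Tuple[int, str, str], np.ndarray] = {}

    def cum_weights(sig: int, chrom: str, key: str) -> Optional[np.ndarray]:
        k = (sig, chrom, key)
        if k not in wcache:
            pos, orient = index.sbs(chrom, key)
            if len(pos) == 0:
                wcache[k] = None
            else:
                w = 1.0 + (spec.late_ratio - 1.0) * _lateness(
                    pos.astype(float), wavelength
                )
                if sig == 1:
                    if spec.lagging_ratio != 1.0:
                        eff = _ascending(pos.astype(float), wavelength)
                        eff = np.where(orient, eff, -eff)
                        w = np.where(eff < 0, w * spec.lagging_ratio, w)
                    if spec.tx_ratio != 1.0:
                        code = tx_codes[chrom][pos]
                        transcribed = ((code == 1) & ~orient) | ((code == 2) & orient)
                        w = np.where(transcribed, w * spec.tx_ratio, w)
                wcache[k] = np.cumsum(w)
        return wcache[k]

    mutations: List[MutationRecord] = []
    true_sigs: List[str] = []
    act = np.zeros((spec.n_samples, 2))

    def place_sbs(sig: int, sample_idx: int):
        sub = sig_subs[sig]
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        key = tri_keys[sig][rng.integers(0, 16)]
        cw = cum_weights(sig, chrom, key)
        if cw is None:
            return None
        pos_arr, orient_arr = index.sbs(chrom, key)
        j = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
        j = min(j, len(pos_arr) - 1)
        p, o = int(pos_arr[j]), bool(orient_arr[j])
        ref, alt = sub[0], sub[2]
        if not o:
            ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
        m = MutationRecord(samples[sample_idx], chrom, p, ref, alt, "SBS")
        mutations.append(m)
        true_sigs.append(spec.signature_names[sig])
        act[sample_idx, sig] += 1
        return m

    sig_p = np.asarray(spec.signature_weights, dtype=float)
    sig_p /= sig_p.sum()
    for i in range(n_sbs):
        sig = int(rng.choice(2, p=sig_p))
        sample_idx = int(rng.integers(0, spec.n_samples))
        place_sbs(sig, sample_idx)

    # injected same-strand C>T clusters (first signature)
    plus_c: Dict[str, np.ndarray] = {
        chrom: np.flatnonzero(genome.codes(chrom) == 1) for chrom in chroms
    }
    n_injected = 0
    for length, count in spec.clusters:
        for _ in range(count):
            sample_idx = int(rng.integers(0, spec.n_samples))
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            cpos = plus_c[chrom]
            start_j = int(rng.integers(100, len(cpos) - 100))
            run_pos = [int(cpos[start_j])]
            j = start_j
            ok = True
            for _k in range(length - 1):
                gap = int(rng.integers(*spec.cluster_gap_bp))
                j = int(np.searchsorted(cpos, run_pos[-1] + gap))
                if j >= len(cpos) or cpos[j] - run_pos[-1] > 9000:
                    ok = False
                    break
                run_pos.append(int(cpos[j]))
            if not ok:
                continue
            for p in run_pos:
                if p < 1 or p >= genome.lengths[chrom] - 1:
                    continue
                m = MutationRecord(samples[sample_idx], chrom, p, "C", "T", "SBS")
                mutations.append(m)
                true_sigs.append(spec.signature_names[0])
                act[sample_idx, 0] += 1
            n_injected += 1

    # doublets: uniform placement on canonical doublet candidates
    doublets = sorted(_DBS_CANONICAL)
    for i in range(n_dbs):
        sample_idx = int(rng.integers(0, spec.n_samples))
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        duo = doublets[rng.integers(0, len(doublets))]
        pos_arr, orient_arr = index.dbs(chrom, duo)
        if len(pos_arr) == 0:
            continue
        j = int(rng.integers(0, len(pos_arr)))
        p, o = int(pos_arr[j]), bool(orient_arr[j])
        alts = _DBS_CANONICAL[duo]
        alt = alts[rng.integers(0, len(alts))]
        ref = duo
        if not o:
            ref, alt = ref.translate(COMPLEMENT)[::-1], alt.translate(COMPLEMENT)[::-1]
        if p < 1 or p + 2 >= genome.lengths[chrom]:
            continue
        mutations.append(MutationRecord(samples[sample_idx], chrom, p, ref, alt, "DBS"))
        true_sigs.append("")

    # 1 bp indels at uniform positions
    for i in range(n_id):
        sample_idx = int(rng.integers(0, spec.n_samples))
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        p = int(rng.integers(10, genome.lengths[chrom] - 10))
        anchor = genome.fetch(chrom, p - 1, p)
        if rng.integers(0, 2) == 0:  # deletion of the base at p
            base = genome.fetch(chrom, p, p + 1)
            rec = MutationRecord(
                samples[sample_idx], chrom, p - 1, anchor + base, anchor, "ID"
            )
        else:  # insertion of a random base before p
            base = _BASES[rng.integers(0, 4)]
            rec = MutationRecord(
                samples[sample_idx], chrom, p - 1, anchor, anchor + base, "ID"
            )
        mutations.append(rec)
        true_sigs.append("")

    activities = ActivityMatrix(samples, list(spec.signature_names), act)
    truth = CohortTruth(
        true_signatures=true_sigs,
        n_injected_clusters=n_injected,
        spec=dataclasses.asdict(spec),
    )
    return mutations, profile, activities, truth


# ------------------------------------------------------- channel probe genome


def make_channel_probe_genome(seed: int = 0, random_bp: int = 10_000) -> GenomeSequence:
    """A genome engineered so every ID-83 channel is reachable by enumeration.

    Random background plus cassettes: homopolymer runs of every base and
    length 1-7, tandem repeats of motif lengths 2-6 with 2-7 copies, and
    partial-homology (microhomology) constructs for every deletion length.
    """
    rng = np.random.default_rng(seed)

    def junk(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))

    def clean_motif(L: int) -> str:
        # a motif that is not itself periodic (so copy counting is exact)
        while True:
            m = junk(L)
            if all(m[: L - k] != m[k:] for k in range(1, L)):
                return m

    parts = [junk(random_bp)]
    for base in _BASES:
        for run in range(1, 8):
            sep = junk(10).replace(base, "T" if base != "T" else "A")
            parts.append(sep + base * run + sep)
    for L in range(2, 7):
        for copies in range(2, 8):
            m = clean_motif(L)
            parts.append(junk(12) + m * copies + junk(12))
    for L in range(2, 7):
        for h in range(1, min(L, 6)):
            m = clean_motif(L)
            parts.append(junk(12) + m + m[:h] + junk(12))
    return GenomeSequence({"probe": "".join(parts)})


# --------------------------------------------------------------- file output


def write_fixture_files(
    out_dir: str,
    spec: FixtureSpec,
    genome: GenomeSequence,
    tracks: Dict[str, IntervalSignal],
    transcripts: TranscriptSet,
    mutations: Sequence[MutationRecord],
    profile: SignatureProfile,
    activities: ActivityMatrix,
) -> Dict[str, str]:
    """Write the full fixture dataset in the standard on-disk formats."""
    import os

    from . import io as tio

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["genome"] = os.path.join(out_dir, "genome.fa")
    genome.to_fasta(paths["genome"])
    for name, sig in tracks.items():
        p = os.path.join(out_dir, f"{name}.bedgraph")
        with open(p, "w") as fh:
            for chrom, s, e, v in sig.records():
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
        paths[name] = p
    paths["transcripts"] = os.path.join(out_dir, "transcripts.bed")
    tio.write_transcripts_bed(transcripts, paths["transcripts"])
    paths["mutations"] = os.path.join(out_dir, "mutations.txt")
    tio.write_mutations_text(list(mutations), paths["mutations"])
    paths["signatures"] = os.path.join(out_dir, "signatures.tsv")
    paths["activities"] = os.path.join(out_dir, "activities.tsv")
    tio.write_matrices(profile, activities, paths["signatures"], paths["activities"])
    return paths
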