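"""End-to-end orchestration: read, classify, simulate, attribute, analyze.

The pipeline order is fixed: mutations are read and classified, simulated
``n`` times on their context index, probabilistically attributed to
signatures, filtered to high-confidence per-signature sets, and only then
do the topography analyses (occupancy, replication timing, replication
strand, transcription strand, strand-coordinated mutagenesis) run, each
comparing the real cohort to the simulated replicates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import attribution, io, occupancy, processivity, replication, transcription
from .classification import classify_cohort
from .datamodel import Config, GenomeSequence, MutationRecord
from .simulation import ContextIndex, SimulationSet, build_context_index, simulate
from .stattests import finalize_results

log = logging.getLogger(__name__)

ALL_ANALYSES = [
    "occupancy",
    "timing",
    "replication_strand",
    "transcription_strand",
    "processivity",
]


@dataclass
class RunSpec:
    """Resolved inputs for one pipeline run."""

    genome: str
    mutations: str
    signatures: str
    activities: str
    out_dir: str
    mutation_format: str = "text"
    tracks: Dict[str, str] = field(default_factory=dict)  # occupancy feature tracks
    repliseq: Optional[str] = None
    transcripts: Optional[str] = None
    regions: Optional[str] = None  # BED restricting the simulation background
    analyses: List[str] = field(default_factory=lambda: list(ALL_ANALYSES))
    config: Config = field(default_factory=Config)

    @classmethod
    def from_yaml(cls, path: str) -> "RunSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = Config.from_dict(raw.pop("config", {}) or {})
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        tracks = {k: resolve(v) for k, v in (raw.pop("tracks", {}) or {}).items()}
        known = {
            "genome",
            "mutations",
            "signatures",
            "activities",
            "out_dir",
            "mutation_format",
            "repliseq",
            "transcripts",
            "regions",
            "analyses",
        }
        kwargs = {k: v for k, v in raw.items() if k in known}
        for k in ("genome", "mutations", "signatures", "activities", "repliseq",
                  "transcripts", "regions", "out_dir"):
            if k in kwargs:
                kwargs[k] = resolve(kwargs[k])
        return cls(tracks=tracks, config=cfg, **kwargs)


def _sims_cache_path(out_dir: str) -> str:
    return os.path.join(out_dir, "simulations.tsv")


def _write_sims(sims: SimulationSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("replicate\tsample\tchrom\tpos\tref\talt\n")
        for rep_records in sims.replicates:
            for m in rep_records:
                fh.write(
                    f"{m.replicate_index}\t{m.sample_id}\t{m.chrom}\t{m.pos + 1}\t"
                    f"{m.ref}\t{m.alt}\n"
                )


def _load_sims(path: str, genome: GenomeSequence) -> Optional[SimulationSet]:
    reps: Dict[int, List[MutationRecord]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("replicate"):
            return None
        for line in fh:
            rep_s, sample, chrom, pos_s, ref, alt = line.rstrip("\n").split("\t")
            rep = int(rep_s)
            mc = (
                "SBS"
                if len(ref) == len(alt) == 1
                else "DBS"
                if len(ref) == len(alt) == 2
                else "ID"
            )
            reps.setdefault(rep, []).append(
                MutationRecord(
                    sample, chrom, int(pos_s) - 1, ref, alt, mc,
                    origin="simulated", replicate_index=rep,
                )
            )
    if not reps:
        return None
    return SimulationSet(replicates=[reps[k] for k in sorted(reps)])


def run_topography(spec: RunSpec) -> Dict[str, str]:
    """Execute the configured analyses and write TSVs plus a manifest.

    A missing input fails before any computation; a failure inside one
    analysis is recorded in the manifest while the others continue.
    """
    cfg = spec.config
    for required in ("genome", "mutations", "signatures", "activities"):
        p = getattr(spec, required)
        if not p or not os.path.exists(p):
            raise FileNotFoundError(f"required input {required} missing: {p!r}")
    analyses = [a for a in spec.analyses if a in ALL_ANALYSES]

    genome = GenomeSequence.from_fasta(spec.genome)
    mutations = io.read_mutations(spec.mutations, spec.mutation_format, genome)
    mutations, qc = classify_cohort(mutations, genome)
    log.info("classified %d mutations (%s excluded)", len(mutations), dict(qc))
    profile, activities = io.read_matrices(spec.signatures, spec.activities)
    n_unattr = attribution.annotate_probabilities(mutations, profile, activities)

    regions = io.read_signal_track(spec.regions) if spec.regions else None
    transcripts = io.read_transcripts(spec.transcripts) if spec.transcripts else None

    index = build_context_index(genome, regions=regions, flank_bp=cfg.local_flank_bp)

    os.makedirs(spec.out_dir, exist_ok=True)
    cache = _sims_cache_path(spec.out_dir)
    cache_key = (
        f"seed={cfg.rng_seed} n={cfg.n_sims} tx={cfg.match_tx_strand} "
        f"mutations={io.file_checksum(spec.mutations)}"
    )
    key_path = cache + ".key"
    sims = None
    if os.path.exists(cache) and os.path.exists(key_path):
        if open(key_path).read().strip() == cache_key:
            sims = _load_sims(cache, genome)
            if sims is not None and sims.n != cfg.n_sims:
                sims = None
    if sims is None:
        sims = simulate(
            mutations,
            index,
            cfg.n_sims,
            cfg.rng_seed,
            match_tx_strand=cfg.match_tx_strand,
            transcripts=transcripts,
        )
        _write_sims(sims, cache)
        with open(key_path, "w") as fh:
            fh.write(cache_key + "\n")
    for rep in sims.replicates:
        unclassified = [m for m in rep if not m.channel]
        if unclassified:
            classified, _ = classify_cohort(unclassified, genome)
        attribution.annotate_probabilities(
            [m for m in rep if m.channel], profile, activities
        )

    # high-confidence per-signature sets (identical rule for real and sims)
    real_by_sig = attribution.select_high_confidence(
        mutations, profile.signatures, cfg.prob_threshold, cfg.min_selected_mutations
    )
    sims_by_sig = {
        sig: [
            [m for m in rep if m.probabilities.get(sig, 0.0) >= cfg.prob_threshold]
            for rep in sims.replicates
        ]
        for sig in real_by_sig
    }

    tables: Dict[str, pd.DataFrame] = {}
    status: Dict[str, str] = {}

    smoothed = None
    if spec.repliseq and (
        "timing" in analyses or "replication_strand" in analyses
    ):
        repli_track = io.read_signal_track(spec.repliseq)
        smoothed = replication.smooth_signal(
            repli_track,
            step_bp=cfg.smoothing_step_bp,
            window_bp=cfg.smoothing_window_bp,
            wavelet=cfg.wavelet,
            scale_bp=cfg.wavelet_scale_bp,
        )

    for analysis in analyses:
        try:
            if analysis == "occupancy":
                tables["occupancy"] = _run_occupancy(
                    spec, cfg, genome, real_by_sig, sims_by_sig
                )
            elif analysis == "timing":
                if smoothed is None:
                    raise ValueError("timing analysis requires a repliseq track")
                tables["timing"] = _run_timing(cfg, genome, smoothed, real_by_sig,
                                               sims_by_sig)
            elif analysis == "replication_strand":
                if smoothed is None:
                    raise ValueError("strand analysis requires a repliseq track")
                extrema = replication.find_extrema(smoothed, cfg.min_peak_prominence)
                strand_regions = replication.annotate_strand_regions(extrema, cfg)
                tables["replication_strand"] = replication.replication_strand_counts(
                    real_by_sig, sims_by_sig, strand_regions, cfg
                )
            elif analysis == "transcription_strand":
                if transcripts is None:
                    raise ValueError("transcription analysis requires transcripts")
                tables["transcription_strand"] = transcription.transcription_strand_tests(
                    real_by_sig, sims_by_sig, transcripts, cfg
                )
            elif analysis == "processivity":
                tables["processivity"] = _run_processivity(
                    cfg, mutations, sims, real_by_sig
                )
            status[analysis] = "ok"
        except Exception as exc:  # keep other analyses running
            log.exception("analysis %s failed", analysis)
            status[analysis] = f"failed: {exc}"

    checksums = {}
    for key in ("genome", "mutations", "signatures", "activities", "repliseq",
                "transcripts", "regions"):
        p = getattr(spec, key)
        if p and os.path.exists(p):
            checksums[key] = io.file_checksum(p)
    for name, p in spec.tracks.items():
        if os.path.exists(p):
            checksums[f"track:{name}"] = io.file_checksum(p)

    extra = {
        "status": status,
        "qc": dict(qc),
        "n_mutations": len(mutations),
        "n_unattributable": n_unattr,
        "selected_per_signature": {s: len(v) for s, v in real_by_sig.items()},
        "simulation_fallbacks": dict(sims.fallback_counts),
        "id_matching": "channel-level",
    }
    return io.write_results(
        tables, spec.out_dir, cfg.to_dict(), cfg.rng_seed, checksums, extra
    )


def _run_occupancy(spec, cfg, genome, real_by_sig, sims_by_sig) -> pd.DataFrame:
    rows = []
    results = []
    for feature in sorted(spec.tracks):
        track = io.read_signal_track(spec.tracks[feature])
        for sig in sorted(real_by_sig):
            real_prof = occupancy.occupancy_profile(
                real_by_sig[sig], track, cfg.occupancy_halfwidth_bp, genome.lengths
            )
            sim_profs = [
                occupancy.occupancy_profile(
                    rep, track, cfg.occupancy_halfwidth_bp, genome.lengths
                )
                for rep in sims_by_sig[sig]
            ]
            enr = occupancy.occupancy_enrichment(
                real_prof, sim_profs, cfg, signature=sig, feature=feature
            )
            results.append(enr.result)
            rows.append(
                {
                    "signature": sig,
                    "feature": feature,
                    "n_mutations": real_prof.n_mutations,
                    "real_center": enr.real_center,
                    "sim_mean": float(np.mean(enr.sim_centers)),
                    "sim_sd": float(np.std(enr.sim_centers, ddof=1)),
                    "fold_change": enr.fold_change,
                    "z": enr.result.statistic,
                }
            )
    finalize_results(results, cfg.alpha)
    for row, res in zip(rows, results):
        row.update(p=res.p, q=res.q, significant=res.significant,
                   direction=res.direction)
    return pd.DataFrame(
        rows,
        columns=["signature", "feature", "n_mutations", "real_center", "sim_mean",
                 "sim_sd", "fold_change", "z", "p", "q", "significant", "direction"],
    )


def _run_timing(cfg, genome, smoothed, real_by_sig, sims_by_sig) -> pd.DataFrame:
    frames = []
    for sig in sorted(real_by_sig):
        bins = replication.timing_analysis(
            real_by_sig[sig], sims_by_sig[sig], smoothed, genome, cfg.n_timing_bins
        )
        frame = bins.to_frame()
        frame.insert(0, "signature", sig)
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _run_processivity(cfg, mutations, sims, real_by_sig) -> pd.DataFrame:
    threshold = cfg.prob_threshold
    real_assigned = attribution.hard_assignment(
        [m for m in mutations if m.mut_class == "SBS"], threshold
    )
    real_groups = []
    for sig, ms in sorted(real_assigned.items()):
        if sig not in real_by_sig:
            continue
        real_groups += processivity.find_processive_groups(
            ms, cfg.processivity_max_gap_bp, sig,
            span_bound=cfg.processivity_span_bound,
        )
    sim_groups = []
    for rep in sims.replicates:
        assigned = attribution.hard_assignment(
            [m for m in rep if m.mut_class == "SBS"], threshold
        )
        groups = []
        for sig, ms in sorted(assigned.items()):
            if sig not in real_by_sig:
                continue
            groups += processivity.find_processive_groups(
                ms, cfg.processivity_max_gap_bp, sig,
                span_bound=cfg.processivity_span_bound,
            )
        sim_groups.append(groups)
    return processivity.processivity_significance(real_groups, sim_groups, cfg)
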