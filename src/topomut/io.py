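"""Readers and writers for the standard formats the tool touches.

Somatic mutations come in as VCF, MAF, or simple tab-separated text (all
1-based; converted to the internal 0-based convention on read). Signal
tracks come in as BED/bedGraph, wiggle, bigWig, or bigBed. Signature and
activity matrices are tab-separated text with labeled rows and columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    ActivityMatrix,
    GenomeSequence,
    IntervalSignal,
    MutationRecord,
    SignatureProfile,
    TranscriptSet,
    norm_chrom,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def _infer_class(ref: str, alt: str) -> Optional[str]:
    if len(ref) == 1 and len(alt) == 1:
        return "SBS"
    if len(ref) == 2 and len(alt) == 2:
        return "DBS"
    if len(ref) != len(alt):
        return "ID"
    return None  # longer MNVs unsupported


# ---------------------------------------------------------------- mutations


def read_mutations(
    path: str,
    format: str,
    genome: GenomeSequence,
    sample_id: Optional[str] = None,
) -> List[MutationRecord]:
    """Read somatic mutations from VCF, MAF, or simple text.

    Positions are converted from the 1-based file conventions to internal
    0-based coordinates. Records on chromosomes absent from the genome are
    skipped (logged with a counter); unsupported same-length MNVs likewise.
    ``mut_class`` is inferred from allele lengths; channels are left unset.
    """
    fmt = format.lower()
    if fmt == "vcf":
        records = _read_vcf(path, genome, sample_id)
    elif fmt == "maf":
        records = _read_maf(path, genome)
    elif fmt == "text":
        records = _read_text(path, genome)
    else:
        raise ValueError(f"unknown mutation format {format!r}")
    return records


def _skip_or_keep(records, skipped: Dict[str, int], path: str):
    for reason, n in skipped.items():
        if n:
            log.warning("%s: skipped %d records (%s)", path, n, reason)
    return records


def _read_vcf(path, genome, sample_id):
    import pysam

    records: List[MutationRecord] = []
    skipped = {"unknown_chromosome": 0, "unsupported_allele": 0}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        default_sample = (
            sample_id
            or (samples[0] if len(samples) == 1 else None)
            or os.path.splitext(os.path.basename(str(path)))[0]
        )
        for rec in vf:
            chrom = norm_chrom(rec.chrom)
            if chrom not in genome:
                skipped["unknown_chromosome"] += 1
                continue
            if not rec.alts:
                skipped["unsupported_allele"] += 1
                continue
            for alt in rec.alts:
                mc = _infer_class(rec.ref, alt)
                if mc is None or any(ch not in "ACGTN" for ch in rec.ref + alt):
                    skipped["unsupported_allele"] += 1
                    continue
                records.append(
                    MutationRecord(
                        sample_id=default_sample,
                        chrom=chrom,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        mut_class=mc,
                    )
                )
    return _skip_or_keep(records, skipped, path)


_MAF_COLS = {
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "start": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}


def _read_maf(path, genome):
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_COLS.values() if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing MAF columns {missing}")
    records: List[MutationRecord] = []
    skipped = {"unknown_chromosome": 0, "unsupported_allele": 0}
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        chrom = norm_chrom(str(row["Chromosome"]))
        if chrom not in genome:
            skipped["unknown_chromosome"] += 1
            continue
        try:
            start1 = int(row["Start_Position"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {i + 2}: bad Start_Position")
        ref = str(row["Reference_Allele"]).upper()
        alt = str(row["Tumor_Seq_Allele2"]).upper()
        sample = str(row["Tumor_Sample_Barcode"])
        if ref == "-" or alt == "-":
            # MAF unanchored indels: re-anchor on the preceding reference base
            if alt == "-":  # deletion of `ref` starting at start1
                anchor0 = start1 - 2
                if anchor0 < 0:
                    skipped["unsupported_allele"] += 1
                    continue
                base = genome.fetch(chrom, anchor0, anchor0 + 1)
                rec = MutationRecord(sample, chrom, anchor0, base + ref, base, "ID")
            else:  # insertion between start1 and start1+1 (MAF convention)
                anchor0 = start1 - 1
                base = genome.fetch(chrom, anchor0, anchor0 + 1)
                rec = MutationRecord(sample, chrom, anchor0, base, base + alt, "ID")
            records.append(rec)
            continue
        mc = _infer_class(ref, alt)
        if mc is None or any(ch not in "ACGTN" for ch in ref + alt):
            skipped["unsupported_allele"] += 1
            continue
        records.append(MutationRecord(sample, chrom, start1 - 1, ref, alt, mc))
    return _skip_or_keep(records, skipped, path)


def _read_text(path, genome):
    """Simple text: sample, chrom, 1-based pos, ref, alt (anchored, VCF-style)."""
    records: List[MutationRecord] = []
    skipped = {"unknown_chromosome": 0, "unsupported_allele": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample":  # optional header
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            sample, chrom, pos_s, ref, alt = parts[:5]
            chrom = norm_chrom(chrom)
            if chrom not in genome:
                skipped["unknown_chromosome"] += 1
                continue
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad position {pos_s!r}")
            ref, alt = ref.upper(), alt.upper()
            mc = _infer_class(ref, alt)
            if mc is None or any(ch not in "ACGTN" for ch in ref + alt):
                skipped["unsupported_allele"] += 1
                continue
            records.append(MutationRecord(sample, chrom, pos1 - 1, ref, alt, mc))
    return _skip_or_keep(records, skipped, path)


def write_mutations_text(records: List[MutationRecord], path: str) -> None:
    """Write the simple 1-based text dialect (round-trips with read_mutations)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\n")
        for m in records:
            fh.write(f"{m.sample_id}\t{m.chrom}\t{m.pos + 1}\t{m.ref}\t{m.alt}\n")


# ------------------------------------------------------------------- tracks


def read_signal_track(path: str, format: Optional[str] = None) -> IntervalSignal:
    """Load a genomic signal track as a sorted, non-overlapping IntervalSignal.

    Supported formats: bed/bedGraph (value from the score column if numeric,
    else the 4th column if numeric, else 1.0), fixedStep/variableStep wiggle,
    bigWig, and bigBed. Overlapping input intervals are merged by the
    arithmetic mean of their values.
    """
    fmt = format
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower().lstrip(".")
        fmt = {
            "bed": "bed",
            "bedgraph": "bed",
            "bdg": "bed",
            "narrowpeak": "bed",
            "wig": "wig",
            "bigwig": "bigwig",
            "bw": "bigwig",
            "bigbed": "bigbed",
            "bb": "bigbed",
        }.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer track format from {path!r}")
    fmt = fmt.lower()
    if fmt in ("bed", "bedgraph"):
        triples = _read_bed_triples(path)
    elif fmt == "wig":
        triples = _read_wig_triples(path)
    elif fmt in ("bigwig", "bigbed"):
        triples = _read_big_triples(path, fmt)
    else:
        raise ValueError(f"unknown track format {format!r}")
    return IntervalSignal.from_intervals(triples)


def _bed_value(fields: List[str]) -> float:
    # column 5 (score) if numeric, else column 4, else presence/absence
    for idx in (4, 3):
        if len(fields) > idx:
            try:
                return float(fields[idx])
            except ValueError:
                continue
    return 1.0


def _read_bed_triples(path) -> Dict[str, List[Tuple[int, int, float]]]:
    triples: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")
            triples.setdefault(norm_chrom(fields[0]), []).append(
                (start, end, _bed_value(fields))
            )
    return triples


def _read_wig_triples(path) -> Dict[str, List[Tuple[int, int, float]]]:
    triples: Dict[str, List[Tuple[int, int, float]]] = {}
    mode = None
    chrom = ""
    pos = 0
    step = span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode = "fixed"
                chrom = norm_chrom(kv["chrom"])
                pos = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode = "variable"
                chrom = norm_chrom(kv["chrom"])
                span = int(kv.get("span", 1))
                continue
            if mode is None:
                raise ParseError(f"{path}: line {lineno}: data before step header")
            fields = line.split()
            try:
                if mode == "fixed":
                    value = float(fields[0])
                    triples.setdefault(chrom, []).append((pos, pos + span, value))
                    pos += step
                else:
                    p1, value = int(fields[0]), float(fields[1])
                    triples.setdefault(chrom, []).append((p1 - 1, p1 - 1 + span, value))
            except (ValueError, IndexError):
                raise ParseError(f"{path}: line {lineno}: bad wig data line")
    return triples


def _read_big_triples(path, fmt) -> Dict[str, List[Tuple[int, int, float]]]:
    import pyBigWig

    triples: Dict[str, List[Tuple[int, int, float]]] = {}
    bw = pyBigWig.open(str(path))
    try:
        for chrom, length in bw.chroms().items():
            if fmt == "bigwig":
                ivs = bw.intervals(chrom, 0, length) or []
                triples[norm_chrom(chrom)] = [
                    (int(s), int(e), float(v)) for s, e, v in ivs if not np.isnan(v)
                ]
            else:
                entries = bw.entries(chrom, 0, length) or []
                out = []
                for s, e, rest in entries:
                    fields = ["", "", ""] + (rest.split("\t") if rest else [])
                    out.append((int(s), int(e), _bed_value(fields)))
                triples[norm_chrom(chrom)] = out
    finally:
        bw.close()
    return triples


def write_bed(signal: IntervalSignal, path: str, name_prefix: str = "iv") -> None:
    with open(path, "w") as fh:
        i = 0
        for chrom, s, e, v in signal.records():
            fh.write(f"{chrom}\t{s}\t{e}\t{name_prefix}{i}\t{v:.17g}\n")
            i += 1


# ----------------------------------------------------------------- matrices


def read_matrices(sig_path: str, act_path: str) -> Tuple[SignatureProfile, ActivityMatrix]:
    """Read signature-profile and activity matrices (TSV, labeled rows/cols).

    Profile columns must sum to 1 (tolerance 1e-3); activities must be
    non-negative; the two signature label sets must agree.
    """
    sig_df = pd.read_csv(sig_path, sep="\t", index_col=0)
    act_df = pd.read_csv(act_path, sep="\t", index_col=0)
    profile = SignatureProfile(
        list(sig_df.index.astype(str)),
        list(sig_df.columns.astype(str)),
        sig_df.to_numpy(dtype=float),
    )
    activities = ActivityMatrix(
        list(act_df.index.astype(str)),
        list(act_df.columns.astype(str)),
        act_df.to_numpy(dtype=float),
    )
    if set(profile.signatures) != set(activities.signatures):
        raise ValueError(
            "signature labels differ between profile and activity matrices"
        )
    return profile, activities


def write_matrices(
    profile: SignatureProfile, activities: ActivityMatrix, sig_path: str, act_path: str
) -> None:
    pd.DataFrame(profile.P, index=profile.channels, columns=profile.signatures).to_csv(
        sig_path, sep="\t"
    )
    pd.DataFrame(
        activities.A, index=activities.samples, columns=activities.signatures
    ).to_csv(act_path, sep="\t")


# -------------------------------------------------------------- transcripts


def read_transcripts(path: str, format: Optional[str] = None) -> TranscriptSet:
    """Gene spans from BED6 or GTF (``gene`` features; protein_coding when typed)."""
    fmt = format
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower().lstrip(".")
        fmt = "gtf" if ext in ("gtf", "gff") else "bed"
    records: List[Tuple[str, int, int, str, str]] = []
    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 6:
                    raise ParseError(f"{path}: line {lineno}: BED6 required")
                records.append((f[0], int(f[1]), int(f[2]), f[5], f[3]))
    elif fmt == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ParseError(f"{path}: line {lineno}: 9 GTF columns required")
                if f[2] != "gene":
                    continue
                attrs = {}
                for item in f[8].rstrip(";").split(";"):
                    item = item.strip()
                    if " " in item:
                        k, v = item.split(" ", 1)
                        attrs[k] = v.strip().strip('"')
                if attrs.get("gene_biotype", "protein_coding") != "protein_coding":
                    continue
                gid = attrs.get("gene_id", f"gene{lineno}")
                records.append((f[0], int(f[3]) - 1, int(f[4]), f[6], gid))
    else:
        raise ValueError(f"unknown transcript format {format!r}")
    return TranscriptSet(records)


def write_transcripts_bed(tx: TranscriptSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in tx.chroms():
            starts, ends, strands, ids = tx.spans(chrom)
            for s, e, st, gid in zip(starts, ends, strands, ids):
                strand = "+" if st > 0 else "-"
                fh.write(f"{chrom}\t{s}\t{e}\t{gid}\t0\t{strand}\n")


# ------------------------------------------------------------------ results


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str,
    config: Mapping,
    seed: int,
    input_checksums: Optional[Mapping[str, str]] = None,
    extra: Optional[Mapping] = None,
) -> Dict[str, str]:
    """Write one TSV per analysis plus a JSON run manifest.

    Floats are written with repr-level precision so identical runs produce
    byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = path
    manifest = {
        "config": dict(config),
        "rng_seed": int(seed),
        "inputs": dict(input_checksums or {}),
        "analyses": {name: int(len(df)) for name, df in tables.items()},
    }
    if extra:
        manifest.update(extra)
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = mpath
    return paths
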