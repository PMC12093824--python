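"""Strand-coordinated mutagenesis (processivity) analysis.

Within each sample, consecutive single base substitutions that are
attributed to the same signature, share the same reference-strand
substitution (C>T and G>A are kept distinct, so members lie on one strand),
and are separated by no more than 10 kb form a strand-coordinated group.
Group counts per (signature, length) are pooled across samples and compared
to the counts observed in each simulated replicate with an upper-tail
z-test; long groups correspond to kataegis, length-2 groups to omikli-like
events.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import Config, MutationRecord
from .stattests import TestResult, finalize_results, ztest_vs_sims


@dataclass
class ProcessiveGroup:
    sample: str
    signature: str
    subtype: str  # reference-strand ref>alt, e.g. C>A or G>T kept distinct
    chrom: str
    positions: List[int]

    @property
    def length(self) -> int:
        return len(self.positions)


def find_processive_groups(
    mutations: Sequence[MutationRecord],
    max_gap: int,
    signature: str,
    span_bound: bool = False,
    breakpoints: Dict[Tuple[str, str], Sequence[int]] | None = None,
) -> List[ProcessiveGroup]:
    """Maximal same-strand runs within one signature's selected SBS records.

    ``mutations`` is the set of one sample's SBS mutations hard-assigned to
    ``signature``. Adjacency is evaluated in the per-chromosome
    position-sorted order of that set: an interleaved mutation of the same
    signature but a different reference-strand subtype breaks the run
    (mutations of other signatures are not in the set and therefore do
    not). Runs of length 1 are discarded. With ``span_bound`` the 10 kb
    limit applies to the whole group span instead of adjacent gaps. In
    strict mode the caller passes ``breakpoints`` — per (sample, chrom)
    sorted positions of SBS mutations outside this signature's set — and
    any breakpoint strictly between two members also ends the run.
    """
    by_key: Dict[Tuple[str, str], List[MutationRecord]] = defaultdict(list)
    for m in mutations:
        if m.mut_class != "SBS":
            continue
        by_key[(m.sample_id, m.chrom)].append(m)
    groups: List[ProcessiveGroup] = []
    for (sample, chrom), ms in sorted(by_key.items()):
        ms.sort(key=lambda m: m.pos)
        run: List[MutationRecord] = []

        def flush():
            if len(run) >= 2:
                groups.append(
                    ProcessiveGroup(
                        sample=sample,
                        signature=signature,
                        subtype=run[0].ref_strand_subtype,
                        chrom=chrom,
                        positions=[m.pos for m in run],
                    )
                )

        brk = None
        if breakpoints is not None:
            brk = np.asarray(breakpoints.get((sample, chrom), ()), dtype=np.int64)
        for m in ms:
            if run:
                same = m.ref_strand_subtype == run[-1].ref_strand_subtype
                anchor = run[0].pos if span_bound else run[-1].pos
                close = m.pos - anchor <= max_gap
                interrupted = False
                if brk is not None and len(brk):
                    lo = np.searchsorted(brk, run[-1].pos, side="right")
                    hi = np.searchsorted(brk, m.pos, side="left")
                    interrupted = hi > lo
                if same and close and not interrupted:
                    run.append(m)
                    continue
                flush()
            run = [m]
        flush()
    return groups


def count_groups(groups: Sequence[ProcessiveGroup]) -> Counter:
    """(signature, length) -> number of groups, pooled across samples."""
    c: Counter = Counter()
    for g in groups:
        c[(g.signature, g.length)] += 1
    return c


def processivity_significance(
    real_groups: Sequence[ProcessiveGroup],
    sim_groups_per_replicate: Sequence[Sequence[ProcessiveGroup]],
    cfg: Config,
) -> pd.DataFrame:
    """Observed vs simulated group counts per (signature, length).

    The z statistic compares the observed count to the mean and sd of the
    replicate counts (upper tail: the question is whether clustering
    exceeds the context-preserving null); BH runs over all
    (signature, length) cells of the run.
    """
    if len(sim_groups_per_replicate) < 2:
        raise ValueError("processivity significance needs >= 2 replicates")
    real_counts = count_groups(real_groups)
    sim_counts = [count_groups(reps) for reps in sim_groups_per_replicate]
    cells = sorted(
        set(real_counts) | {key for sc in sim_counts for key in sc},
        key=lambda k: (k[0], k[1]),
    )
    rows = []
    results: List[TestResult] = []
    for sig, length in cells:
        observed = real_counts.get((sig, length), 0)
        sims = np.array([sc.get((sig, length), 0) for sc in sim_counts], dtype=float)
        z, p = ztest_vs_sims(float(observed), sims, tail="upper")
        sim_mean = float(sims.mean())
        effect = observed / sim_mean if sim_mean > 0 else float("inf")
        res = TestResult(statistic=z, effect=effect, p=p)
        results.append(res)
        rows.append(
            {
                "signature": sig,
                "group_length": length,
                "observed": observed,
                "sim_mean": sim_mean,
                "sim_sd": float(sims.std(ddof=1)),
                "z": z,
            }
        )
    finalize_results(results, cfg.alpha)
    for row, res in zip(rows, results):
        q = res.q
        row.update(
            p=res.p,
            q=q,
            significant=res.significant,
            minus_log10_q=float(-np.log10(q)) if q > 0 else float("inf"),
        )
    return pd.DataFrame(
        rows,
        columns=[
            "signature",
            "group_length",
            "observed",
            "sim_mean",
            "sim_sd",
            "z",
            "p",
            "q",
            "significant",
            "minus_log10_q",
        ],
    )
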