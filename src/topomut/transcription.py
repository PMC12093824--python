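"""Transcription strand asymmetry and genic/intergenic classification.

Mutations inside the span of a protein-coding gene are oriented by the
pyrimidine base of the reference Watson-Crick base pair: when the
pyrimidine sits on the gene's coding strand the mutation is on the
un-transcribed strand, otherwise on the transcribed (template) strand.
Positions covered by genes on both strands are "bidirectional" (no defined
template strand; excluded from the strand comparison but counted as genic),
and positions outside every gene are intergenic.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .datamodel import Config, MutationRecord, TranscriptSet
from .replication import SBS_SUBTYPES
from .stattests import TestResult, fisher_exact_2x2, finalize_results

TRANSCRIBED = "transcribed"
UNTRANSCRIBED = "untranscribed"
BIDIRECTIONAL = "bidirectional"
INTERGENIC = "intergenic"


def classify_transcription(m: MutationRecord, tx: TranscriptSet) -> str:
    """Transcription class of one mutation (see module docstring)."""
    starts, ends, strands, _ = tx.spans(m.chrom)
    if len(starts) == 0:
        return INTERGENIC
    cache = getattr(tx, "_prefix_max_end", None)
    if cache is None:
        cache = {}
        tx._prefix_max_end = cache
    if m.chrom not in cache:
        cache[m.chrom] = np.maximum.accumulate(ends) if len(ends) else ends
    prefix_max_end = cache[m.chrom]
    hit_plus = hit_minus = False
    i = int(np.searchsorted(starts, m.pos, side="right"))
    for j in range(i - 1, -1, -1):
        # spans are sorted by start but may nest; stop once no earlier span
        # can still reach this position
        if prefix_max_end[j] <= m.pos:
            break
        if ends[j] > m.pos:
            if strands[j] > 0:
                hit_plus = True
            else:
                hit_minus = True
    if hit_plus and hit_minus:
        return BIDIRECTIONAL
    if not (hit_plus or hit_minus):
        return INTERGENIC
    if hit_plus:
        return UNTRANSCRIBED if m.pyr_on_plus else TRANSCRIBED
    return TRANSCRIBED if m.pyr_on_plus else UNTRANSCRIBED


def classify_cohort_transcription(
    mutations: Sequence[MutationRecord], tx: TranscriptSet
) -> List[str]:
    return [classify_transcription(m, tx) for m in mutations]


def _class_counts(muts: Sequence[MutationRecord], tx: TranscriptSet):
    strand = {sub: [0, 0] for sub in SBS_SUBTYPES}  # [transcribed, untranscribed]
    region = {sub: [0, 0] for sub in SBS_SUBTYPES}  # [genic, intergenic]
    for m in muts:
        if m.mut_class != "SBS":
            continue
        cls = classify_transcription(m, tx)
        sub = m.pyr_subtype
        if cls == TRANSCRIBED:
            strand[sub][0] += 1
            region[sub][0] += 1
        elif cls == UNTRANSCRIBED:
            strand[sub][1] += 1
            region[sub][0] += 1
        elif cls == BIDIRECTIONAL:
            region[sub][0] += 1
        else:
            region[sub][1] += 1
    return strand, region


def transcription_strand_tests(
    real_by_sig: Dict[str, Sequence[MutationRecord]],
    sims_by_sig: Dict[str, Sequence[Sequence[MutationRecord]]],
    tx: TranscriptSet,
    cfg: Config,
) -> pd.DataFrame:
    """Transcribed-vs-untranscribed and genic-vs-intergenic asymmetry tests.

    One Fisher's exact test per (signature, subtype, comparison) against the
    per-replicate expectation of the simulated cohort; BH adjustment spans
    both comparisons of the whole run, and significance requires the odds
    ratio to exceed the configured threshold in either direction.
    """
    rows = []
    results: List[TestResult] = []
    for sig in sorted(real_by_sig):
        strand_real, region_real = _class_counts(real_by_sig[sig], tx)
        reps = sims_by_sig.get(sig, [])
        strand_pool = {sub: [0, 0] for sub in SBS_SUBTYPES}
        region_pool = {sub: [0, 0] for sub in SBS_SUBTYPES}
        for rep in reps:
            sr, rr = _class_counts(rep, tx)
            for sub in SBS_SUBTYPES:
                strand_pool[sub][0] += sr[sub][0]
                strand_pool[sub][1] += sr[sub][1]
                region_pool[sub][0] += rr[sub][0]
                region_pool[sub][1] += rr[sub][1]
        nrep = max(len(reps), 1)
        for comparison, real_c, pool in (
            ("transcribed_vs_untranscribed", strand_real, strand_pool),
            ("genic_vs_intergenic", region_real, region_pool),
        ):
            for sub in SBS_SUBTYPES:
                a, b = real_c[sub]
                c = int(round(pool[sub][0] / nrep))
                d = int(round(pool[sub][1] / nrep))
                if a + b == 0 and c + d == 0:
                    continue
                if a + b == 0:
                    continue  # empty class: test skipped
                odds, p = fisher_exact_2x2(a, b, c, d)
                res = TestResult(statistic=odds, effect=odds, p=p)
                results.append(res)
                rows.append(
                    {
                        "signature": sig,
                        "comparison": comparison,
                        "subtype": sub,
                        "real_a": a,
                        "real_b": b,
                        "sim_a": c,
                        "sim_b": d,
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
            "comparison",
            "subtype",
            "real_a",
            "real_b",
            "sim_a",
            "sim_b",
            "odds_ratio",
            "p",
            "q",
            "significant",
            "direction",
        ],
    )
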