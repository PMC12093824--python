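"""Probabilistic attribution of mutations to signatures.

Given a signature-profile matrix P (channel x signature) and an activity
matrix A (sample x signature), the probability that signature s generated a
mutation of channel c in sample m is

    p_s = A[m, s] * P[c, s] / sum_t A[m, t] * P[c, t].

Downstream per-signature analyses only use mutations whose probability for
that signature meets a threshold (0.9 by default), which controls the
false-positive rate of signature-specific topography calls.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional

import numpy as np

from .datamodel import ActivityMatrix, MutationRecord, SignatureProfile

log = logging.getLogger(__name__)


def signature_probabilities(
    sample: str,
    channel: str,
    profile: SignatureProfile,
    activities: ActivityMatrix,
) -> Dict[str, float]:
    """Per-signature probability vector for one (sample, channel) pair.

    A zero denominator (no active signature emits this channel) yields an
    all-zero vector, flagging the mutation as unattributable.
    """
    if sample not in activities:
        raise KeyError(f"unknown sample {sample!r}")
    if channel not in profile:
        raise KeyError(f"unknown channel {channel!r}")
    sig_order = [activities.signatures.index(s) for s in profile.signatures]
    a = activities.row(sample)[sig_order]
    w = a * profile.row(channel)
    total = w.sum()
    if total <= 0:
        return {s: 0.0 for s in profile.signatures}
    return {s: float(x) for s, x in zip(profile.signatures, w / total)}


def annotate_probabilities(
    mutations: List[MutationRecord],
    profile: SignatureProfile,
    activities: ActivityMatrix,
) -> int:
    """Attach probability vectors to every record whose channel is in the profile.

    Returns the number of unattributable mutations (zero vector or channel
    not covered by the profile; the latter keep an empty vector).
    """
    cache: Dict[tuple, Dict[str, float]] = {}
    unattributable = 0
    for m in mutations:
        if m.channel not in profile:
            m.probabilities = {}
            unattributable += 1
            continue
        key = (m.sample_id, m.channel)
        if key not in cache:
            cache[key] = signature_probabilities(
                m.sample_id, m.channel, profile, activities
            )
        m.probabilities = cache[key]
        if not any(v > 0 for v in m.probabilities.values()):
            unattributable += 1
    return unattributable


def select_high_confidence(
    mutations: List[MutationRecord],
    signatures: List[str],
    threshold: float = 0.9,
    min_count: int = 0,
) -> Dict[str, List[MutationRecord]]:
    """Per-signature subsets of mutations passing the probability threshold.

    A mutation enters signature S's set iff p_S >= threshold; the set is
    retained only when non-empty, its mean selected probability also meets
    the threshold (guarding the average-probability reading of the filter),
    and it holds at least ``min_count`` mutations. Simulated mutations carry
    their source's probabilities, so selection is identical across real and
    simulated cohorts.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    out: Dict[str, List[MutationRecord]] = {}
    for sig in signatures:
        sel = [m for m in mutations if m.probabilities.get(sig, 0.0) >= threshold]
        if not sel:
            continue
        mean_p = float(np.mean([m.probabilities[sig] for m in sel]))
        if mean_p < threshold:
            log.info("signature %s dropped: mean selected probability %.3f", sig, mean_p)
            continue
        if len(sel) < min_count:
            log.info(
                "signature %s dropped: %d selected mutations < floor %d",
                sig,
                len(sel),
                min_count,
            )
            continue
        out[sig] = sel
    return out


def hard_assignment(
    mutations: List[MutationRecord], threshold: float = 0.9
) -> Dict[str, List[MutationRecord]]:
    """Assign each mutation to its argmax signature when that passes the threshold.

    Used by the strand-coordinated mutagenesis analysis, which needs one
    signature label per mutation. Ties go to the lexicographically first
    signature for determinism.
    """
    out: Dict[str, List[MutationRecord]] = {}
    for m in mutations:
        if not m.probabilities:
            continue
        best = max(sorted(m.probabilities), key=lambda s: m.probabilities[s])
        if m.probabilities[best] >= threshold:
            out.setdefault(best, []).append(m)
    return out
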