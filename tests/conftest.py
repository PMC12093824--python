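"""Shared fixtures: one synthetic genome bundle reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from topomut import attribution
from topomut import fixtures as fx
from topomut.classification import classify_cohort
from topomut.datamodel import Config, GenomeSequence
from topomut.simulation import ContextIndex


@pytest.fixture(scope="session")
def std_spec() -> fx.FixtureSpec:
    return fx.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def std_genome(std_spec) -> GenomeSequence:
    return fx.make_genome(std_spec)


@pytest.fixture(scope="session")
def std_tracks(std_spec, std_genome):
    return fx.make_tracks(std_spec, std_genome)


@pytest.fixture(scope="session")
def std_transcripts(std_spec, std_genome):
    return fx.make_transcripts(std_spec, std_genome)


@pytest.fixture(scope="session")
def std_index(std_genome) -> ContextIndex:
    return ContextIndex(std_genome)


@pytest.fixture(scope="session")
def probe_genome() -> GenomeSequence:
    return fx.make_channel_probe_genome(seed=0)


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeSequence:
    """A 10 kb single-chromosome random genome for exhaustive checks."""
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    return GenomeSequence({"t": seq})


def build_cohort(spec, genome, transcripts, index, n_sims, seed, min_selected=50):
    """Classify, attribute, simulate, and select a fixture cohort."""
    from topomut.simulation import simulate

    muts, profile, activities, truth = fx.make_cohort(
        spec, genome, transcripts, index
    )
    kept, _qc = classify_cohort(muts, genome)
    attribution.annotate_probabilities(kept, profile, activities)
    sims = simulate(kept, index, n_sims, seed=seed)
    for rep in sims.replicates:
        classify_cohort(rep, genome)
        attribution.annotate_probabilities(rep, profile, activities)
    real_by_sig = attribution.select_high_confidence(
        kept, profile.signatures, 0.9, min_selected
    )
    sims_by_sig = {
        sig: [
            [m for m in rep if m.probabilities.get(sig, 0.0) >= 0.9]
            for rep in sims.replicates
        ]
        for sig in real_by_sig
    }
    return kept, sims, real_by_sig, sims_by_sig, profile, activities, truth


@pytest.fixture(scope="session")
def fixture_config() -> Config:
    return Config(
        n_sims=20,
        rng_seed=1,
        wavelet_scale_bp=25_000,
        min_selected_mutations=50,
    )
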