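"""Shared fixtures: the standard planted-truth simulations.

The full discovery suite (40 expected-pass hairpin loci plus 10 loci per
violated criterion) and the degradome suite (30 true cleavage sites plus
10 sub-threshold controls) are simulated once per session and shared by
the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wheatmir.config import PipelineConfig
from wheatmir.discovery import call_mirna_loci
from wheatmir.preprocess import preprocess_reads
from wheatmir import degradome, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def standard_sim(config):
    """Full simulation: genome, truth, decoys, per-library tag counts."""
    sim = synthetic.SimulationSpec(seed=7)
    genome, truths, decoys, libraries = synthetic.simulate(sim, None, config)
    return sim, genome, truths, decoys, libraries


@pytest.fixture(scope="session")
def standard_tags(standard_sim, config):
    """Tags recovered by running raw reads through preprocessing."""
    sim, genome, truths, decoys, libraries = standard_sim
    raw = {lib: synthetic.raw_reads_from_counts(c, sim.adapter, sim.read_len)
           for lib, c in libraries.items()}
    tags, logs = preprocess_reads(raw, sim.adapter)
    return tags, logs


@pytest.fixture(scope="session")
def standard_candidates(standard_sim, standard_tags, config):
    sim, genome, truths, decoys, _ = standard_sim
    tags, _ = standard_tags
    return call_mirna_loci(tags, genome, config, decoys)


@pytest.fixture(scope="session")
def degradome_suite(config):
    """Transcripts, miRNAs, reads, truths, profiles and called events."""
    rng = np.random.default_rng(5)
    specs = synthetic.default_degradome_specs()
    transcripts, mirnas, reads, truths = synthetic.simulate_degradome_truth(
        specs, rng)
    profiles = {tid: degradome.build_degradome_profile(reads, seq)
                for tid, seq in transcripts.items()}
    alignments = []
    for mir_id, mir_seq in sorted(mirnas.items()):
        for tx_id, tx_seq in sorted(transcripts.items()):
            alignments.extend(degradome.score_target_alignment(
                mir_seq, tx_seq, config, mirna_id=mir_id, transcript_id=tx_id))
    events = degradome.call_cleavage_events(alignments, profiles, config)
    for tx_id, tx_seq in transcripts.items():
        evs = [ev for ev in events if ev.transcript_id == tx_id]
        degradome.find_orfs_and_classify_region(tx_seq, evs, config)
    return transcripts, mirnas, reads, truths, profiles, events


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
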