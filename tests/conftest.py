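"""Shared fixtures: toy genomes with planted motifs and scored cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from svfold import ToyPredictor, ToyPredictorParams, score_variant
from svfold.disruption import results_to_frame
from svfold.synthetic import SimulationConfig, simulate_study

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


@pytest.fixture(scope="session")
def params() -> ToyPredictorParams:
    return ToyPredictorParams()


@pytest.fixture(scope="session")
def predictor(params) -> ToyPredictor:
    return ToyPredictor(params)


@pytest.fixture(scope="session")
def toy_genome(params):
    """One 2.4 Mb contig: boundary motif at center, convergent anchors around.

    Layout (positions from contig start):
      1,100,000  anchor (forward)
      1,200,000  boundary motif
      1,300,000  anchor (reverse complement)
    """
    rng = np.random.default_rng(42)
    n = 2_400_000
    seq = list(random_seq(rng, n))
    from svfold.predictor import revcomp
    from svfold.synthetic import _scrub_motifs

    _scrub_motifs(seq, params)
    seq[1_100_000 : 1_100_000 + 12] = params.anchor_motif
    seq[1_200_000 : 1_200_000 + 12] = params.boundary_motif
    seq[1_300_000 : 1_300_000 + 12] = revcomp(params.anchor_motif)
    return {"chr1": "".join(seq)}


@pytest.fixture(scope="session")
def two_contig_genome(params):
    """Two motif-free 2.2 Mb contigs for breakend fusion tests."""
    rng = np.random.default_rng(7)
    seqs = {}
    from svfold.synthetic import _scrub_motifs

    for name in ("chrA", "chrB"):
        seq = list(random_seq(rng, 2_200_000))
        _scrub_motifs(seq, params)
        seqs[name] = "".join(seq)
    return seqs


# ---------------------------------------------------------------------------
# scored synthetic cohorts, cached per seed (scoring a full cohort is the
# expensive step; several tests share the same seeds)

_SCORED_CACHE: dict[int, tuple] = {}


def scored_cohort(seed: int):
    """(study, scored-variants frame) for the default study at ``seed``."""
    if seed not in _SCORED_CACHE:
        config = SimulationConfig(seed=seed)
        study = simulate_study(config)
        pred = ToyPredictor(config.predictor_params)
        results = [
            score_variant(sv, study.genome.contigs, pred, compute_tracks=False)
            for sv in study.svs
        ]
        _SCORED_CACHE[seed] = (study, results_to_frame(results, study.svs))
    return _SCORED_CACHE[seed]


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study for structural (non-statistical) checks."""
    return simulate_study(
        SimulationConfig(
            seed=11,
            samples_per_type=2,
            svs_per_sample_mean=6.0,
            carriers_per_bin=3,
            n_enhancer_drivers=2,
        )
    )
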