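"""Shared fixtures: small reusable genomes and the heavy headline runs."""

from __future__ import annotations

import importlib.util
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")

from surrosim.founder_genomes import generate_base_haplotypes
from surrosim.nucleus_engine import NucleusConfig, run_nucleus
from surrosim.trait_architecture import sample_architecture


def _load_acceptance_module():
    path = Path(__file__).resolve().parent.parent / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("acceptance_script", path)
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    return module


@pytest.fixture(scope="session")
def headline():
    """The acceptance script's computation helpers, loaded as a module."""
    return _load_acceptance_module()


# ---------------------------------------------------------------------------
# light genomes
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def tiny_panel():
    """2 chromosomes x 30 loci, 40 haplotypes: fast structural checks."""
    return generate_base_haplotypes(
        n_haplotypes=40, n_chromosomes=2, loci_per_chromosome=30, seed=101
    )


@pytest.fixture(scope="session")
def tiny_arch(tiny_panel):
    return sample_architecture(tiny_panel, 20, np.random.default_rng(102))


@pytest.fixture(scope="session")
def desk_panel():
    """The study's desk-scale genome: 10 chromosomes x 200 loci."""
    return generate_base_haplotypes(loci_per_chromosome=200, seed=7)


@pytest.fixture(scope="session")
def desk_arch(desk_panel):
    return sample_architecture(desk_panel, 200, np.random.default_rng(8))


@pytest.fixture(scope="session")
def small_run(desk_panel, desk_arch):
    """One small-nucleus trajectory at genomic accuracy 0.5."""
    return run_nucleus(NucleusConfig.small(0.5), desk_panel, desk_arch, seed=9)


# ---------------------------------------------------------------------------
# heavy headline conditions (shared across acceptance and metrics tests)
# ---------------------------------------------------------------------------

ROOT_SEED = 1


@pytest.fixture(scope="session")
def small_lo(headline):
    """100 paired replicates: small nucleus, genomic accuracy 0.5."""
    return headline.run_condition(
        ROOT_SEED,
        0,
        1000,
        0.5,
        [headline.CONV50, headline.CONV500, headline.SS2_BEST, headline.SS3_BEST],
        n_replicates=100,
        keep_trajectories=True,
    )


@pytest.fixture(scope="session")
def big_lo(headline):
    """20 paired replicates: big nucleus, genomic accuracy 0.5."""
    return headline.run_condition(
        ROOT_SEED,
        1,
        5000,
        0.5,
        [headline.CONV50, headline.SS2_BEST, headline.SS3_BEST],
        n_replicates=20,
    )


@pytest.fixture(scope="session")
def small_hi(headline):
    """20 paired replicates: small nucleus, genomic accuracy 0.7."""
    return headline.run_condition(
        ROOT_SEED,
        2,
        1000,
        0.7,
        [headline.CONV50, headline.SS3_BEST, headline.SS3_BEST_HIGH_ACC],
        n_replicates=20,
    )
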