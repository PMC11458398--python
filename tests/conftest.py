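"""Shared fixtures: one session-scoped synthetic genome bundle with the
full planted duplication plan, plus its derived homolog/block structures
(expensive to compute, reused across tests)."""

from __future__ import annotations

import pytest

from famsurveyor.duplication import collinear_blocks, homolog_pairs
from famsurveyor.identify import select_longest_isoform
from famsurveyor.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def genome_bundle(default_config):
    return generate_genome(default_config)


@pytest.fixture(scope="session")
def representative_proteome(genome_bundle):
    return select_longest_isoform(genome_bundle.annotation)


@pytest.fixture(scope="session")
def genome_anchors(representative_proteome):
    return homolog_pairs(representative_proteome)


@pytest.fixture(scope="session")
def genome_blocks(genome_anchors, genome_bundle):
    return collinear_blocks(genome_anchors, genome_bundle.annotation)
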