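"""Shared fixtures: archetypes and generated datasets are expensive, so they
are built once per session and shared read-only across tests."""

from __future__ import annotations

import numpy as np
import pytest

from hsp70census.classifier import classify_all
from hsp70census.simulate import CLASSES, GeneratorConfig, build_archetypes, generate


@pytest.fixture(scope="session")
def archetypes():
    return build_archetypes(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact genome: 10 instances/class (43 Type II to fill the planted
    12/7/5 supercluster, its duplicated copy and the shuffled-flank control)."""
    cfg = GeneratorConfig(
        counts={**{c: 10 for c in CLASSES}, "T1_II": 43}, seed=5
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """The study conditions: 100 instances per class at 5 % substitution."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def study_calls(study_dataset):
    ds = study_dataset
    locus = {g.protein_id: g.gene_id for g in ds.genes}
    calls, counts = classify_all(
        ds.proteins, ds.archetypes.panel, ds.archetypes.blocks, locus_of=locus
    )
    return calls, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
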