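"""Shared fixtures: synthetic scenarios and pre-compiled core groups.

Session scope keeps the expensive artefacts (scenario generation, core-group
compilation) shared across test modules.
"""

from __future__ import annotations

import pytest

from orthotrace.core_compile import CompileOptions, compile_core_group
from orthotrace.synthdata import ScenarioSpec, generate


@pytest.fixture(scope="session")
def default_fixture():
    """The standard 16-taxon / 20-family scenario."""
    return generate(ScenarioSpec(rng_seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A lighter scenario for structural tests (6 families, fewer decoys)."""
    return generate(ScenarioSpec(n_families=6, n_decoys=3, rng_seed=2))


@pytest.fixture(scope="session")
def compile_options():
    return CompileOptions(rng_seed=7)


@pytest.fixture(scope="session")
def compiled_group(default_fixture, compile_options):
    """Core group for the first plain-family seed of the default scenario."""
    fixture = default_fixture
    seed_id = sorted(fixture.seeds)[0]
    group, log = compile_core_group(
        fixture.seeds[seed_id],
        fixture.proteomes,
        fixture.tree,
        fixture.architectures,
        compile_options,
    )
    return group, log
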