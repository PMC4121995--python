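"""Shared fixtures: one small synthetic dataset per test session."""

from __future__ import annotations

import pytest

from srnapipe.synthdata import (
    SimulationConfig,
    build_references,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        genome_length=60_000,
        n_known_mirna=20,
        n_novel_hairpin=6,
        n_de=6,
        library_depth=20_000,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return build_references(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_refs, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    control, knockdown, manifest = simulate_libraries(
        small_config, small_refs, outdir
    )
    refdir = tmp_path_factory.mktemp("refs")
    paths = small_refs.write(refdir)
    return {
        "config": small_config,
        "refs": small_refs,
        "ref_paths": paths,
        "control": control,
        "knockdown": knockdown,
        "manifest": manifest,
    }
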