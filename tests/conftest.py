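"""Shared fixtures: synthetic worlds and (expensive) full pipeline runs."""

from __future__ import annotations

import pytest

from plasphage import synth
from plasphage.pipeline import run_pipeline

#: scaled-down generator used where only structure matters (speed)
SMALL_SPEC = dict(
    seed=7,
    n_genomes=12,
    state_mix={
        "putative_active_plasmid_prophage": 4,
        "putative_degenerated_plasmid_prophage": 2,
        "putative_virulent_phage": 1,
        "non_phage_plasmid": 5,
    },
    n_groups=1,
    group_size=3,
    duplicate_pairs=1,
    decoy_pairs=1,
    genome_length_range=(15_000, 30_000),
    cargo_per_group=10,
    cargo_per_singleton=10,
    cargo_per_nonphage=5,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The stated synthetic world at its default parameters."""
    return synth.generate(synth.GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic world (reused widely)."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline({"seed": 1, "out": str(out), "synthetic": {}})


@pytest.fixture(scope="session")
def small_dataset():
    return synth.generate(synth.GeneratorSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    return run_pipeline({"seed": 7, "out": str(out),
                         "synthetic": dict(SMALL_SPEC)})
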