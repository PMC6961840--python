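from pathlib import Path

import pytest

from junctiondb.fixtures import FixtureBundle, generate_fixture, mybpc3_worked_example
from junctiondb.pipeline import RunConfig, run_pipeline

DEFAULT_SEED = 7
DEFAULT_N_LOCI = 14


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> FixtureBundle:
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture(DEFAULT_N_LOCI, DEFAULT_SEED, out)


@pytest.fixture(scope="session")
def mybpc3_bundle(tmp_path_factory) -> FixtureBundle:
    out = tmp_path_factory.mktemp("mybpc3")
    return mybpc3_worked_example(out, seed=1)


def make_run_config(bundle: FixtureBundle, out_dir: Path, **overrides) -> RunConfig:
    kwargs = dict(
        rmats_dir=bundle.rmats_dir,
        genome=bundle.genome_path,
        gtf=bundle.gtf_path,
        canonical=bundle.proteome_path,
        out_dir=out_dir,
        manual_theta=4,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """One pipeline execution on the default bundle, shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    summary = run_pipeline(make_run_config(default_bundle, out, include_decoys=True))
    return summary, out
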