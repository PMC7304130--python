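import json
from pathlib import Path

import pytest

from mirprio.pipeline import PipelineConfig, run_pipeline
from mirprio.synthetic_data import FixtureSpec, write_fixture_dir


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def fixture_dir(default_spec, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("fixture")
    write_fixture_dir(default_spec, d)
    return d


@pytest.fixture(scope="session")
def pipeline_outdir(fixture_dir, tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        predicted=fixture_dir / "predicted.tsv",
        validated=fixture_dir / "validated.tsv",
        edges=fixture_dir / "edges.tsv",
        pathways=fixture_dir / "pathways.gmt",
        out=out,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def truth(fixture_dir) -> dict:
    return json.loads((fixture_dir / "truth.json").read_text())
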