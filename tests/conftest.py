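import json

import pytest

from cnvcurate import fixtures_synthetic as fx
from cnvcurate.acmg_engine import Rubric
from cnvcurate.annotation_resources import load_resources


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    return fx.generate_resource_bundle(tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def resources(bundle_dir):
    return load_resources(bundle_dir)


@pytest.fixture(scope="session")
def bundle_answers(bundle_dir):
    return json.loads((bundle_dir / "answers.json").read_text())


@pytest.fixture(scope="session")
def rubric():
    return Rubric.load()


@pytest.fixture(scope="session")
def caller_fixture(tmp_path_factory):
    """(paths by caller, expected record dicts) for the filter fixtures."""
    out = tmp_path_factory.mktemp("callers")
    return fx.generate_caller_vcfs(out, seed=7)
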