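import warnings

import pytest

from lcenet.pipeline import run_all
from lcenet.simulate import make_fixture


@pytest.fixture(scope="session")
def fixture_study():
    """The canonical seed-7 synthetic study with planted ground truth."""
    return make_fixture(seed=7)


@pytest.fixture(scope="session")
def pipeline_result(fixture_study):
    """Full pipeline run on the canonical fixture (computed once)."""
    fx = fixture_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(fx.catalog, fx.study, fx.survival, fx.tag_genes)
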