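import pytest

from fpfundflow import run_pipeline, synthetic


@pytest.fixture(scope="session")
def indonesia2019():
    """The packaged Indonesia-2019 scenario (published tables verbatim)."""
    return synthetic.in_paper_fixture()


@pytest.fixture(scope="session")
def indonesia_report(indonesia2019):
    return run_pipeline(indonesia2019)
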