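import pytest

from mpaimpact import fixtures


@pytest.fixture(scope="session")
def bundle():
    """Shared synthetic parameter bundle for the benchmark cases."""
    return fixtures.case_parameter_bundle()


@pytest.fixture(scope="session")
def case_results(bundle):
    """Evaluated impact results for all four benchmark cases."""
    from mpaimpact import decision

    return {
        cid: decision.evaluate_project(fixtures.case_components(cid), bundle)
        for cid in fixtures.CASE_IDS
    }
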