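import pytest

from epilogic import eggshell


@pytest.fixture(scope="session")
def mech_model():
    return eggshell.mechanistic_model()


@pytest.fixture(scope="session")
def phenom_model():
    return eggshell.phenomenological_model()


@pytest.fixture(scope="session")
def fates():
    return eggshell.fate_table()


@pytest.fixture(scope="session")
def wt():
    """Wild-type mechanistic run on the default grid (shared: it is the
    reference configuration for most pattern and reachability checks)."""
    return eggshell.run_scenario("WT")


@pytest.fixture(scope="session")
def wt_report(wt, fates):
    return eggshell.region_reachability_report(wt.epi_pre, fates, phase="pre")


def run_cached(cache={}):
    """Scenario runner memoized across tests within a session."""

    def _run(name):
        if name not in cache:
            cache[name] = eggshell.run_scenario(name)
        return cache[name]

    return _run


@pytest.fixture(scope="session")
def scenario():
    return run_cached()
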