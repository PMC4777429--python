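import numpy as np
import pytest

from pollinet.pipeline import RunConfig, run_all


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study conditions, shared by
    the tests that assert on its artifacts."""
    return run_all(RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160303)


@pytest.fixture()
def census_csv(tmp_path):
    path = tmp_path / "census.csv"
    path.write_text(
        "community,date,plant,duration_min,flowers_observed,visitor,individuals,flowers_contacted\n"
        "SB,2010-04-05,Cistus,3,20,Apis,2,6\n"
        "SB,2010-04-05,Lotus,3,15,NONE,0,0\n"
        "SB,2010-05-03,Cistus,3,18,Bombus,1,4\n"
    )
    return path


@pytest.fixture()
def surveys_csv(tmp_path):
    path = tmp_path / "surveys.csv"
    path.write_text(
        "community,date,plant,open_flowers,area_m2\n"
        "SB,2010-04-07,Cistus,1,0.5\n"
        "SB,2010-04-07,Lotus,10,0.25\n"
        "SB,2010-05-07,Cistus,40,0.25\n"
    )
    return path


@pytest.fixture()
def taxonomy_csv(tmp_path):
    path = tmp_path / "taxonomy.csv"
    path.write_text(
        "name,guild,group\n"
        "Cistus,plant,Cistaceae\n"
        "Lotus,plant,Fabaceae\n"
        "Apis,visitor,large bees\n"
        "Bombus,visitor,large bees\n"
    )
    return path
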