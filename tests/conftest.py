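import pandas as pd
import pytest

import sirsfluids as sf


@pytest.fixture(scope="session")
def vocab():
    return sf.load_vocab()


@pytest.fixture(scope="session")
def boundary():
    return sf.boundary_bundle()


@pytest.fixture(scope="session")
def small_sim():
    """Default-scenario bundle at modest n for structural tests."""
    cfg = sf.default_config(n_patients=2000, seed=11)
    bundle, truth = sf.simulate_bundle(cfg)
    return bundle, truth


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture
def mk_labs():
    """Build a labs frame from (encounter_id, analyte, value, specimen, when)."""
    def _mk(rows):
        return pd.DataFrame(
            [{"encounter_id": r[0], "analyte": r[1], "value": float(r[2]),
              "unit": "", "specimen": r[3], "datetime": pd.Timestamp(r[4])}
             for r in rows])
    return _mk


@pytest.fixture
def mk_vitals():
    def _mk(rows):
        return pd.DataFrame(
            [{"encounter_id": r[0], "vital": r[1], "value": float(r[2]),
              "datetime": pd.Timestamp(r[3])} for r in rows])
    return _mk


@pytest.fixture
def mk_meds():
    def _mk(rows):
        return pd.DataFrame(
            [{"encounter_id": r[0], "drug": r[1], "route": r[2],
              "datetime": pd.Timestamp(r[3])} for r in rows])
    return _mk


@pytest.fixture
def one_sirs():
    """A single-encounter SIRS frame qualifying on 2012-03-02."""
    return pd.DataFrame([{"encounter_id": "E1",
                          "qualification_date": pd.Timestamp("2012-03-02"),
                          "tachycardia": True, "temperature": True,
                          "respiratory": False, "leukocyte": False}])
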