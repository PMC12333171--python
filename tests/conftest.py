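import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_profiles():
    from mscpotency import load_table1_fixture
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_by_name(table1_profiles):
    return {p.protein: p for p in table1_profiles}


@pytest.fixture()
def wide_npx_files(tmp_path):
    """A tiny wide-layout NPX CSV (with decimal commas) plus its design."""
    npx = tmp_path / "npx.csv"
    npx.write_text("protein,s1,s2,s3\nEGF,\"5,08\",4.9,5.2\nIL6,1.3,1.1,1.2\n")
    design = tmp_path / "design.csv"
    design.write_text("sample,condition\ns1,Medium\ns2,Medium\ns3,Medium\n")
    return npx, design


@pytest.fixture()
def long_npx_files(tmp_path):
    npx = tmp_path / "long.csv"
    npx.write_text(
        "sample,protein,npx,lod\n"
        "s1,EGF,5.08,1.0\n"
        "s2,EGF,0.5,1.0\n"
        "s1,IL6,2.0,\n"
        "s2,IL6,2.5,\n")
    design = tmp_path / "design.csv"
    design.write_text("sample,condition\ns1,Medium\ns2,PBMC\n")
    return npx, design


def make_matrix(values: dict, design: dict):
    """Build an NPXMatrix from {protein: {sample: value}} and {sample: cond}."""
    from mscpotency import NPXMatrix
    frame = pd.DataFrame(values).T
    return NPXMatrix(values=frame, design=pd.Series(design))
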