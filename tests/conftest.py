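import numpy as np
import pytest

import algiscore as a


@pytest.fixture(scope="session")
def small_panel():
    return a.fixture_smiles_set("small_panel")


@pytest.fixture(scope="session")
def synthetic_profile():
    """Profile fitted once per session on the default positive condition."""
    pos = a.simulate_descriptor_set(a.SimulationSpec(n=500, seed=11, mode="positive"))
    return a.fit_profile_from_descriptors(pos, provenance="synthetic n=500 seed=11"), pos


@pytest.fixture()
def smi_file(tmp_path):
    p = tmp_path / "mols.smi"
    p.write_text(
        "# comment line\n"
        "CCO ethanol\n"
        "c1ccccc1 benzene\n"
        "not_a_smiles broken\n"
        "CC(=O)O acetic_acid\n"
    )
    return p


@pytest.fixture()
def csv_file(tmp_path):
    p = tmp_path / "mols.csv"
    p.write_text(
        "id,SMILES,extra\n"
        "m1,CCO,x\n"
        "m2,xyz(((,y\n"
        "m3,c1ccccc1,z\n"
    )
    return p
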