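"""Shared fixtures: a hand-built toy region and a cached simulated dataset."""

import pytest

import cpgflank as cf

# 30 nt toy reference, designed by hand:
#   CpG sites at 5 and 20; one CCAGG (Dcm) at 10-14 with internal C at 11
#   (bottom-strand internal C opposite the G at 13); eligible non-CpG,
#   non-Dcm cytosines on the top strand at 3, 10 and 24.
TOY_SEQ = "ATACTCGTAT" + "CCAGGA" + "ATTA" + "CGTAC" + "ATGGA"


@pytest.fixture(scope="session")
def toy_region():
    return cf.ReferenceRegion.from_sequence("toy", TOY_SEQ)


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-size simulated experiment shared by read-only tests."""
    region = cf.generate_reference(400, 0.6, 30, seed=11, name="fixture_region")
    model = cf.build_preference_model("3A-like", 1.0)
    params = cf.SimulationParams(n_molecules=120, maintenance_efficiency=0.95,
                                 conversion_rate=0.991, seed=12)
    molecules, truth = cf.simulate_molecules(region, model, params)
    matrix = cf.call_clones([(m.fasta_header, m.read) for m in molecules], region)
    return {"region": region, "model": model, "params": params,
            "molecules": molecules, "truth": truth, "matrix": matrix}
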