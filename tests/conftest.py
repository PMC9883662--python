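import numpy as np
import pytest

import pbpkddi as p

#: solver settings for tests that do not probe integration accuracy
FAST_OPTS = {"rtol": 1e-6, "atol": 1e-9, "dt": 0.25}


@pytest.fixture(scope="session")
def ref_chinese_adult():
    return p.reference_subject("Chinese", 40.0, "M")


@pytest.fixture(scope="session")
def ref_caucasian_adult():
    return p.reference_subject("Caucasian", 40.0, "M")


@pytest.fixture(scope="session")
def dabe_chain():
    return p.load_bundled_chain("dabigatran_etexilate")


@pytest.fixture(scope="session")
def riva_chain():
    return p.load_bundled_chain("rivaroxaban")


@pytest.fixture(scope="session")
def ki_table():
    return p.load_interactions()


def one_compartment_compound(cl_L_h=5.0, vc_L_per_kg=0.5, fu=1.0):
    """Degenerate bolus/linear-clearance compound for analytic oracles."""
    from pbpkddi.compounds import ClearanceParams, CompoundModel, DistributionParams

    return CompoundModel(
        name="toy",
        molecular_weight=400.0,
        fu_plasma=fu,
        distribution=DistributionParams(vc_L_per_kg=vc_L_per_kg),
        clearance=ClearanceParams(
            renal_filtration=False, systemic_cl_L_h=cl_L_h
        ),
    )


@pytest.fixture(scope="session")
def toy_compound():
    return one_compartment_compound()
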