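import numpy as np
import pytest

import bondbio as bb


@pytest.fixture()
def enzyme_module():
    """Two-step enzyme motif E + S <-> C <-> E + P with mass-action laws."""
    return bb.network_from_reactions(
        "enzyme",
        {"E": 2.0, "C": 3.0, "S": 0.5, "P": 1.5},
        {
            "r1": (bb.MassAction(1.2), ["E", "S"], ["C"]),
            "r2": (bb.MassAction(0.7), ["C"], ["E", "P"]),
        },
    )


@pytest.fixture()
def enzyme_network(enzyme_module):
    model = bb.BondGraphModel(
        enzyme_module, initial={"E": 1.0, "S": 2.0, "C": 0.1, "P": 0.05}
    )
    return model.network()


@pytest.fixture(scope="session")
def glycolysis_reference():
    from bondbio import glycolysis

    return glycolysis.build_glycolysis()


@pytest.fixture(scope="session")
def glycolysis_trio(glycolysis_reference):
    """GK reference plus calibrated MA and MM variants."""
    from bondbio import glycolysis

    g = glycolysis_reference
    ma, ma_report = glycolysis.calibrate_mass_action(g.network, g.x_ref)
    mm, mm_report = glycolysis.calibrate_michaelis_menten(g.network, g.x_ref)
    return {
        "GK": g.network,
        "MA": ma,
        "MM": mm,
        "x_ref": g.x_ref,
        "ma_report": ma_report,
        "mm_report": mm_report,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
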