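import sys
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))  # lp_oracle importable as a module

from petriflux import MetabolicModel, build_model
from petriflux.synth import (
    ToyGSMNSpec,
    ToyRegulomeSpec,
    make_toy_hepatocyte_gsmn,
    make_toy_qualitative_setup,
)


@pytest.fixture(scope="session")
def toy_gsmn() -> MetabolicModel:
    return make_toy_hepatocyte_gsmn(ToyGSMNSpec())


@pytest.fixture(scope="session")
def toy_qual_setup():
    return make_toy_qualitative_setup(ToyRegulomeSpec())


@pytest.fixture()
def chain_model() -> MetabolicModel:
    """Aext -> A -> B -> Bext with the middle step capped at 5."""
    return build_model(
        stoich={
            "EX_A": {"A_e": -1},
            "T_A": {"A_e": -1, "A": 1},
            "CONV": {"A": -1, "B": 1},
            "T_B": {"B": -1, "B_e": 1},
            "EX_B": {"B_e": -1},
        },
        bounds={
            "EX_A": (-100.0, 100.0),
            "T_A": (0.0, 100.0),
            "CONV": (0.0, 5.0),
            "T_B": (0.0, 100.0),
            "EX_B": (0.0, 100.0),
        },
    )


def model_from_arrays(N: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> MetabolicModel:
    m, n = N.shape
    model = MetabolicModel(
        metabolites=[f"M{i}" for i in range(m)],
        reactions=[f"R{j}" for j in range(n)],
        stoichiometry=sp.csr_matrix(N),
        lower_bounds=lb.copy(),
        upper_bounds=ub.copy(),
    )
    model.validate()
    return model
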