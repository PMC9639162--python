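import numpy as np
import pytest

from memfret.coupling import CouplingGeometry
from memfret.rates import AcceptorState

# Published reference values for the membrane-embedded donor/acceptor pair:
# per-state squared couplings (kg² m⁴ s⁻⁴), coupling magnitudes (cm⁻¹),
# spectral overlaps (cm), rates (s⁻¹) and lifetimes (ns).
REFERENCE_TABLE = {
    "S5": {"V2": 9.90e-47, "V_cm": 0.501, "J": 2.12e-4, "k": 6.28e7, "tau_ns": 15.9},
    "S6": {"V2": 5.80e-46, "V_cm": 1.21, "J": 1.44e-4, "k": 2.49e8, "tau_ns": 4.01},
    "S7": {"V2": 7.15e-46, "V_cm": 1.35, "J": 8.00e-5, "k": 1.72e8, "tau_ns": 5.82},
    "S8": {"V2": 9.76e-46, "V_cm": 1.57, "J": 8.00e-5, "k": 2.34e8, "tau_ns": 4.27},
}
REFERENCE_TOTAL_K = 7.18e8
REFERENCE_TOTAL_TAU_NS = 1.39

DONOR_STRENGTH_DEBYE = 12.3
DONOR_TILT_DEG = 11.7
# near-degenerate state pairs share strength; tilts follow the parallel (49.6°)
# vs perpendicular (29.6°) reference-vector assignment
ACCEPTOR_PARAMS = {
    "S5": (1.2, 49.6),
    "S6": (2.5, 29.6),
    "S7": (3.2, 49.6),
    "S8": (3.2, 29.6),
}
R_ANGSTROM = 33.4
ETA = 1.478


@pytest.fixture
def table_geometry():
    return CouplingGeometry(R_ANGSTROM, ETA)


@pytest.fixture
def table_states():
    return [
        AcceptorState(label, *ACCEPTOR_PARAMS[label], overlap_cm=REFERENCE_TABLE[label]["J"])
        for label in ("S5", "S6", "S7", "S8")
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20220919)
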