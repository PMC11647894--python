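"""Shared fixtures and published reference values used as test oracles.

The reference dictionaries below hold published per-atom partial charges,
pairwise interaction energies of the cellulose Ibeta O6oH···O3o interchain
hydrogen bond, and the averaged hydrogen-bond geometry/energy tables of
energy-minimized cellulose Ibeta crystals.  They are *inputs* to the tests:
the package must reproduce derived quantities from them.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import cellenergy as ce

# partial charges (e) of the non-neutral cellulose atoms in GLYCAM
TABLE_CHARGES = {
    "C2": 0.310, "O2": -0.718, "HO2": 0.437,
    "C3": 0.284, "O3": -0.709, "HO3": 0.432,
    "C6": 0.282, "O6": -0.688, "HO6": 0.424,
    "O4": -0.468, "C1": 0.384, "O5": -0.471, "C5": 0.225, "C4": 0.276,
}

# published pairwise electrostatic energies (kcal/mol) between the donor
# triple H_O6-O6-C6 and acceptor triple H_O3-O3-C3 of the Ibeta interchain
# bond O6oH···O3o; rows: O6, HO6, C6; columns: O3, HO3, C3.
PAIR_ELEC_O6O3 = np.array(
    [
        [59.5, -30.4, -16.7],
        [-56.3, 25.2, 13.7],
        [-18.1, 9.2, 5.9],
    ]
)
PAIR_DONOR = ["O6", "HO6", "C6"]
PAIR_ACCEPTOR = ["O3", "HO3", "C3"]

# averaged hydrogen-bond geometry and donor-COH vs acceptor-O electrostatic
# energies of energy-minimized cellulose Ibeta (osmotic-recalibrated force
# field): (label, donor O, acceptor O, d_HO, d_OO, angle, E_COH_O, sd)
IBETA_HBOND_ROWS = [
    ("O3oH-O5o intra", "O3", "O5", 1.82, 2.76, 161.0, -9.7, 0.2),
    ("O3cH-O5c intra", "O3", "O5", 1.78, 2.74, 170.0, -10.4, 0.2),
    ("O2oH-O6o intra", "O2", "O6", 1.81, 2.79, 172.0, -15.7, 0.2),
    ("O2cH-O6c intra", "O2", "O6", 1.76, 2.72, 166.0, -15.9, 0.2),
    ("O6oH-O3o inter", "O6", "O3", 1.77, 2.72, 162.0, -14.9, 0.6),
    ("O6cH-O3c inter", "O6", "O3", 1.90, 2.87, 170.0, -14.4, 0.5),
    ("O6oH-O2o inter", "O6", "O2", 2.97, 3.59, 122.0, -7.5, 0.3),
    ("O6cH-O2c inter", "O6", "O2", 2.98, 3.54, 118.0, -9.5, 0.2),
]

# published per-bond interchain energies (kcal/mol) entering the per-glucose
# aggregation: (class, parity, COH_COX elec, COH_O elec)
IBETA_INTER_BOND_ENERGIES = [
    ("O6oH-O3o", "origin", -8.1, -14.9),
    ("O6oH-O2o", "origin", -0.7, -7.5),
    ("O6cH-O3c", "center", -6.7, -14.4),
    ("O6cH-O2c", "center", -2.3, -9.5),
]
II_INTER_BOND_ENERGIES = [
    ("O2oH-O2c", "origin", -7.0, -18.5),
    ("O6oH-O2o", "origin", -8.1, -18.0),
    ("O2cH-O6c", "center", -8.6, -18.5),
    ("O6cH-O6o", "center", -7.8, -16.8),
]

# bulk electrostatic interchain energies per glucose unit (kcal/mol),
# osmotic-recalibrated force field
BULK_ELEC_INTERCHAIN = {"Ibeta": -13.5, "II": -21.5}


@pytest.fixture(scope="session")
def ff():
    return ce.load_forcefield()


@pytest.fixture(scope="session")
def ff_osmo():
    return ce.load_forcefield("GLYCAM06_OSMOr14_TIP5P")


@pytest.fixture(scope="session")
def small_ibeta():
    return ce.build_crystal("Ibeta", 6, 4)


@pytest.fixture(scope="session")
def small_ii():
    return ce.build_crystal("II", 6, 4)


@pytest.fixture(scope="session")
def param_ibeta(small_ibeta, ff):
    return ce.neutralize_termini(ce.assign_parameters(small_ibeta, ff))


def derived_pair_distances():
    """Interatomic distances implied by the published pairwise energies."""
    q_d = np.array([TABLE_CHARGES[n] for n in PAIR_DONOR])
    q_a = np.array([TABLE_CHARGES[n] for n in PAIR_ACCEPTOR])
    return ce.COULOMB_PREFACTOR * np.outer(q_d, q_a) / PAIR_ELEC_O6O3
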