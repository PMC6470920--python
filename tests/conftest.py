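"""Shared fixtures: the synthetic host/guest/force-field system plus tiny
hand-built structures for closed-form checks."""

import numpy as np
import pytest

import chiroscan as cs
from chiroscan.structure import AtomRecord, Structure


@pytest.fixture(scope="session")
def ff():
    return cs.make_toy_forcefield()


@pytest.fixture(scope="session")
def solv():
    return cs.SolventSpec(epsilon=1.0, guest_variant="NP")


@pytest.fixture(scope="session")
def guest_pair(ff):
    return cs.make_chiral_guest("NP")


@pytest.fixture(scope="session")
def guest_pair_p():
    return cs.make_chiral_guest("P")


@pytest.fixture(scope="session")
def host():
    return cs.make_toy_host()


@pytest.fixture(scope="session")
def host_chiral():
    return cs.make_toy_host(chiral=True)


@pytest.fixture(scope="session")
def cavity():
    return cs.cavity_for_host()


def single_atom(
    x=0.0, y=0.0, z=0.0, charge=0.0, mass=12.0, lj_type="X", role="none"
) -> Structure:
    return Structure(
        atoms=[
            AtomRecord(
                id=0, element="C", mass=mass, charge=charge, lj_type=lj_type, hbond_role=role
            )
        ],
        coords=np.array([[x, y, z]]),
    )


def toy_pair_ff(A=4096.0, B=1.0, C=0.0, D=0.0, kappa=332.0522) -> cs.ForceFieldParams:
    return cs.ForceFieldParams(
        lj_pairs={("X", "X"): (A, B)},
        hbond_pairs={("X", "X"): (C, D)},
        coulomb_constant=kappa,
    )
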