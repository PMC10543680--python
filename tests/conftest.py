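import numpy as np
import pytest

import islandsas as isl


@pytest.fixture(scope="session")
def xray():
    return isl.ProbeContrast("xray")


@pytest.fixture(scope="session")
def sans_d2o():
    return isl.ProbeContrast("neutron", x_d=1.0)


@pytest.fixture(scope="session")
def dppc_profile(xray):
    return isl.DPPC.bilayer_profile(xray)


@pytest.fixture(scope="session")
def dppc_system(xray, dppc_profile):
    return isl.MembraneSystem(
        bilayer=dppc_profile, probe=xray, concentrations=((3.0, isl.DPPC.volume),)
    )


@pytest.fixture(scope="session")
def domain_system(xray):
    """DOPC domains (R1 = 60 A) in DPPC, a = 150 A, g_a = 0.3, 3 mM host."""
    return isl.build_domain_system(isl.DPPC, isl.DOPC, 150.0, 60.0, 0.3, 3.0, xray)


@pytest.fixture(scope="session")
def pore_system(xray, dppc_profile):
    island = isl.build_pore(20.0, dppc_profile)
    return isl.MembraneSystem(
        bilayer=dppc_profile,
        probe=xray,
        island=island,
        lattice=isl.ParacrystalLattice2D(150.0, 0.3),
        concentrations=((3.0, isl.DPPC.volume),),
    )


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.01, 0.5, 120)
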