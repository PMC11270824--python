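import pytest

import cg2des as cg


@pytest.fixture(scope="session")
def dimer_single():
    system = cg.make_dimer_fixture("single_segment")
    system.temperature = None  # HT limit
    return system


@pytest.fixture(scope="session")
def dimer_double():
    system = cg.make_dimer_fixture("double_segment")
    system.temperature = None
    return system


@pytest.fixture(scope="session")
def static_dimer_traj(dimer_single):
    """Noise-free dimer trajectory: every frame equals the mean energies."""
    bath = cg.BathParams(sigma=[0.0, 0.0], lambda_inv=[220.0, 220.0])
    return cg.generate_ou_trajectory(bath, dimer_single.means, 200, 2.0, seed=0)


@pytest.fixture(scope="session")
def single_site_ht():
    return cg.SystemModel(
        means=[12000.0],
        bath=cg.BathParams([198.0], [220.0]),
        J=cg.CouplingMatrix([[0.0]]),
        dipoles=cg.DipoleSet([[1.0, 0.0, 0.0]]),
        segmentation=cg.Segmentation([0]),
        temperature=None,
    )


@pytest.fixture(scope="session")
def static_site_ht():
    return cg.SystemModel(
        means=[12000.0],
        bath=cg.BathParams([0.0], [100.0]),
        J=cg.CouplingMatrix([[0.0]]),
        dipoles=cg.DipoleSet([[1.0, 0.0, 0.0]]),
        segmentation=cg.Segmentation([0]),
        temperature=None,
    )
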