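import numpy as np
import pytest

from apbnrr.core import LabelMap, RegistrationConfig
from apbnrr.phantom import PhantomSpec, make_brain_phantom, make_case


@pytest.fixture(scope="session")
def cube_labels():
    """A 20^3-voxel solid cube of parenchyma inside a 24^3 grid (1 mm)."""
    lab = np.zeros((24, 24, 24), dtype=np.int32)
    lab[2:22, 2:22, 2:22] = 1
    return LabelMap(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def sphere_labels():
    """A radius-20 sphere with an embedded radius-7 tumor (1 mm grid)."""
    x, y, z = np.meshgrid(*[np.arange(48.0)] * 3, indexing="ij")
    r = np.sqrt((x - 24) ** 2 + (y - 24) ** 2 + (z - 24) ** 2)
    lab = np.where(r <= 20, 1, 0).astype(np.int32)
    lab[np.sqrt((x - 30) ** 2 + (y - 24) ** 2 + (z - 24) ** 2) <= 7] = 2
    return LabelMap(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom for unit tests (40^3 at 2 mm)."""
    return PhantomSpec(
        shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0),
        brain_semiaxes=(34.0, 30.0, 32.0),
        tumor_center_offset=(10.0, 0.0, 0.0), tumor_radius=10.0,
        amplitude=4.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_brain_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 64^3 / 2 mm phantom (no deformation)."""
    spec = PhantomSpec(amplitude=0.0, seed=1)
    image, labels = make_brain_phantom(spec)
    return spec, image, labels


@pytest.fixture(scope="session")
def tr_case():
    """Total-resection case: 5 mm deformation, full tumor removal."""
    spec = PhantomSpec(amplitude=5.0, eor=1.0, seed=2)
    preop, labels, intraop, truth = make_case("TR", spec)
    return spec, preop, labels, intraop, truth


@pytest.fixture(scope="session")
def tr_fits(tr_case):
    """PBNRR and A-PBNRR fitted on the total-resection case."""
    from apbnrr.model import AdaptivePBNRR, PBNRR

    _, preop, labels, intraop, _ = tr_case
    config = RegistrationConfig().with_case_type("TR")
    pbnrr = PBNRR(intraop, preop, labels, config).fit()
    apbnrr = AdaptivePBNRR(intraop, preop, labels, config).fit()
    return pbnrr, apbnrr
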