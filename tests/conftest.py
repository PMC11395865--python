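import numpy as np
import pytest

from rapidwashout import phantom
from rapidwashout.phantom import Lesion, PhantomLayout


@pytest.fixture(scope="session")
def default_case():
    """One seeded default phantom (identity transform, bias + noise)."""
    return phantom.generate(seed=11)


@pytest.fixture(scope="session")
def small_layout():
    """Small grid for N4-heavy tests (48^3 voxels at 2.5 mm)."""
    return PhantomLayout(
        shape=(48, 48, 40), spacing=(2.5, 2.5, 2.5),
        head_semiaxes_mm=(42.0, 48.0, 38.0),
        lesions=[
            Lesion("enhancing_tumor", "sphere", (14.0, 8.0, 4.0), radius_mm=8.0),
            Lesion("necrosis_scar", "sphere", (-18.0, -8.0, 0.0), radius_mm=9.0),
        ],
    )


@pytest.fixture(scope="session")
def small_case(small_layout):
    return phantom.generate(layout=small_layout, seed=21)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0
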