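import numpy as np
import pytest

from talenkit import (
    Architecture,
    ArrayGeometry,
    Scaffold,
    SpacerWindows,
    all_architectures,
    array_geometry,
)


@pytest.fixture(scope="session")
def geom() -> ArrayGeometry:
    """Standard 15.5-repeat array (16 recognised nt, 17-bp footprint)."""
    return array_geometry()


@pytest.fixture(scope="session")
def geom3() -> ArrayGeometry:
    """Tiny 3-nt arrays used by hand-checkable examples."""
    return ArrayGeometry(3)


@pytest.fixture(scope="session")
def archs() -> dict[str, Architecture]:
    return all_architectures()


@pytest.fixture(scope="session")
def toy_archs() -> dict[str, Architecture]:
    """All three layouts restricted to a single 4-bp spacer window."""
    w = SpacerWindows(((4, 4),))
    return {
        "TtT": Architecture("TtT", Scaffold("TALE_FOKI"), Scaffold("TALE_FOKI"), w),
        "HtH": Architecture("HtH", Scaffold("FOKI_TALE"), Scaffold("FOKI_TALE"), w),
        "TtH": Architecture("TtH", Scaffold("TALE_FOKI"), Scaffold("FOKI_TALE"), w),
    }


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
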