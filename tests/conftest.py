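import numpy as np
import pytest

from cordstereo.phantom import (
    Ellipse,
    PhantomSpec,
    Rect,
    SegmentGeom,
    build_phantom,
    default_spec,
)


def make_plain_segment(
    name="S1",
    length=20.0,
    gs_start=(6.0, 5.0),
    gs_end=None,
    with_gm=True,
    cc_semi=(0.18, 0.09),
):
    """Small test segment; ``gs_end=None`` means untapered."""
    if gs_end is None:
        gs_end = gs_start
    if with_gm:
        dh = (Ellipse(-1.5, 1.6, 0.9, 1.1), Ellipse(1.5, 1.6, 0.9, 1.1))
        vh = (Ellipse(-1.6, -1.8, 1.0, 1.3), Ellipse(1.6, -1.8, 1.0, 1.3))
        isthmus = Rect(0.0, 0.0, 0.6, 0.3)
        cc = Ellipse(0.0, 0.0, *cc_semi)
    else:
        # vanishing grey matter tucked at the centre so invariants still hold
        dh = (Ellipse(-0.65, 0.5, 0.05, 0.05), Ellipse(0.65, 0.5, 0.05, 0.05))
        vh = (Ellipse(-0.65, -0.5, 0.05, 0.05), Ellipse(0.65, -0.5, 0.05, 0.05))
        isthmus = Rect(0.0, 0.0, 0.6, 0.3)
        cc = Ellipse(0.0, 0.0, 0.01, 0.01)
    return SegmentGeom(
        name=name,
        length=length,
        gs_start=gs_start,
        gs_end=gs_end,
        dh=dh,
        vh=vh,
        isthmus=isthmus,
        cc=cc,
    )


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Untapered elliptical cord: every section identical, volume = pi*a*b*L."""
    return build_phantom(PhantomSpec(segments=(make_plain_segment(),)))


@pytest.fixture(scope="session")
def tapered_phantom():
    seg = make_plain_segment(name="T1", gs_start=(6.0, 5.0), gs_end=(8.0, 6.0), length=38.0)
    return build_phantom(PhantomSpec(segments=(seg,)))


@pytest.fixture(scope="session")
def cord_phantom():
    """Default 8-segment phantom."""
    return build_phantom(default_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
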