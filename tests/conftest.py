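"""Shared fixtures: expensive objects are built once per session."""

import math

import pytest
from hypothesis import HealthCheck, settings

import scosfire as sc
from scosfire.presets import preset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CENTER_512 = (255.5, 255.5)
SQUARE_ORIENTATION = math.pi / 12
SQUARE_HALF_SIDE = 100.0


@pytest.fixture(scope="session")
def fig4():
    return preset("fig4-triangle")


@pytest.fixture(scope="session")
def gabor12():
    return sc.build_gabor_bank([4.0], 12)


@pytest.fixture(scope="session")
def vbank(fig4):
    return sc.build_vertex_bank(blur=fig4.blur, response_t1=fig4.v_t1)


@pytest.fixture(scope="session")
def triangle512():
    return sc.make_triangle(50.0, canvas=(512, 512))


@pytest.fixture(scope="session")
def tri_filter(triangle512, vbank, fig4):
    return sc.configure_s_cosfire(
        triangle512, CENTER_512, vbank,
        t1=fig4.t1, t2=fig4.t2, blur=fig4.blur, t3=0.0, frontend=fig4.frontend,
    )


@pytest.fixture(scope="session")
def square512():
    return sc.make_square(SQUARE_HALF_SIDE, canvas=(512, 512),
                          orientation=SQUARE_ORIENTATION)


@pytest.fixture(scope="session")
def square_filter(square512, vbank, fig4):
    return sc.configure_s_cosfire(
        square512, CENTER_512, vbank,
        t1=fig4.t1, t2=fig4.t2, blur=fig4.blur, t3=0.0, frontend=fig4.frontend,
    )
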