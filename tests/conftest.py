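import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from auxinpulse.flux import LinearFluxParams
from auxinpulse.simulator import ChannelSpec, DiscretizationParams, TissueModel


def make_single_channel(
    p=4e-4, q=2.08e-5, D=5e-6, n_cells=250, N=5, dt=0.05, width=20e-4
) -> TissueModel:
    """One cell file with a linear axial face law (test helper)."""
    return TissueModel(
        channels=(ChannelSpec(face_law=LinearFluxParams(p, q), D=D, width=width),),
        couplings=(),
        n_cells=n_cells,
        disc=DiscretizationParams(n_compartments=N, delta_t=dt),
    )


def make_minimal_two_channel(s=7.1e-6, p=1.4e-3, n_cells=350, N=5, dt=0.05):
    """Polar + apolar channel pair with symmetric lateral coupling."""
    return TissueModel(
        channels=(
            ChannelSpec(face_law=LinearFluxParams(p, 0.0), name="polar"),
            ChannelSpec(face_law=LinearFluxParams(0.0, 0.0), name="apolar",
                        polarity="apolar"),
        ),
        couplings=(s,),
        n_cells=n_cells,
        disc=DiscretizationParams(n_compartments=N, delta_t=dt),
    )


@pytest.fixture
def single_channel_fig3():
    return make_single_channel()


@pytest.fixture
def minimal_two_channel():
    return make_minimal_two_channel()
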