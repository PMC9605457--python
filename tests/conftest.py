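import numpy as np
import pytest

from pulsevar import BeatTemplate, HarmonicProfile, JitterModel, simulate_recording
from pulsevar.simulate import N_HARMONICS


@pytest.fixture
def template() -> BeatTemplate:
    return BeatTemplate()


@pytest.fixture
def zero_jitter_recording(template):
    return simulate_recording(
        template, JitterModel(rr_mean=0.75, seed=0), duration_s=60.0, fs=500.0
    )


def make_profile(**overrides) -> HarmonicProfile:
    """A HarmonicProfile with easily controllable index values.

    Keyword arguments use flat index names, e.g. ``CV2=3.0, P1_SD=4.0``.
    """
    fields = {
        "C": np.linspace(40.0, 1.0, N_HARMONICS),
        "CV": np.full(N_HARMONICS, 3.0),
        "P": np.zeros(N_HARMONICS),
        "P_SD": np.full(N_HARMONICS, 5.0),
        "HR": 75.0,
        "HR_CV": 4.0,
        "n_beats": 75,
    }
    for name, value in overrides.items():
        if name in fields:
            fields[name] = value
            continue
        if name.startswith("CV"):
            fields["CV"] = fields["CV"].copy()
            fields["CV"][int(name[2:]) - 1] = value
        elif name.startswith("P") and name.endswith("_SD"):
            fields["P_SD"] = fields["P_SD"].copy()
            fields["P_SD"][int(name[1:-3]) - 1] = value
        elif name.startswith("C"):
            fields["C"] = fields["C"].copy()
            fields["C"][int(name[1:]) - 1] = value
        elif name.startswith("P"):
            fields["P"] = fields["P"].copy()
            fields["P"][int(name[1:]) - 1] = value
        else:
            raise KeyError(name)
    return HarmonicProfile(**fields)
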