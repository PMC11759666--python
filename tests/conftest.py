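import numpy as np
import pytest

from mousephys import pupil, synth


@pytest.fixture
def cfg():
    return pupil.PupilConfig()


def render_pupil(minor, major=None, **kwargs):
    """Render an eye frame with a given minor axis; returns (frame, truth)."""
    if major is None:
        major = max(minor * 1.6, minor + 2.0)
    params = synth.EyeSceneParams(axes=(float(major), float(minor)), **kwargs)
    return synth.render_eye_frame(params)


@pytest.fixture
def render():
    return render_pupil
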