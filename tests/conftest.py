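import numpy as np
import pytest

import spindlemetrics as sm

NOISE_OFF = sm.NoiseModel(shot=False, read_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_scene() -> sm.SpindleScene:
    return sm.SpindleScene(noise=sm.NoiseModel(shot=False, read_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_render(noiseless_scene):
    """(scene, image, ground truth) for the default noise-free spindle."""
    image, gt = sm.generate_spindle_image(noiseless_scene)
    return noiseless_scene, image, gt


def half_spindle_scan(
    image: sm.SpindleImage,
    ann: sm.PoleAnnotation,
    from_pole: str = "a",
    length_um: float = 6.5,
    width_px: int = 10,
) -> sm.IntensityProfile:
    """Normalized wide line scan from one pole toward the spindle center."""
    origin, other = (
        (ann.pole_a, ann.pole_b) if from_pole == "a" else (ann.pole_b, ann.pole_a)
    )
    o = np.asarray(origin, dtype=float)
    u = np.asarray(other, dtype=float) - o
    u = u / np.hypot(*u)
    end = o + u * (length_um / image.pixel_size)
    profile = sm.extract_line_profile(
        image, tuple(o), tuple(end), width_px, ["gamma_tubulin", "kif18a"]
    )
    return sm.normalize_profile(profile)
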