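import numpy as np
import pytest

from respiradar import (BreathingPattern, PatternClass, RadarConfig,
                        SceneConfig, synthesize_cube)


@pytest.fixture(scope="session")
def radar():
    """Reference radar profile (77 GHz, 4 GHz sweep, 50 ms frames, 4 rx)."""
    return RadarConfig()


@pytest.fixture(scope="session")
def breathing_pattern():
    """Plain sinusoidal breathing at 0.28 Hz, 4 mm amplitude."""
    return BreathingPattern(PatternClass.NORMAL, amplitude=0.004, rate=0.28,
                            shape_exponent=2.0)


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, clutter-free scene with aligned channels at 0.8 m."""
    return SceneConfig(target_range=0.8, snr_db=np.inf, clutter=(),
                       rx_phase_offsets=(0.0, 0.0, 0.0, 0.0),
                       rx_delays=(0, 0, 0, 0), seed=1)


@pytest.fixture(scope="session")
def noiseless_cube(radar, breathing_pattern, clean_scene):
    """25 s noiseless single-target cube (500 frames)."""
    return synthesize_cube(breathing_pattern, clean_scene, radar, 25.0)
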