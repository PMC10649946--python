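import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mhdecg as m
from mhdecg.mhd_extraction import TemplateDatabase

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_ecg():
    """30 s 12-lead recording, 60 bpm, light noise, exact R-peak truth."""
    return m.synth_clean_ecg(m.BeatModel(noise_sd=0.004, seed=11),
                             duration=30.0)


@pytest.fixture(scope="session")
def clean_vcg():
    return m.synth_clean_ecg(m.BeatModel(noise_sd=0.0, seed=12),
                             duration=30.0, leads=3)


@pytest.fixture(scope="session")
def template_db():
    """64 synthetic distortion templates (for GAN smoke training etc.)."""
    return TemplateDatabase(
        templates=[m.synth_distortion(m.DistortionModel(seed=i))
                   for i in range(64)])


@pytest.fixture(scope="session")
def benchmark_suite():
    return m.make_benchmark_suite(seed=42)
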