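import numpy as np
import pytest

from ripplecam import (
    CnnArchitecture,
    GeneratorConfig,
    RippleWaveform,
    generate_dataset,
)

CATS = ("Restraint", "Female", "Male", "Object", "Before")


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def small_dataset(gen_config):
    """Forty synthetic events (8 per category) plus manifest."""
    events, manifest = generate_dataset(
        gen_config, {c: 8 for c in CATS}, seed=5
    )
    return events, manifest


@pytest.fixture
def toy_arch():
    """A miniature architecture for gradient checks (same code path)."""
    return CnnArchitecture(
        input_len=30, conv_filters=4, conv_kernel=8, conv_stride=2,
        pool_size=3, pool_stride=2, fc_hidden=7, n_classes=3,
    )


def make_wave(samples, *, id="w", category="Restraint", stage="raw", fs=25000.0,
              **kw):
    return RippleWaveform(
        id=id, rat_id=0, category=category, fs=fs,
        samples=np.asarray(samples, dtype=float), stage=stage, **kw,
    )
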