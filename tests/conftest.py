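import numpy as np
import pytest

from caosc import DffTrace, RawTrace, build_morph_presets, build_stage_presets


@pytest.fixture(scope="session")
def stage_presets():
    return build_stage_presets()


@pytest.fixture(scope="session")
def morph_presets():
    return build_morph_presets()


@pytest.fixture
def make_dff():
    """Wrap a plain array as a DffTrace (f0 = 1, so values are dF/F0)."""

    def _make(values, fs=5.0):
        return DffTrace(values=np.asarray(values, dtype=float), f0=1.0, fs=fs)

    return _make


@pytest.fixture
def make_raw():
    def _make(values, fs=5.0):
        return RawTrace(values=np.asarray(values, dtype=float), fs=fs)

    return _make
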