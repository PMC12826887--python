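import numpy as np
import pytest

from ppgsurv.synthetic_data import canonical_beat_params, generate_beat


@pytest.fixture(scope="session")
def canonical_params():
    return canonical_beat_params()


@pytest.fixture(scope="session")
def canonical_beat(canonical_params):
    """(PulseWave, BeatTruth) for the default beat at 250 Hz."""
    return generate_beat(canonical_params, 250.0)


@pytest.fixture(scope="session")
def canonical_beat_500(canonical_params):
    return generate_beat(canonical_params, 500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_beat_params(rng, morph_low=0.7, morph_high=1.3):
    """Random valid beat parameters near the canonical contour."""
    from ppgsurv.synthetic_data import BeatParams

    base = canonical_beat_params(
        morph_c=rng.uniform(morph_low, morph_high),
        decay=rng.uniform(0.8, 1.3),
        period=rng.uniform(0.64, 0.76),
    )
    jig = lambda v, f: v * rng.uniform(1 - f, 1 + f)
    return BeatParams(
        amplitudes=tuple(jig(a, 0.05) for a in base.amplitudes),
        centers=base.centers,
        widths=tuple(jig(w, 0.05) for w in base.widths),
        decay=base.decay,
        period=base.period,
    )
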