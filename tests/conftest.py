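import numpy as np
import pytest

from respconn.synthetic_data import (
    CouplingSpec,
    ParadigmSpec,
    default_coupling,
    default_paradigm,
)


def pair_coupling(
    kappa: float,
    band: str = "alpha",
    center: float = 10.5,
    conditions=("SB",),
    phase_noise_sd: float = 1.4,
    phase_noise_ac: float = 0.995,
    sensor_noise_sd: float = 1.0,
    amplitude: float = 15.0,
    freq_jitter: float = 0.08,
) -> CouplingSpec:
    """Two-channel, single-band coupling spec with one adjustable edge."""
    k = np.array([[0.0, kappa], [kappa, 0.0]])
    return CouplingSpec(
        coupling={(c, band): k.copy() for c in conditions},
        amplitudes={band: amplitude},
        band_centers={band: center},
        phase_noise_sd=phase_noise_sd,
        phase_noise_ac=phase_noise_ac,
        freq_jitter=freq_jitter,
        sensor_noise_sd=sensor_noise_sd,
    )


def pair_paradigm(duration: float = 10.0, fs: float = 500.0) -> ParadigmSpec:
    return ParadigmSpec((("SB", duration),), fs, ("A", "B"))


@pytest.fixture(scope="session")
def small_paradigm():
    """Full three-condition layout at one tenth of the standard block lengths."""
    return default_paradigm(block_scale=0.1)


@pytest.fixture(scope="session")
def coupling16():
    return default_coupling()


@pytest.fixture(scope="session")
def small_cohort(small_paradigm, coupling16):
    """Six subjects through the default generator (session-cached for speed)."""
    from respconn.synthetic_data import generate_cohort

    return generate_cohort(6, small_paradigm, coupling16, seed=11)


@pytest.fixture(scope="session")
def small_cohort_blocks(small_cohort):
    from respconn.preprocessing import bandpass, split_conditions_and_bands

    out = {}
    for s in small_cohort:
        rec = bandpass(s.recording, 1.0, 45.0)
        out[s.subject_id] = split_conditions_and_bands(rec)
    return out
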