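import numpy as np
import pytest

from icmaldi.msp_builder import ConsensusPeak, ConsensusProfile
from icmaldi.spectra_io import Peak, PeakList
from icmaldi.synthetic_data import TreatmentEffectConfig, generate_control_template, generate_proteome


def profile_from_pairs(pairs, profile_id="p", frequency=1.0):
    """ConsensusProfile from (mz, intensity) pairs; test helper."""
    peaks = tuple(ConsensusPeak(mz, inten, frequency) for mz, inten in sorted(pairs))
    return ConsensusProfile(profile_id=profile_id, peaks=peaks, n_source_spectra=1)


def peaklist_from_pairs(pairs, spectrum_id="s"):
    return PeakList(spectrum_id=spectrum_id, peaks=tuple(Peak(m, i) for m, i in sorted(pairs)))


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n_proteins=200, seed=42)


@pytest.fixture(scope="session")
def small_template(small_proteome):
    return generate_control_template(small_proteome, n_peaks=50, seed=42)


@pytest.fixture
def default_cfg():
    return TreatmentEffectConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
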