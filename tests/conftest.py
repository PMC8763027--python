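import pytest

from rnashapespace import (
    SamplerConfig,
    build_spectrum,
    get_folder,
    natural_spectrum,
    sample_sequences,
)
from rnashapespace.synthetic_data import SyntheticSpec, generate_null_database

# fixed study conditions for the synthetic-null walkthrough
NULL_L = 30
NULL_LEVEL = 5
N_NATURAL = 5_000
N_GSAMPLE = 50_000
SEED_NATURAL = 11
SEED_GSAMPLE = 12


@pytest.fixture(scope="session")
def builtin_folder():
    folder, backend_id = get_folder("builtin")
    return folder


@pytest.fixture(scope="session")
def gsample_spectrum_L30(builtin_folder):
    """The reference G-sample at the default synthetic scale (shared across
    tests: 50k folds are cheap but not free)."""
    config = SamplerConfig(NULL_L, N_GSAMPLE, SEED_GSAMPLE)
    return build_spectrum(sample_sequences(config), builtin_folder,
                          NULL_LEVEL, L=NULL_L)


@pytest.fixture(scope="session")
def natural_spectrum_L30(builtin_folder):
    """Spectrum of a synthetic null database of 5k unique sequences."""
    ds = generate_null_database(
        SyntheticSpec(L=NULL_L, n=N_NATURAL, seed=SEED_NATURAL),
        builtin_folder, NULL_LEVEL)
    return natural_spectrum(ds, builtin_folder, NULL_LEVEL)
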