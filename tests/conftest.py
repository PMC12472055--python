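import numpy as np
import pytest

from neutromet import (
    BinDefinition,
    FeatureTable,
    Spectrum,
    SyntheticConfig,
    default_pattern,
)


@pytest.fixture(scope="session")
def pattern():
    return default_pattern()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, artefact-free config for exact-arithmetic checks."""
    return SyntheticConfig(
        noise_sigma_ref=0.0,
        baseline_amplitude=0.0,
        water_hump_amplitude=0.0,
        shift_jitter_sd_ppm=0.0,
        tsp_amplitude=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced titration design for pipeline smoke tests.

    Keeps the full spectral resolution (the line-width QC needs it) but
    trims the design to 2 cell counts x 2 NS x 3 replicates.
    """
    return SyntheticConfig(
        cell_counts=(400_000, 5_000_000),
        ns_values=(256, 2048),
        replicates_per_condition=3,
        n_points=16384,
        seed=11,
    )


def make_spectrum(ppm, intensity, **meta):
    return Spectrum(np.asarray(ppm, float), np.asarray(intensity, float), meta=meta)


@pytest.fixture
def simple_table():
    """3 samples x 4 bins raw table with two annotated metabolites."""
    bins = [
        BinDefinition("b1", 2.0, 1.9, "alanine", "M_ala"),
        BinDefinition("b2", 1.8, 1.7, "alanine", "M_ala"),
        BinDefinition("b3", 1.6, 1.5, "lactate", "M_lac"),
        BinDefinition("b4", 1.4, 1.3, "unknown", ""),
    ]
    values = np.array(
        [[2.0, 3.0, 5.0, 1.0], [1.0, 4.0, 5.0, 2.0], [3.0, 3.0, 4.0, 3.0]]
    )
    import pandas as pd

    meta = pd.DataFrame({"sample_id": ["s1", "s2", "s3"], "group": ["A", "A", "B"]})
    return FeatureTable(values, meta, bins, state="raw")
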