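import numpy as np
import pandas as pd
import pytest

from plasmaftir.io import SpectraSet
from plasmaftir.simulate import BandModel, CohortConfig, generate_cohort


def noise_free_config(**overrides) -> CohortConfig:
    """Deterministic generator: no subject variation, baseline, gain or noise."""
    kw = dict(subject_cv=0.0, baseline_scale=0.0, gain_cv=0.0, noise_sd=0.0,
              replicates_per_subject=1, seed=0)
    kw.update(overrides)
    return CohortConfig(**kw)


def null_config(**overrides) -> CohortConfig:
    """Cohort with every disease multiplier forced to 1 (no class effect)."""
    base = CohortConfig()
    lib = [BandModel(b.center, b.fwhm, b.base_amplitude, 1.0, b.assignment_label)
           for b in base.band_library]
    kw = dict(band_library=lib)
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def default_cohort() -> SpectraSet:
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_cohort() -> SpectraSet:
    return generate_cohort(noise_free_config())


@pytest.fixture
def tiny_set() -> SpectraSet:
    """Two subjects x two replicates on a 4-point grid."""
    wn = np.array([1000.0, 1010.0, 1020.0, 1030.0])
    mat = np.array(
        [[0.0, 0.0, 0.0, 0.0],
         [2.0, 2.0, 2.0, 2.0],
         [1.0, 2.0, 3.0, 4.0],
         [1.0, 2.0, 3.0, 4.0]]
    )
    meta = pd.DataFrame(
        {
            "subject_id": ["HC001", "HC001", "MS001", "MS001"],
            "replicate": [1, 2, 1, 2],
            "class_label": ["HC", "HC", "MS", "MS"],
            "edss": [np.nan, np.nan, 2.0, 2.0],
            "onset_years": [np.nan, np.nan, 4.0, 4.0],
        }
    )
    return SpectraSet(wn, mat, meta)
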