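import numpy as np
import pytest

import ivmpk as pk


@pytest.fixture(scope="session")
def typical_params() -> pk.StructuralParams:
    """Typical-female structural parameters of the final published model."""
    return pk.StructuralParams(cl=7.02, q=9.11, vc=138.0, vp=424.33, ka=0.71, tk0=3.73, tlag=0.75)


@pytest.fixture(scope="session")
def ref_model() -> pk.PopulationModel:
    return pk.reference_model()


@pytest.fixture(scope="session")
def study_dataset(ref_model) -> pk.Dataset:
    """One 56-subject cohort simulated at the study design."""
    return pk.generate_dataset(pk.CohortSpec(seed=20240915), ref_model)


@pytest.fixture(scope="session")
def small_dataset(ref_model) -> pk.Dataset:
    """A small, fast cohort (8 subjects, sparse schedule) for estimator tests."""
    spec = pk.CohortSpec(
        n_subjects=8, schedule=(1.0, 3.0, 8.0, 24.0, 72.0, 168.0), n_missing_last=0, seed=42
    )
    return pk.generate_dataset(spec, ref_model)


def random_params(rng: np.random.Generator) -> pk.StructuralParams:
    """A random plausible parameter draw (log-uniform around the typical values)."""
    base = np.array([7.02, 9.11, 138.0, 424.33, 0.71, 3.73, 0.75])
    return pk.StructuralParams.from_array(base * np.exp(rng.uniform(-0.7, 0.7, size=7)))
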