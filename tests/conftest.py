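import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imgx.expression import build_expression_matrix
from imgx.pipeline import run_synthetic
from imgx.synthetic import (CohortSpec, EffectCluster, ExpressionSpec,
                            make_cohort, make_expression)

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-group cohort (n=83/83) with one planted atrophy cluster,
    d = -1.5 in AD, on a 32^3 grid of 1.5 mm voxels."""
    spec = CohortSpec(
        grid_shape=(32, 32, 32), n_per_group=83, groups=("NC", "AD"),
        effect_clusters=[EffectCluster((10, 16, 16), 6.0, {"AD": -1.5})],
        seed=11)
    return make_cohort(spec)


@pytest.fixture(scope="session")
def small_expression():
    """Small synthetic donor bundle + reduced matrix + the cohort whose
    atrophy field it was planted against."""
    spec = CohortSpec(
        grid_shape=(40, 48, 40), n_per_group=10, groups=("NC", "AD"),
        effect_clusters=[
            EffectCluster((12, 24, 20), 6.0, {"AD": -1.5}),
            EffectCluster((14, 34, 18), 6.0, {"AD": 1.5})],
        seed=3)
    cohort = make_cohort(spec)
    es = ExpressionSpec(n_samples_left=400, seed=4)
    synth = make_expression(es, cohort.effect_field("AD"))
    matrix = build_expression_matrix(synth.donors, synth.rnaseq)
    return {"cohort": cohort, "spec": es, "synth": synth, "matrix": matrix}


@pytest.fixture(scope="session")
def recovery_run():
    """One moderate-size end-to-end synthetic run with planted truth."""
    return run_synthetic(seed=5, n_per_group=30, n_boot=200,
                         n_samples_left=600)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
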