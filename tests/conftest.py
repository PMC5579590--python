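import numpy as np
import pandas as pd
import pytest

from polypattern.preprocessing import CovariateSet, IntakeTable, MetaboliteMatrix
from polypattern.synthetic import CovariateParams, GeneratorConfig


def make_matrix(values: pd.DataFrame, stage: str = "raw",
                below_loq: pd.DataFrame | None = None,
                loq: pd.Series | None = None,
                n_centers: int = 2, n_batches: int = 2) -> MetaboliteMatrix:
    """MetaboliteMatrix with trivial masks/labels for unit tests."""
    if below_loq is None:
        below_loq = pd.DataFrame(False, index=values.index, columns=values.columns)
    if loq is None:
        loq = pd.Series(np.nan, index=values.columns, name="loq")
    n = len(values)
    center = pd.Series([f"C{i % n_centers + 1}" for i in range(n)], index=values.index)
    batch = pd.Series([f"B{i % n_batches + 1}" for i in range(n)], index=values.index)
    return MetaboliteMatrix(values=values, below_loq=below_loq, loq=loq,
                            center=center, batch=batch, stage=stage)


def make_config(n_subjects: int = 200, n_foods: int = 4, n_metabolites: int = 10,
                loading_matrix=None, seed: int = 0, **overrides) -> GeneratorConfig:
    """Small generic-name generator config; defaults to no censoring/missing
    so preprocessing is exact unless a test opts in."""
    foods = tuple(f"food{j + 1}" for j in range(n_foods))
    mets = tuple(f"met{j + 1}" for j in range(n_metabolites))
    if loading_matrix is None:
        loading_matrix = np.zeros((n_foods, n_metabolites))
    defaults = dict(
        n_subjects=n_subjects,
        metabolite_names=mets,
        food_names=foods,
        consumer_prev=0.5,
        intake_logmean=4.0,
        intake_logsd=0.7,
        loading_matrix=loading_matrix,
        noise_sd=1.0,
        n_centers=2,
        n_batches=2,
        center_effect_sd=0.3,
        batch_effect_sd=0.2,
        loq_quantile=0.0,
        missing_rate=0.0,
        dq_attenuation=0.5,
        covariate_params=CovariateParams(),
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """200-subject cohort with one strongly loaded (food, metabolite) pair."""
    from polypattern.synthetic import generate_cohort, loading_for_target_correlation

    lam = np.zeros((4, 10))
    lam[0, 0] = loading_for_target_correlation(0.6, 1.0)
    cfg = make_config(n_subjects=200, loading_matrix=lam, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def covariates(rng):
    n = 200
    frame = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(26, 4, n).clip(15),
            "age": rng.normal(54, 8, n).clip(20),
        },
        index=[f"S{i:04d}" for i in range(n)],
    )
    return CovariateSet(frame=frame)
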