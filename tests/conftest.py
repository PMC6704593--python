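import logging

import numpy as np
import pytest
from hypothesis import settings

from anaerodyn import (GeneratorConfig, HierarchicalGrowthModel, build_deltas,
                       density_series, generate_cohort)
from anaerodyn.io import EMPIRICAL_LABELS, PROPHYLACTIC_LABELS
from anaerodyn.model import PosteriorDraws

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

logging.getLogger("anaerodyn").setLevel(logging.ERROR)

#: reduced sampler settings used throughout the suite
FAST_SAMPLER = dict(chains=3, draws=1500, warmup=500, steps=600)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_deltas(default_cohort):
    samples, exposures, metas, _ = default_cohort
    return build_deltas(density_series(samples), exposures, metas)


@pytest.fixture(scope="session")
def fitted_model(default_deltas):
    est = HierarchicalGrowthModel(seed=101, **FAST_SAMPLER)
    est.fit(default_deltas)
    return est


def make_point_posterior(n_draws: int = 200, patients=(), **values):
    """Posterior with every parameter a point mass (default 0)."""
    names = (["r", "phase1", "phase2", "prophylactic_pooled", "capacity",
              "sigma_m", "tau_prophylactic", "tau_patient"]
             + list(EMPIRICAL_LABELS)
             + [f"o_dev[{lbl}]" for lbl in PROPHYLACTIC_LABELS]
             + [f"patient[{p}]" for p in patients])
    params = {nm: np.full((1, n_draws), float(values.get(nm, 0.0)))
              for nm in names}
    return PosteriorDraws(params=params, patient_ids=tuple(patients))
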