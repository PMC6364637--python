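"""Shared fixtures.

The expensive posterior fits (the p = 20 recovery study, its deliberately
mis-grouped twin, and the GAM scene fit) are session-scoped so the recovery,
convergence and robustness properties are all checked against one fit each.
"""

import numpy as np
import pytest

from lncass.inference import run_mcmc, summarize
from lncass.models import GAMConfig, build_hierarchical_gam
from lncass.priors import LNCASSHyperparams
from lncass.synthetic import (
    default_scenarios,
    generate_gam_scene,
    generate_grouped_regression,
    run_simulation_study,
)

STUDY_SEED = 11
GAM_SEED = 5


@pytest.fixture(scope="session")
def hyper_default():
    return LNCASSHyperparams()


@pytest.fixture(scope="session")
def p20_scenario():
    config = default_scenarios()[0]
    data, truth = generate_grouped_regression(config)
    return config, data, truth


@pytest.fixture(scope="session")
def p20_study():
    """Grouped + flat LN-CASS and OLS fitted on the default p=20 scenario."""
    return run_simulation_study(
        [default_scenarios()[0]],
        methods=("lncass_grouped", "lncass_flat", "ols"),
        seed=STUDY_SEED,
    )


@pytest.fixture(scope="session")
def p20_misassigned_study():
    """Same scenario refit with one predictor's group label flipped."""
    return run_simulation_study(
        [default_scenarios()[0]],
        methods=("lncass_grouped",),
        seed=STUDY_SEED,
        misassign_one=True,
    )


@pytest.fixture(scope="session")
def gam_scene():
    return generate_gam_scene(150, GAM_SEED)


@pytest.fixture(scope="session")
def gam_fit(gam_scene, hyper_default):
    config = GAMConfig(n_knots=5)
    model = build_hierarchical_gam(gam_scene.data, hyper_default, config)
    samples = run_mcmc(model, chains=4, warmup=1000, draws=1000, seed=GAM_SEED)
    return config, samples, summarize(samples)
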