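import numpy as np
import pandas as pd
import pytest

from timeclust import (RegressionConfig, SimulationConfig, TemplateAssignment,
                       build_design, circle_templates, fit_contrast, generate_study)


@pytest.fixture(scope="session")
def small_design():
    """3-arm design with 3 animals per arm per day (4 at day 27), 2 batches."""
    return build_design({1.0: 3, 3.0: 3, 7.0: 3, 13.0: 3, 27.0: 4}, n_batches=2)


@pytest.fixture(scope="session")
def planted_study():
    """Small high-amplitude study: 4 planted templates x 20 probes + 100 nulls."""
    tpls = circle_templates(4, amplitude=5 * 0.25, prefix="t")
    cfg = SimulationConfig(
        n_probes=180,
        assignments=[TemplateAssignment(t, 20, "ba") for t in tpls],
        noise_sd=0.25, seed=314,
    )
    em, design, truth = generate_study(cfg)
    return em, design, truth


@pytest.fixture(scope="session")
def planted_fit(planted_study):
    em, design, truth = planted_study
    fit = fit_contrast(em, design, RegressionConfig(contrast="ba", r2_threshold=0.5))
    return fit, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
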