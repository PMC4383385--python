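import numpy as np
import pandas as pd
import pytest

import medsem as ms


@pytest.fixture(scope="session")
def params5():
    """General-model generating parameters with covariates (study defaults)."""
    return ms.model5_params()


@pytest.fixture(scope="session")
def params4_nocov():
    return ms.model4_params(covariates=False)


@pytest.fixture(scope="session")
def model4_data():
    """Minimal-model dataset at moderate n, with covariates."""
    cfg = ms.study_config(n=20000, seed=101, model="model4")
    data, truth = ms.generate(cfg)
    return data, truth, cfg


@pytest.fixture(scope="session")
def model5_data():
    """General-model dataset (truth satisfies the no-interaction constraint)."""
    cfg = ms.study_config(n=20000, seed=7, model="model5")
    data, truth = ms.generate(cfg)
    return data, truth, cfg


@pytest.fixture(scope="session")
def model4_fit(model4_data):
    data, truth, cfg = model4_data
    return ms.fit_sem(data, ms.spec_for(cfg.params))


@pytest.fixture(scope="session")
def model5_fit(model5_data):
    data, truth, cfg = model5_data
    return ms.fit_sem(data, ms.spec_for(cfg.params))


def orthogonal_noise(rng, design, scale=1.0):
    """Noise exactly orthogonal to the column span of ``design``.

    OLS on data built with such residuals reproduces the generating
    coefficients to machine precision (exact interpolation).
    """
    raw = rng.normal(0.0, scale, len(design))
    q, _ = np.linalg.qr(design)
    return raw - q @ (q.T @ raw)
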