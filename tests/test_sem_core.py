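import dataclasses

import numpy as np
import pandas as pd
import pytest

import medsem as ms
from medsem.errors import (
    CollinearityError,
    InvalidInputError,
    MissingDataError,
)

from conftest import orthogonal_noise


# ----------------------------------------------------------------------
# specification validation
class TestSpec:
    def test_roles_must_be_distinct(self):
        with pytest.raises(InvalidInputError):
            ms.SEMSpec(x="x", m="x", y="y", l="l")

    def test_covariates_disjoint_from_roles(self):
        with pytest.raises(InvalidInputError):
            ms.SEMSpec(x="x", m="m", y="y", l="l", c=("x",))

    def test_lm_product_term_rejected(self):
        with pytest.raises(InvalidInputError, match="L\\*M"):
            ms.SEMSpec(x="x", m="m", y="y", l="l",
                       terms_y={"x", "m", "l", "lm"})

    def test_mandatory_terms(self):
        with pytest.raises(InvalidInputError):
            ms.SEMSpec(x="x", m="m", y="y", l="l", terms_m={"x"})
        with pytest.raises(InvalidInputError):
            ms.SEMSpec(x="x", m="m", y="y", l="l", terms_y={"x", "m"})

    def test_unknown_terms_rejected(self):
        with pytest.raises(InvalidInputError):
            ms.SEMSpec(x="x", m="m", y="y", l="l", terms_y={"x", "m", "l", "ml2"})

    def test_yaml_round_trip(self):
        spec = ms.SEMSpec(
            x="exposure", m="med", y="out", l="conf", c=("c1", "c2"),
            terms_m={"x", "l", "c", "xl"},
            terms_y={"x", "m", "l", "c", "m2", "l2", "xl"},
        )
        assert ms.SEMSpec.from_yaml(spec.to_yaml()) == spec

    def test_constrained_removes_only_outcome_terms(self):
        spec = ms.SEMSpec(x="x", m="m", y="y", l="l",
                          terms_m={"x", "l", "xl"},
                          terms_y={"x", "m", "l", "m2", "l2", "xl", "xm"})
        rg = spec.constrained("robins_greenland")
        assert "xm" not in rg.terms_y and "xl" in rg.terms_y
        pet = spec.constrained("petersen")
        assert pet.terms_y == frozenset({"x", "m", "l", "m2", "xm"})
        assert "xl" in pet.terms_m  # mediator equation untouched


# ----------------------------------------------------------------------
# fitting
def _interpolating_table(params, spec, n=400, seed=5):
    """Data whose residuals are exactly orthogonal to each design."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.4, n).astype(float)
    x[:2] = [0, 1]
    c = np.column_stack([rng.binomial(1, 0.5, n) for _ in spec.c]) \
        if spec.c else np.zeros((n, 0))
    Xl = np.column_stack([np.ones(n), x, c])
    l = params.l_mean(x, c) + orthogonal_noise(rng, Xl)
    cols_m = [np.ones(n), x, l] + [c[:, j] for j in range(c.shape[1])]
    if "xl" in spec.terms_m:
        cols_m.append(x * l)
    m = params.m_mean(x, l, c) + orthogonal_noise(rng, np.column_stack(cols_m))
    cols_y = [np.ones(n), x, m, l] + [c[:, j] for j in range(c.shape[1])]
    for t, arr in (("m2", m * m), ("l2", l * l), ("xl", x * l), ("xm", x * m)):
        if t in spec.terms_y:
            cols_y.append(arr)
    y = params.y_mean(x, m, l, c) + orthogonal_noise(rng, np.column_stack(cols_y))
    data = {f"c{j+1}": c[:, j] for j in range(c.shape[1])}
    data.update({"x": x, "l": l, "m": m, "y": y})
    return pd.DataFrame(data)


def test_exact_interpolation_recovers_coefficients(params5):
    """OLS recovers generating coefficients exactly when the injected
    residuals are orthogonal to the design."""
    spec = ms.spec_for(params5)
    data = _interpolating_table(params5, spec)
    fit = ms.fit_sem(data, spec)
    p, t = fit.params, params5
    for name in ("gamma0", "gamma_x", "alpha0", "alpha_x", "alpha_l",
                 "alpha_xl", "beta0", "beta_x", "beta_m", "beta_l",
                 "beta_mm", "beta_ll", "beta_xl", "beta_xm"):
        assert getattr(p, name) == pytest.approx(getattr(t, name), abs=1e-9)
    assert p.gamma_c == pytest.approx(t.gamma_c, abs=1e-9)
    assert p.beta_c == pytest.approx(t.beta_c, abs=1e-9)


def test_recovery_within_four_se():
    """Every coefficient of a n=5000 fit lies within 4 estimated SEs of its
    generating value."""
    cfg = ms.study_config(n=5000, seed=1)
    data, truth = ms.generate(cfg)
    spec = ms.spec_for(cfg.params)
    fit = ms.fit_sem(data, spec)
    truth_fit = ms.FittedSEM.from_params(spec, cfg.params)
    se = np.sqrt(fit.coef_cov.diagonal())
    z = np.abs(fit.theta - truth_fit.theta) / se
    assert np.all(z < 4.0), dict(zip(fit.coef_names, z))


def test_duplicated_covariate_raises_collinearity(model4_data):
    data = data_dup = model4_data[0].copy()
    data_dup["c1_copy"] = data_dup["c1"]
    spec = ms.SEMSpec(x="x", m="m", y="y", l="l", c=("c1", "c1_copy"))
    with pytest.raises(CollinearityError, match="c1"):
        ms.fit_sem(data_dup, spec)


def test_missing_values_rejected(model4_data):
    data = model4_data[0].copy()
    data.loc[3, "m"] = np.nan
    spec = ms.SEMSpec(x="x", m="m", y="y", l="l", c=("c1", "c2"))
    with pytest.raises(MissingDataError, match="complete-case"):
        ms.fit_sem(data, spec)


def test_nonbinary_exposure_rejected(model4_data):
    data = model4_data[0].copy()
    data["x"] = data["x"] + 0.5
    spec = ms.SEMSpec(x="x", m="m", y="y", l="l", c=("c1", "c2"))
    with pytest.raises(InvalidInputError, match="0/1"):
        ms.fit_sem(data, spec)


def test_missing_column_named(model4_data):
    spec = ms.SEMSpec(x="x", m="mediator", y="y", l="l")
    with pytest.raises(InvalidInputError, match="mediator"):
        ms.fit_sem(model4_data[0], spec)


def test_reduced_form_identity(model4_data):
    """For the minimal model the reduced-form X coefficient from regressing
    Y on (X, C) equals beta_x + alpha_x*beta_m + alpha_l*beta_m*gamma_x +
    beta_l*gamma_x exactly (nested least-squares algebra)."""
    import statsmodels.api as sm

    data, _, cfg = model4_data
    spec = ms.spec_for(cfg.params)
    fit = ms.fit_sem(data, spec)
    p = fit.params
    composed = (p.beta_x + p.alpha_x * p.beta_m
                + p.alpha_l * p.beta_m * p.gamma_x + p.beta_l * p.gamma_x)
    X = np.column_stack([np.ones(len(data)), data["x"], data["c1"], data["c2"]])
    reduced = sm.OLS(data["y"].to_numpy(), X).fit().params[1]
    assert reduced == pytest.approx(composed, abs=1e-10)


def test_residuals_orthogonal_to_regressors(model5_fit, model5_data):
    data, _, cfg = model5_data
    from medsem.sem_core import _design

    for eq in ("l", "m", "y"):
        resid = model5_fit.residuals[eq]
        assert abs(resid.mean()) < 1e-10
        _, X, _ = _design(eq, data, model5_fit.spec)
        assert np.max(np.abs(X.T @ resid)) / len(resid) < 1e-8


def test_coef_cov_symmetric_psd(model5_fit):
    V = model5_fit.coef_cov
    assert np.allclose(V, V.T)
    assert np.min(np.linalg.eigvalsh(V)) > -1e-12
    assert V.shape[0] == len(model5_fit.theta)


def test_refit_is_bit_reproducible(model5_data):
    data, _, cfg = model5_data
    spec = ms.spec_for(cfg.params)
    f1 = ms.fit_sem(data, spec)
    f2 = ms.fit_sem(data, spec)
    assert np.array_equal(f1.theta, f2.theta)
    assert np.array_equal(f1.coef_cov, f2.coef_cov)


def test_from_params_round_trip(params5):
    spec = ms.spec_for(params5)
    fit = ms.FittedSEM.from_params(spec, params5)
    assert fit.params_from_theta(fit.theta) == params5
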