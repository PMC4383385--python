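import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import medsem as ms
from medsem.combine import _point
from medsem.errors import IdentificationError, InvalidInputError

coef = st.floats(-1.0, 1.0, allow_nan=False, width=32)


def _simple_fit(**kw):
    spec = ms.SEMSpec(x="x", m="m", y="y", l="l")
    return ms.FittedSEM.from_params(spec, ms.SEMParameters(**kw))


# ----------------------------------------------------------------------
def test_hand_computed_path_products():
    fit = _simple_fit(gamma_x=0.5, alpha_x=0.3, alpha_l=0.2,
                      beta_x=0.2, beta_l=0.4, beta_m=0.5)
    est = ms.combine_simple(fit)
    assert est.pnde == pytest.approx(0.40)
    assert est.tnie == pytest.approx(0.20)
    assert est.tce == pytest.approx(0.60)
    assert est.cde == pytest.approx(0.40)


@settings(derandomize=True, max_examples=50)
@given(gx=coef, ax=coef, al=coef, bx=coef, bl=coef)
def test_zero_mediator_coefficient_severs_indirect_path(gx, ax, al, bx, bl):
    fit = _simple_fit(gamma_x=gx, alpha_x=ax, alpha_l=al,
                      beta_x=bx, beta_l=bl, beta_m=0.0)
    est = ms.combine_simple(fit)
    assert est.tnie == 0.0
    assert est.pnde == pytest.approx(est.tce, abs=1e-14)


@settings(derandomize=True, max_examples=100)
@given(gx=coef, ax=coef, al=coef, bx=coef, bl=coef, bm=coef)
def test_path_tracing_identity(gx, ax, al, bx, bl, bm):
    """The combination equals the sum of products of coefficients along the
    directed paths, and TNIE = TCE - PNDE holds identically."""
    fit = _simple_fit(gamma_x=gx, alpha_x=ax, alpha_l=al,
                      beta_x=bx, beta_l=bl, beta_m=bm)
    est = ms.combine_simple(fit)
    indirect = ax * bm + gx * al * bm
    direct = bx + gx * bl
    assert est.tnie == pytest.approx(indirect, abs=1e-12)
    assert est.pnde == pytest.approx(direct, abs=1e-12)
    assert est.tnie == pytest.approx(est.tce - est.pnde, abs=1e-12)


def test_tnie_linear_in_beta_m():
    base = dict(gamma_x=0.5, alpha_x=0.3, alpha_l=0.2, beta_x=0.2, beta_l=0.4)
    t1 = ms.combine_simple(_simple_fit(beta_m=0.25, **base)).tnie
    t2 = ms.combine_simple(_simple_fit(beta_m=0.50, **base)).tnie
    t3 = ms.combine_simple(_simple_fit(beta_m=1.00, **base)).tnie
    assert t2 == pytest.approx(2 * t1)
    assert t3 == pytest.approx(4 * t1)


def test_combine_simple_refuses_general_spec(model5_fit):
    with pytest.raises(InvalidInputError, match="combine_general"):
        ms.combine_simple(model5_fit)


# ----------------------------------------------------------------------
def test_general_degenerates_to_simple(model4_fit):
    """With all interaction/quadratic coefficients zero the general closed
    form equals the path-tracing form to machine precision."""
    simple = ms.combine_simple(model4_fit)
    general = ms.combine_general(model4_fit, "auto")
    assert general.assumption == "both"
    for name in ("tce", "pnde", "tnie", "cde"):
        assert getattr(general, name) == pytest.approx(
            getattr(simple, name), abs=1e-13)
        assert getattr(general, f"se_{name}") == pytest.approx(
            getattr(simple, f"se_{name}"), rel=1e-6)


def test_general_matches_mc_at_true_parameters():
    """Closed form vs Monte Carlo integration of the counterfactual
    integrals at the spec's general parameter set (no covariates)."""
    params = ms.model5_params(covariates=False)
    spec = ms.spec_for(params, c_names=())
    fit = ms.FittedSEM.from_params(spec, params)
    exact = ms.combine_general(fit, "robins_greenland")
    mc = ms.mc_estimands(fit, ms.MCSettings(seed=42, n_mc=1_000_000))
    for name in ("tce", "pnde", "tnie", "cde"):
        diff = abs(getattr(exact, name) - getattr(mc, name))
        assert diff < 3 * getattr(mc, f"se_{name}"), name


def test_tnie_equals_tce_minus_pnde_general(model5_fit):
    est = ms.combine_general(model5_fit, "robins_greenland")
    assert est.tnie == pytest.approx(est.tce - est.pnde, abs=1e-12)


def test_cde_affine_in_m_with_slope_beta_xm():
    params = dataclasses.replace(
        ms.model5_params(covariates=False), beta_xm=0.11,
        beta_ll=0.0, beta_xl=0.0)  # petersen-compatible
    spec = ms.spec_for(params, c_names=())
    fit = ms.FittedSEM.from_params(spec, params)
    cde = {m: ms.combine_general(fit, "petersen", cde_m_level=m).cde
           for m in (-1.0, 0.0, 2.0)}
    slope1 = (cde[0.0] - cde[-1.0]) / 1.0
    slope2 = (cde[2.0] - cde[0.0]) / 2.0
    assert slope1 == pytest.approx(params.beta_xm, abs=1e-12)
    assert slope2 == pytest.approx(params.beta_xm, abs=1e-12)


def test_cde_constant_in_m_under_no_interaction(model5_fit):
    cde = [ms.combine_general(model5_fit, "robins_greenland", cde_m_level=m).cde
           for m in (-2.0, 0.0, 3.0)]
    assert max(cde) - min(cde) < 1e-12


# ----------------------------------------------------------------------
# identification constraint enforcement
def test_rg_violation_names_offending_term():
    params = dataclasses.replace(ms.model5_params(covariates=False),
                                 beta_xm=0.2)
    fit = ms.FittedSEM.from_params(ms.spec_for(params, c_names=()), params)
    with pytest.raises(IdentificationError, match="xm"):
        ms.combine_general(fit, "robins_greenland")


def test_petersen_violation_names_offending_terms(model5_fit):
    with pytest.raises(IdentificationError, match="l2"):
        ms.combine_general(model5_fit, "petersen")


def test_auto_fails_when_neither_holds():
    params = dataclasses.replace(ms.model5_params(covariates=False),
                                 beta_xm=0.2)
    fit = ms.FittedSEM.from_params(ms.spec_for(params, c_names=()), params)
    with pytest.raises(IdentificationError, match="neither"):
        ms.combine_general(fit, "auto")


# ----------------------------------------------------------------------
# delta-method standard errors
def test_delta_se_hand_example():
    """PNDE = beta_x + beta_l*gamma_x with diagonal V gives
    Var = 0.01 + 1^2*0.04 + 0.5^2*0.09 = 0.0725."""
    fit = _simple_fit(gamma_x=1.0, beta_x=0.2, beta_l=0.5, beta_m=0.3)
    V = np.zeros((len(fit.theta), len(fit.theta)))
    idx = {nt: i for i, nt in enumerate(fit.coef_names)}
    V[idx[("y", "x")], idx[("y", "x")]] = 0.01
    V[idx[("y", "l")], idx[("y", "l")]] = 0.04
    V[idx[("l", "x")], idx[("l", "x")]] = 0.09
    fit.coef_cov = V
    se = ms.delta_se(fit, "pnde")
    assert se == pytest.approx(math.sqrt(0.0725), rel=1e-6)
    assert se == pytest.approx(0.2693, abs=5e-4)


def test_delta_se_zero_covariance(model5_fit):
    fit = ms.FittedSEM.from_params(model5_fit.spec, model5_fit.params,
                                   covariate_rows=model5_fit.covariate_rows)
    for name in ("tce", "pnde", "tnie", "cde"):
        assert ms.delta_se(fit, name, "robins_greenland") == 0.0


def test_delta_se_nan_covariance_warns(model4_fit):
    fit = ms.FittedSEM.from_params(model4_fit.spec, model4_fit.params)
    fit.coef_cov = np.full_like(fit.coef_cov, np.nan)
    with pytest.warns(RuntimeWarning, match="NaN"):
        se = ms.delta_se(fit, "tnie")
    assert np.isnan(se)


def test_delta_se_unknown_estimand(model4_fit):
    with pytest.raises(InvalidInputError):
        ms.delta_se(model4_fit, "nde")


# ----------------------------------------------------------------------
def test_robust_to_unmeasured_ly_confounding():
    """With an unmeasured L-Y confounder U, the path-tracing PNDE and TNIE
    stay unbiased across replicates even though beta_l itself is biased."""
    u = ms.UConfig(lambda_l=0.7, lambda_y=0.7, sd_u=1.0)
    n_rep, est, bl = 60, [], []
    for r in range(n_rep):
        cfg = ms.study_config(n=8000, seed=5000 + r, model="model4", u_config=u)
        data, truth = ms.generate(cfg)
        fit = ms.fit_sem(data, ms.spec_for(cfg.params))
        e = ms.combine_simple(fit)
        est.append([e.pnde, e.tnie])
        bl.append(fit.params.beta_l)
    est = np.asarray(est)
    truth_vals = np.array([truth.true_pnde, truth.true_tnie])
    mc_se = est.std(axis=0, ddof=1) / math.sqrt(n_rep)
    assert np.all(np.abs(est.mean(axis=0) - truth_vals) < 3 * mc_se)
    # beta_l is badly biased by the unmeasured confounder
    bl = np.asarray(bl)
    bl_bias = bl.mean() - 0.03
    assert abs(bl_bias) > 5 * bl.std(ddof=1) / math.sqrt(n_rep)


def test_prop_mediated_flagged_unstable_when_tce_ci_covers_zero():
    fit = _simple_fit(gamma_x=0.0, alpha_x=0.5, beta_m=0.01, beta_x=-0.005)
    V = np.eye(len(fit.theta)) * 0.25  # huge SEs -> CI covers zero
    fit.coef_cov = V
    est = ms.combine_simple(fit)
    assert est.prop_mediated_unstable
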