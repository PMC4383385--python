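"""Estimation by combination: closed-form mediation estimands from SEM fits.

With an exposure-induced intermediate confounder the natural direct and
indirect effects are identified only under a parametric restriction.  Two
are supported:

``robins_greenland``
    no individual-level exposure--mediator interaction on the outcome;
    for the linear system this holds iff ``beta_xm = 0``.
``petersen``
    the controlled direct effect does not vary with M(0) within covariate
    strata; for the linear system this holds iff ``beta_ll = beta_xl = 0``.

Under either restriction the mediation-formula integrals

.. math::

    \\mathrm{PNDE} = \\int_c \\int_{l'} \\int_m \\Big[ \\int_l
        \\{E(Y|1,m,l,c) f_L(l|1,c) - E(Y|0,m,l,c) f_L(l|0,c)\\}\\,dl \\Big]
        f_M(m|l',0,c)\\, f_L(l'|0,c)\\, dm\\, dl'\\, f_C(c)\\, dc

(and the analogous TNIE and CDE expressions) can be evaluated analytically:
the outcome equation is quadratic with no ``L*M`` product, ``L(x) | c`` is
Gaussian with mean :math:`\\mu_L(x,c)` and variance :math:`\\sigma_l^2`, and
``M(x') | c`` is Gaussian with mean
:math:`\\mu_M(x',c) = \\alpha_0 + \\alpha_x x' +
(\\alpha_l + \\alpha_{xl} x')\\mu_L(x',c) + \\alpha_c'c` and variance
:math:`(\\alpha_l + \\alpha_{xl} x')^2 \\sigma_l^2 + \\sigma_m^2`, so the
first two moments of ``L(x)`` and ``M(x')`` given ``c`` suffice.  Writing

.. math::

    \\eta(x, x', c) = \\beta_0 + \\beta_x x + \\beta_c' c
        + (\\beta_l + \\beta_{xl} x)\\, E[L(x)|c]
        + \\beta_{ll}\\, E[L(x)^2|c]
        + (\\beta_m + \\beta_{xm} x)\\, E[M(x')|c]
        + \\beta_{mm}\\, E[M(x')^2|c],

the estimands are PNDE = avg_c{eta(1,0,c) - eta(0,0,c)},
TNIE = avg_c{eta(1,1,c) - eta(1,0,c)}, TCE = PNDE + TNIE, and CDE(m) fixes
the mediator while still standardizing over ``L(x) | c``.  Covariate
standardization is empirical: the per-``c`` closed form is averaged over the
observed covariate rows.  For the minimal model every nonlinearity vanishes
and the expressions collapse to the familiar path-tracing products
PNDE = CDE(m) = beta_x + beta_l*gamma_x and
TNIE = beta_m*(alpha_x + alpha_l*gamma_x).

Standard errors use the delta method: SE = sqrt(g' V g) with g the gradient
of the combination with respect to the stacked coefficient vector (central
finite differences, relative step 1e-6) and V the block-diagonal OLS
coefficient covariance.  Uncertainty in the residual variances (which enter
through the second moments) is not propagated; the bootstrap covers it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import IdentificationError, InvalidInputError
from .sem_core import FittedSEM, SEMParameters

__all__ = [
    "ASSUMPTIONS",
    "MediationEstimates",
    "combine_simple",
    "combine_general",
    "delta_se",
    "resolve_assumption",
    "estimands_from_params",
]

#: supported identification-assumption labels (``"auto"`` defers to the
#: fitted spec / diagnostics; a resolved value of ``"both"`` means the fit
#: satisfies both constraint sets, i.e. the minimal model)
ASSUMPTIONS = ("robins_greenland", "petersen", "auto")

_Z975 = float(stats.norm.ppf(0.975))
_ESTIMANDS = ("tce", "pnde", "tnie", "cde")


@dataclass
class MediationEstimates:
    """Point estimates, SEs and 95% CIs for TCE, PNDE, TNIE and CDE(m).

    ``tnie == tce - pnde`` holds exactly by construction.  For
    ``method="monte_carlo"`` the SEs are Monte Carlo integration errors, not
    sampling standard errors (use the bootstrap for the latter).
    ``prop_mediated`` is TNIE/TCE and is flagged unstable when the TCE
    confidence interval covers zero (a ratio with a near-zero denominator is
    ill-behaved).
    """

    tce: float
    pnde: float
    tnie: float
    cde: float
    cde_m_level: float
    prop_mediated: float
    prop_mediated_unstable: bool
    se_tce: float
    se_pnde: float
    se_tnie: float
    se_cde: float
    ci_tce: tuple[float, float]
    ci_pnde: tuple[float, float]
    ci_tnie: tuple[float, float]
    ci_cde: tuple[float, float]
    method: str
    assumption: str
    mc_error: dict | None = None

    def to_records(self) -> list[dict]:
        """Serialize as one JSON-ready record per estimand."""
        out = []
        for name in _ESTIMANDS:
            ci = getattr(self, f"ci_{name}")
            out.append(
                {
                    "estimand": name,
                    "value": float(getattr(self, name)),
                    "se": float(getattr(self, f"se_{name}")),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "method": self.method,
                    "assumption": self.assumption,
                    "cde_m_level": float(self.cde_m_level),
                }
            )
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_records(), **kwargs)


# ----------------------------------------------------------------------
def _eta_rows(p: SEMParameters, x: float, xp: float, c_rows: np.ndarray) -> np.ndarray:
    """eta(x, x', c) evaluated at each covariate row."""
    mu_l = p.l_mean(x, c_rows)
    mu_lp = p.l_mean(xp, c_rows)
    el2 = mu_l**2 + p.sigma2_l
    slope = p.alpha_l + p.alpha_xl * xp
    mu_m = p.m_mean(xp, mu_lp, c_rows)
    em2 = mu_m**2 + slope**2 * p.sigma2_l + p.sigma2_m
    return (
        p.beta0
        + p.beta_x * x
        + c_rows @ np.asarray(p.beta_c)
        + (p.beta_l + p.beta_xl * x) * mu_l
        + p.beta_ll * el2
        + (p.beta_m + p.beta_xm * x) * mu_m
        + p.beta_mm * em2
    )


def _cde_rows(p: SEMParameters, m: float, c_rows: np.ndarray) -> np.ndarray:
    """CDE(m | c) per covariate row; the sigma_l^2 terms cancel between arms."""
    mu_l1 = p.l_mean(1.0, c_rows)
    mu_l0 = p.l_mean(0.0, c_rows)
    return (
        p.beta_x
        + p.beta_xm * m
        + (p.beta_l + p.beta_xl) * mu_l1
        - p.beta_l * mu_l0
        + p.beta_ll * (mu_l1**2 - mu_l0**2)
    )


def _point(p: SEMParameters, c_rows: np.ndarray, cde_m: float) -> np.ndarray:
    """(tce, pnde, tnie, cde) averaged over covariate rows."""
    e00 = _eta_rows(p, 0.0, 0.0, c_rows)
    e10 = _eta_rows(p, 1.0, 0.0, c_rows)
    e11 = _eta_rows(p, 1.0, 1.0, c_rows)
    pnde = float(np.mean(e10 - e00))
    tnie = float(np.mean(e11 - e10))
    cde = float(np.mean(_cde_rows(p, cde_m, c_rows)))
    return np.array([pnde + tnie, pnde, tnie, cde])


# ----------------------------------------------------------------------
def resolve_assumption(params: SEMParameters, assumption: str = "auto") -> str:
    """Validate/resolve an identification assumption against fitted values.

    Raises :class:`~medsem.errors.IdentificationError` listing the offending
    nonzero terms when the declared assumption's zero-constraints are
    violated.  ``"auto"`` picks whichever constraint set the parameters
    satisfy (``"both"`` if both do).
    """
    rg_bad = [] if params.beta_xm == 0 else ["xm"]
    pet_bad = [
        term
        for term, value in (("l2", params.beta_ll), ("xl", params.beta_xl))
        if value != 0
    ]
    if assumption == "robins_greenland":
        if rg_bad:
            raise IdentificationError(
                "robins_greenland requires beta_xm = 0; nonzero terms: "
                f"{rg_bad}. Refit with the constrained spec "
                "(SEMSpec.constrained('robins_greenland')) or use the "
                "petersen assumption."
            )
        return assumption
    if assumption == "petersen":
        if pet_bad:
            raise IdentificationError(
                "petersen requires beta_ll = beta_xl = 0; nonzero terms: "
                f"{pet_bad}. Refit with the constrained spec "
                "(SEMSpec.constrained('petersen')) or use the "
                "robins_greenland assumption."
            )
        return assumption
    if assumption == "auto":
        if not rg_bad and not pet_bad:
            return "both"
        if not rg_bad:
            return "robins_greenland"
        if not pet_bad:
            return "petersen"
        raise IdentificationError(
            "neither identification assumption holds for this fit "
            f"(nonzero terms: {rg_bad + pet_bad}); with an intermediate "
            "confounder the natural effects require either beta_xm = 0 or "
            "beta_ll = beta_xl = 0"
        )
    raise InvalidInputError(
        f"unknown assumption {assumption!r}; expected one of {ASSUMPTIONS}"
    )


def _delta_grad_ses(fit: FittedSEM, func: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Delta-method SEs of the vector-valued ``func(theta)``."""
    V = np.asarray(fit.coef_cov, float)
    n_out = len(func(fit.theta))
    if V.size == 0 or not np.all(np.isfinite(V)):
        warnings.warn(
            "coefficient covariance is unavailable or non-finite; "
            "delta-method SEs are reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.full(n_out, np.nan)
    theta = np.asarray(fit.theta, float)
    J = np.empty((n_out, len(theta)))
    for i in range(len(theta)):
        h = 1e-6 * max(1.0, abs(theta[i]))
        up = theta.copy()
        up[i] += h
        down = theta.copy()
        down[i] -= h
        J[:, i] = (func(up) - func(down)) / (2 * h)
    var = np.einsum("ki,ij,kj->k", J, V, J)
    # guard tiny negative values from finite-difference noise
    return np.sqrt(np.clip(var, 0.0, None))


def _package(
    fit: FittedSEM, vals: np.ndarray, cde_m: float, method: str, assumption: str
) -> MediationEstimates:
    func = lambda th: _point(fit.params_from_theta(th), fit.covariate_rows, cde_m)
    ses = _delta_grad_ses(fit, func)
    cis = [(v - _Z975 * s, v + _Z975 * s) for v, s in zip(vals, ses)]
    tce = vals[0]
    prop = float(vals[2] / tce) if tce != 0 else float("nan")
    unstable = bool(cis[0][0] <= 0.0 <= cis[0][1]) or not np.isfinite(prop)
    return MediationEstimates(
        tce=float(vals[0]),
        pnde=float(vals[1]),
        tnie=float(vals[2]),
        cde=float(vals[3]),
        cde_m_level=float(cde_m),
        prop_mediated=prop,
        prop_mediated_unstable=unstable,
        se_tce=float(ses[0]),
        se_pnde=float(ses[1]),
        se_tnie=float(ses[2]),
        se_cde=float(ses[3]),
        ci_tce=cis[0],
        ci_pnde=cis[1],
        ci_tnie=cis[2],
        ci_cde=cis[3],
        method=method,
        assumption=assumption,
    )


def combine_simple(fit: FittedSEM, cde_m_level: float = 0.0) -> MediationEstimates:
    """Path-tracing estimands for the minimal (no-interaction) model.

    PNDE = CDE(m) = beta_x + beta_l*gamma_x for every m, TNIE =
    beta_m*(alpha_x + alpha_l*gamma_x), TCE = PNDE + TNIE.  Raises on any
    spec with interaction or quadratic terms (use :func:`combine_general`).
    """
    if not fit.spec.is_model4:
        raise InvalidInputError(
            "combine_simple requires the minimal model (no interactions or "
            "quadratics); use combine_general for this spec"
        )
    p = fit.params
    pnde = p.beta_x + p.beta_l * p.gamma_x
    tnie = p.beta_m * (p.alpha_x + p.alpha_l * p.gamma_x)
    vals = np.array([pnde + tnie, pnde, tnie, pnde])
    return _package(fit, vals, cde_m_level, "combination", "both")


def combine_general(
    fit: FittedSEM, assumption: str = "auto", cde_m_level: float = 0.0
) -> MediationEstimates:
    """Closed-form estimands for the general linear SEM.

    The fitted spec must satisfy the declared assumption's zero-constraints
    (refit with ``spec.constrained(assumption)`` if needed).  CDE(m) does
    not require either assumption and is always returned.
    """
    resolved = resolve_assumption(fit.params, assumption)
    vals = _point(fit.params, fit.covariate_rows, cde_m_level)
    return _package(fit, vals, cde_m_level, "combination", resolved)


def delta_se(
    fit: FittedSEM,
    estimand: str,
    assumption: str = "auto",
    cde_m_level: float = 0.0,
) -> float:
    """Delta-method SE of one estimand (``tce``/``pnde``/``tnie``/``cde``)."""
    if estimand not in _ESTIMANDS:
        raise InvalidInputError(
            f"unknown estimand {estimand!r}; expected one of {_ESTIMANDS}"
        )
    resolve_assumption(fit.params, assumption)
    func = lambda th: _point(fit.params_from_theta(th), fit.covariate_rows, cde_m_level)
    ses = _delta_grad_ses(fit, func)
    return float(ses[_ESTIMANDS.index(estimand)])


# ----------------------------------------------------------------------
def estimands_from_params(
    params: SEMParameters,
    c_config: Sequence = (),
    cde_m_level: float = 0.0,
) -> dict[str, float]:
    """Closed-form estimands at known parameters, standardized over a
    covariate *distribution* rather than observed rows.

    ``c_config`` is a sequence of independent covariate distributions
    (:class:`~medsem.simulate.Bernoulli` / :class:`~medsem.simulate.Normal`,
    or any object with ``mean``/``var`` attributes).  Because eta(x, x', c)
    is quadratic in ``c`` with the same linear map in both arms, the average
    over ``c`` only involves each covariate's mean and variance, so the
    standardization is exact.  This is the route used to check the closed
    form against the quadrature truth oracle.
    """
    if len(c_config) != params.n_covariates:
        raise InvalidInputError(
            f"params carry {params.n_covariates} covariate coefficients but "
            f"c_config has {len(c_config)} entries"
        )
    mu_c = np.array([d.mean for d in c_config], float)
    var_c = np.array([d.var for d in c_config], float)

    gamma_c = np.asarray(params.gamma_c)
    alpha_c = np.asarray(params.alpha_c)
    beta_c = np.asarray(params.beta_c)
    p = params

    def mu_l_bar(x: float) -> float:
        return p.gamma0 + p.gamma_x * x + float(gamma_c @ mu_c)

    var_l_c = float(gamma_c**2 @ var_c) if len(mu_c) else 0.0

    def eta_bar(x: float, xp: float) -> float:
        mul = mu_l_bar(x)
        el2 = mul**2 + var_l_c + p.sigma2_l
        slope = p.alpha_l + p.alpha_xl * xp
        mum = (
            p.alpha0
            + p.alpha_x * xp
            + slope * mu_l_bar(xp)
            + float(alpha_c @ mu_c)
        )
        h = slope * gamma_c + alpha_c  # linear map c -> mu_M(x', c)
        var_m_c = float(h**2 @ var_c) if len(mu_c) else 0.0
        em2 = mum**2 + var_m_c + slope**2 * p.sigma2_l + p.sigma2_m
        return (
            p.beta0
            + p.beta_x * x
            + float(beta_c @ mu_c)
            + (p.beta_l + p.beta_xl * x) * mul
            + p.beta_ll * el2
            + (p.beta_m + p.beta_xm * x) * mum
            + p.beta_mm * em2
        )

    pnde = eta_bar(1, 0) - eta_bar(0, 0)
    tnie = eta_bar(1, 1) - eta_bar(1, 0)
    # E[mu_L(1,c)^2 - mu_L(0,c)^2]: the covariate-variance parts cancel
    cde = (
        p.beta_x
        + p.beta_xm * cde_m_level
        + (p.beta_l + p.beta_xl) * mu_l_bar(1)
        - p.beta_l * mu_l_bar(0)
        + p.beta_ll * (mu_l_bar(1) ** 2 - mu_l_bar(0) ** 2)
    )
    return {
        "tce": pnde + tnie,
        "pnde": pnde,
        "tnie": tnie,
        "cde": cde,
    }
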