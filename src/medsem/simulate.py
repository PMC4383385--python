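"""Synthetic data from the structural model, plus an exact truth oracle.

The generator draws from the full recursive system: binary exposure X
(default prevalence 0.19), baseline covariates C (default two Bernoulli
covariates with p = 0.55 and 0.13), Gaussian intermediate confounder L,
mediator M and outcome Y on standardized scales, with optional

* cross-equation error correlation ``rho`` between eps_m and eps_y
  (representing unmeasured mediator--outcome confounding), and
* an unmeasured standard-normal confounder U of the L--Y relationship,
  entering L with coefficient ``lambda_l`` and Y with ``lambda_y``
  (U is excluded from the returned table -- it is unmeasured -- but recorded
  in the truth object).

Default coefficient values emulate a cohort-style analysis of a binary
early-life exposure whose effect on a standardized behavioural outcome is
partly mediated by a standardized anthropometric mediator, with birth-size
as the exposure-induced confounder: small direct effect, moderate mediated
effect, mild curvature and exposure--confounder interaction.

:func:`truth_oracle` returns *exact* estimand values for any parameter set
by Gauss--Hermite quadrature over the Gaussian laws of L(x), L(x') and
M(x') and exact averaging over the covariate distribution.  It is
deliberately simulation-free and independent of the closed-form moment
algebra in :mod:`medsem.combine`, so it can serve as that module's oracle.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import InvalidInputError
from .sem_core import SEMParameters, SEMSpec

__all__ = [
    "Bernoulli",
    "Normal",
    "UConfig",
    "GeneratorConfig",
    "SimulationTruth",
    "generate",
    "truth_oracle",
    "model4_params",
    "model5_params",
    "study_config",
    "spec_for",
    "DEFAULT_C_CONFIG",
]


@dataclass(frozen=True)
class Bernoulli:
    """Bernoulli(p) covariate distribution."""

    p: float

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise InvalidInputError(f"Bernoulli p must be in (0, 1), got {self.p}")

    @property
    def mean(self) -> float:
        return self.p

    @property
    def var(self) -> float:
        return self.p * (1 - self.p)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.binomial(1, self.p, n).astype(float)

    def atoms(self, order: int) -> tuple[np.ndarray, np.ndarray]:
        return np.array([0.0, 1.0]), np.array([1 - self.p, self.p])


@dataclass(frozen=True)
class Normal:
    """Normal(mean, sd) covariate distribution."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidInputError(f"Normal sd must be > 0, got {self.sd}")

    @property
    def var(self) -> float:
        return self.sd**2

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, n)

    def atoms(self, order: int) -> tuple[np.ndarray, np.ndarray]:
        t, w = np.polynomial.hermite.hermgauss(order)
        return self.mean + math.sqrt(2.0) * self.sd * t, w / math.sqrt(math.pi)


@dataclass(frozen=True)
class UConfig:
    """Unmeasured L--Y confounder: U ~ Normal(0, sd_u^2), L += lambda_l*U,
    Y += lambda_y*U."""

    lambda_l: float
    lambda_y: float
    sd_u: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_u <= 0:
            raise InvalidInputError(f"sd_u must be > 0, got {self.sd_u}")


#: study-condition covariates: two binary background confounders
DEFAULT_C_CONFIG: tuple = (Bernoulli(0.55), Bernoulli(0.13))


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw one synthetic dataset.

    ``x_logit_c``: optional per-covariate log-odds coefficients making the
    exposure depend on C through a logistic link (intercept = logit(p_x));
    by default X is marginally Bernoulli(p_x), independent of C.
    """

    n: int
    params: SEMParameters
    seed: int
    p_x: float = 0.19
    c_config: tuple = ()
    u_config: UConfig | None = None
    x_logit_c: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError(f"n must be >= 1, got {self.n}")
        if not 0 < self.p_x < 1:
            raise InvalidInputError(f"p_x must be in (0, 1), got {self.p_x}")
        if self.seed is None:
            raise InvalidInputError("GeneratorConfig.seed is mandatory")
        object.__setattr__(self, "c_config", tuple(self.c_config))
        if self.params.n_covariates != len(self.c_config):
            raise InvalidInputError(
                f"params carry {self.params.n_covariates} covariate "
                f"coefficients but c_config has {len(self.c_config)} entries"
            )
        if self.x_logit_c is not None:
            object.__setattr__(self, "x_logit_c", tuple(self.x_logit_c))
            if len(self.x_logit_c) != len(self.c_config):
                raise InvalidInputError(
                    "x_logit_c must have one coefficient per covariate"
                )


@dataclass
class SimulationTruth:
    """Generating parameters plus exact estimand values.

    ``params_effective`` folds the unmeasured confounder's contribution into
    the L-equation error variance (sigma2_l + lambda_l^2 sd_u^2); the
    estimand values are computed from it because U shifts no mean.
    ``errors`` holds the realized error draws when produced by
    :func:`generate` (for generator self-consistency checks); it is excluded
    from serialization.
    """

    params: SEMParameters
    params_effective: SEMParameters
    c_config: tuple
    true_tce: float
    true_pnde: float
    true_tnie: float
    true_cde: float
    cde_m_level: float
    assumption_used: str | None = None
    errors: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "params": asdict(self.params),
            "true_tce": self.true_tce,
            "true_pnde": self.true_pnde,
            "true_tnie": self.true_tnie,
            "true_cde": self.true_cde,
            "cde_m_level": self.cde_m_level,
            "assumption_used": self.assumption_used,
            "c_config": [repr(d) for d in self.c_config],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ----------------------------------------------------------------------
# default parameter sets (study conditions)
def model5_params(covariates: bool = True) -> SEMParameters:
    """General-model generating parameters (standardized scales).

    The no-interaction identifying constraint holds in truth (beta_xm = 0)
    while the constant-CDE one does not (beta_ll, beta_xl != 0).
    """
    c = dict(
        gamma_c=(-0.04, -0.04), alpha_c=(0.10, -0.02), beta_c=(-0.011, 0.207)
    ) if covariates else {}
    return SEMParameters(
        gamma0=0.1,
        gamma_x=0.13,
        alpha0=0.0,
        alpha_x=0.55,
        alpha_l=0.05,
        alpha_xl=0.1,
        beta0=0.0,
        beta_x=0.07,
        beta_m=0.31,
        beta_mm=0.04,
        beta_l=0.03,
        beta_ll=0.03,
        beta_xl=0.08,
        beta_xm=0.0,
        sigma2_l=1.0,
        sigma2_m=1.0,
        sigma2_y=1.0,
        **c,
    )


def model4_params(covariates: bool = True, rho: float = 0.0) -> SEMParameters:
    """Minimal-model generating parameters (no interactions/quadratics)."""
    base = model5_params(covariates)
    return replace(base, alpha_xl=0.0, beta_mm=0.0, beta_ll=0.0, beta_xl=0.0,
                   beta_xm=0.0, rho=rho)


def study_config(
    n: int = 2749,
    seed: int = 0,
    model: str = "model5",
    covariates: bool = True,
    u_config: UConfig | None = None,
    rho: float = 0.0,
) -> GeneratorConfig:
    """Convenience config at the default study conditions."""
    if model == "model5":
        params = replace(model5_params(covariates), rho=rho)
    elif model == "model4":
        params = model4_params(covariates, rho=rho)
    else:
        raise InvalidInputError(f"unknown preset model {model!r}")
    return GeneratorConfig(
        n=n,
        params=params,
        seed=seed,
        p_x=0.19,
        c_config=DEFAULT_C_CONFIG if covariates else (),
        u_config=u_config,
    )


def spec_for(params: SEMParameters, c_names: Sequence[str] | None = None) -> SEMSpec:
    """SEMSpec matching the generator's column names and the nonzero terms
    of a parameter set."""
    if c_names is None:
        c_names = tuple(f"c{i + 1}" for i in range(params.n_covariates))
    terms_m = {"x", "l"} | ({"c"} if c_names else set())
    if params.alpha_xl != 0:
        terms_m.add("xl")
    terms_y = {"x", "m", "l"} | ({"c"} if c_names else set())
    for term, value in (
        ("m2", params.beta_mm),
        ("l2", params.beta_ll),
        ("xl", params.beta_xl),
        ("xm", params.beta_xm),
    ):
        if value != 0:
            terms_y.add(term)
    return SEMSpec(
        x="x", m="m", y="y", l="l", c=tuple(c_names),
        terms_m=frozenset(terms_m), terms_y=frozenset(terms_y),
    )


# ----------------------------------------------------------------------
def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw one dataset and return it with its truth record.

    All randomness comes from one seeded generator in a fixed draw order,
    so identical configs give identical tables.  The unmeasured confounder
    U never appears in the returned columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    p = config.params

    c_cols = [dist.draw(rng, n) for dist in config.c_config]
    c = np.column_stack(c_cols) if c_cols else np.zeros((n, 0))

    if config.x_logit_c is not None:
        prob = expit(logit(config.p_x) + c @ np.asarray(config.x_logit_c))
        x = rng.binomial(1, prob).astype(float)
    else:
        x = rng.binomial(1, config.p_x, n).astype(float)

    if config.u_config is not None:
        u = rng.normal(0.0, config.u_config.sd_u, n)
        lam_l, lam_y = config.u_config.lambda_l, config.u_config.lambda_y
    else:
        u = np.zeros(n)
        lam_l = lam_y = 0.0

    eps_l = rng.normal(0.0, math.sqrt(p.sigma2_l), n)
    l = p.l_mean(x, c) + lam_l * u + eps_l

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps_m = math.sqrt(p.sigma2_m) * z1
    eps_y = math.sqrt(p.sigma2_y) * (p.rho * z1 + math.sqrt(1 - p.rho**2) * z2)
    m = p.m_mean(x, l, c) + eps_m
    y = p.y_mean(x, m, l, c) + lam_y * u + eps_y

    columns = {f"c{i + 1}": col for i, col in enumerate(c_cols)}
    columns.update({"x": x, "l": l, "m": m, "y": y})
    data = pd.DataFrame(columns)

    eff = replace(p, sigma2_l=p.sigma2_l + lam_l**2 * (
        config.u_config.sd_u**2 if config.u_config else 0.0))
    truth = truth_oracle(eff, config.c_config)
    truth.params = p
    truth.errors = {"eps_l": eps_l, "eps_m": eps_m, "eps_y": eps_y, "u": u}
    return data, truth


# ----------------------------------------------------------------------
def _c_atoms(c_config: Sequence, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretize the covariate distribution into (atoms, weights); exact
    for Bernoulli covariates, Gauss--Hermite for normal ones."""
    if not c_config:
        return np.zeros((1, 0)), np.ones(1)
    per_cov = [dist.atoms(order) for dist in c_config]
    values = [v for v, _ in per_cov]
    weights = [w for _, w in per_cov]
    combos = np.array(list(itertools.product(*values)), float)
    w = np.prod(np.array(list(itertools.product(*weights))), axis=1)
    return combos, w


def _eta_quad(p: SEMParameters, x: float, xp: float, c_vec: np.ndarray, order: int) -> float:
    """E{Y(x, M(x')) | C=c} by tensor Gauss--Hermite quadrature over
    l ~ L(x)|c, l' ~ L(x')|c and m | l' ~ M(x', l')|c."""
    t, w = np.polynomial.hermite.hermgauss(order)
    w = w / math.sqrt(math.pi)
    cl = float(c_vec @ np.asarray(p.gamma_c))
    cm = float(c_vec @ np.asarray(p.alpha_c))
    cy = float(c_vec @ np.asarray(p.beta_c))
    sd_l = math.sqrt(2.0 * p.sigma2_l)
    sd_m = math.sqrt(2.0 * p.sigma2_m)

    l_nodes = p.gamma0 + p.gamma_x * x + cl + sd_l * t  # (order,)
    lp_nodes = p.gamma0 + p.gamma_x * xp + cl + sd_l * t
    mu_m = (
        p.alpha0 + p.alpha_x * xp + (p.alpha_l + p.alpha_xl * xp) * lp_nodes + cm
    )
    m_nodes = mu_m[:, None] + sd_m * t[None, :]  # (order, order)

    L = l_nodes[:, None, None]
    M = m_nodes[None, :, :]
    y = (
        p.beta0
        + p.beta_x * x
        + cy
        + (p.beta_l + p.beta_xl * x) * L
        + p.beta_ll * L**2
        + (p.beta_m + p.beta_xm * x) * M
        + p.beta_mm * M**2
    )
    return float(np.einsum("i,j,k,ijk->", w, w, w, y))


def _cde_quad(p: SEMParameters, x: float, m: float, c_vec: np.ndarray, order: int) -> float:
    """E{Y(x, m) | C=c} with the mediator controlled, quadrature over l."""
    t, w = np.polynomial.hermite.hermgauss(order)
    w = w / math.sqrt(math.pi)
    cl = float(c_vec @ np.asarray(p.gamma_c))
    cy = float(c_vec @ np.asarray(p.beta_c))
    l_nodes = p.gamma0 + p.gamma_x * x + cl + math.sqrt(2.0 * p.sigma2_l) * t
    y = (
        p.beta0
        + p.beta_x * x
        + cy
        + (p.beta_l + p.beta_xl * x) * l_nodes
        + p.beta_ll * l_nodes**2
        + (p.beta_m + p.beta_xm * x) * m
        + p.beta_mm * m**2
    )
    return float(w @ y)


def truth_oracle(
    params: SEMParameters,
    c_config: Sequence = (),
    assumption: str | None = None,
    cde_m_level: float = 0.0,
    order: int = 40,
) -> SimulationTruth:
    """Exact estimand values by deterministic quadrature.

    When ``assumption`` is given, the parameter set must satisfy its
    zero-constraints (an identification error is raised otherwise); with
    ``None`` the structural truth is computed unconditionally.
    """
    if len(c_config) != params.n_covariates:
        raise InvalidInputError(
            f"params carry {params.n_covariates} covariate coefficients but "
            f"c_config has {len(c_config)} entries"
        )
    if assumption is not None:
        from .combine import resolve_assumption

        resolve_assumption(params, assumption)

    atoms, weights = _c_atoms(c_config, order)

    def avg_eta(x: float, xp: float) -> float:
        return float(
            sum(
                wt * _eta_quad(params, x, xp, atom, order)
                for atom, wt in zip(atoms, weights)
            )
        )

    def avg_cde(x: float) -> float:
        return float(
            sum(
                wt * _cde_quad(params, x, cde_m_level, atom, order)
                for atom, wt in zip(atoms, weights)
            )
        )

    e11 = avg_eta(1.0, 1.0)
    e10 = avg_eta(1.0, 0.0)
    e00 = avg_eta(0.0, 0.0)
    pnde = e10 - e00
    tce = e11 - e00
    return SimulationTruth(
        params=params,
        params_effective=params,
        c_config=tuple(c_config),
        true_tce=tce,
        true_pnde=pnde,
        true_tnie=tce - pnde,
        true_cde=avg_cde(1.0) - avg_cde(0.0),
        cde_m_level=cde_m_level,
        assumption_used=assumption,
    )
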