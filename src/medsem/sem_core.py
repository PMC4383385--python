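"""Recursive linear structural equation model for mediation analysis.

The system links a binary exposure ``X``, a continuous intermediate
confounder ``L`` (a variable affected by the exposure that confounds the
mediator--outcome relationship), a continuous mediator ``M``, a continuous
outcome ``Y``, and optional baseline covariates ``C``:

.. math::

    L &= \\gamma_0 + \\gamma_x X + \\gamma_c' C + \\epsilon_l \\\\
    M &= \\alpha_0 + \\alpha_x X + \\alpha_l L + \\alpha_c' C
         + \\alpha_{xl} XL + \\epsilon_m \\\\
    Y &= \\beta_0 + \\beta_x X + \\beta_m M + \\beta_l L + \\beta_c' C
         + \\beta_{mm} M^2 + \\beta_{ll} L^2 + \\beta_{xl} XL
         + \\beta_{xm} XM + \\epsilon_y

with mean-zero errors that are uncorrelated with each other and with the
regressors of their own equation.  The minimal model (no interactions or
quadratics) is the classical linear path model; the extended term set allows
exposure--confounder and exposure--mediator interactions and quadratic
curvature in ``L`` and ``M``.

Because the system is recursive with uncorrelated errors, the equations can
be estimated one at a time by ordinary least squares, which is what
:func:`fit_sem` does.  Cross-equation coefficient covariances are zero under
the independent-error assumption, so the joint coefficient covariance is
block-diagonal across equations; the nonparametric bootstrap (``gcomp``
module) is available when that approximation is in doubt.

An ``L*M`` product term in the outcome equation is rejected at specification
time: its coefficient would have to be constrained to zero under either of
the parametric identification assumptions this package supports, so allowing
it would only invite silently unidentified analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.linalg import block_diag, qr

from .errors import CollinearityError, InvalidInputError, MissingDataError

__all__ = [
    "SEMSpec",
    "SEMParameters",
    "FittedSEM",
    "fit_sem",
    "equation_terms",
    "M_TERMS",
    "Y_TERMS",
]

#: admissible term flags for the mediator equation
M_TERMS = frozenset({"x", "l", "c", "xl"})
#: admissible term flags for the outcome equation
Y_TERMS = frozenset({"x", "m", "l", "c", "m2", "l2", "xl", "xm"})

_REQUIRED_M = frozenset({"x", "l"})
_REQUIRED_Y = frozenset({"x", "m", "l"})

_ASSUMPTIONS = ("robins_greenland", "petersen")


@dataclass(frozen=True)
class SEMSpec:
    """Declarative description of the three structural equations.

    Parameters
    ----------
    x, m, y, l
        Column names of the binary exposure, continuous mediator, continuous
        outcome, and continuous intermediate confounder.
    c
        Column names of baseline covariates (possibly empty).
    terms_m
        Term flags for the mediator equation, a subset of
        ``{"x", "l", "c", "xl"}``; must contain ``{"x", "l"}``.
    terms_y
        Term flags for the outcome equation, a subset of
        ``{"x", "m", "l", "c", "m2", "l2", "xl", "xm"}``; must contain
        ``{"x", "m", "l"}``.
    """

    x: str
    m: str
    y: str
    l: str
    c: tuple[str, ...] = ()
    terms_m: frozenset[str] = frozenset({"x", "l", "c"})
    terms_y: frozenset[str] = frozenset({"x", "m", "l", "c"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", tuple(self.c))
        object.__setattr__(self, "terms_m", frozenset(self.terms_m))
        object.__setattr__(self, "terms_y", frozenset(self.terms_y))
        core = [self.x, self.m, self.y, self.l]
        if len(set(core)) != 4:
            raise InvalidInputError(
                "exposure, mediator, outcome and intermediate-confounder "
                f"columns must be distinct, got {core}"
            )
        if len(set(self.c)) != len(self.c):
            raise InvalidInputError(f"duplicate covariate names in c: {self.c}")
        overlap = set(self.c) & set(core)
        if overlap:
            raise InvalidInputError(
                f"covariate names overlap x/m/y/l columns: {sorted(overlap)}"
            )
        if "lm" in self.terms_y:
            raise InvalidInputError(
                "an L*M product term in the outcome equation is not "
                "supported: its coefficient would have to be constrained to "
                "zero under either parametric identification assumption"
            )
        bad_m = self.terms_m - M_TERMS
        if bad_m:
            raise InvalidInputError(f"unknown mediator-equation terms: {sorted(bad_m)}")
        bad_y = self.terms_y - Y_TERMS
        if bad_y:
            raise InvalidInputError(f"unknown outcome-equation terms: {sorted(bad_y)}")
        if not _REQUIRED_M <= self.terms_m:
            raise InvalidInputError("terms_m must contain {'x', 'l'}")
        if not _REQUIRED_Y <= self.terms_y:
            raise InvalidInputError("terms_y must contain {'x', 'm', 'l'}")

    # ------------------------------------------------------------------
    @property
    def is_model4(self) -> bool:
        """True when no interaction or quadratic term is present."""
        return (self.terms_m <= {"x", "l", "c"}) and (
            self.terms_y <= {"x", "m", "l", "c"}
        )

    def constrained(self, assumption: str) -> "SEMSpec":
        """Return the spec with the outcome terms an identification
        assumption forces to zero removed.

        ``robins_greenland`` (no individual-level exposure--mediator
        interaction on the outcome) removes ``xm``; ``petersen`` (the
        controlled direct effect does not vary with M(0)) removes ``l2``
        and ``xl`` from the outcome equation.
        """
        if assumption == "robins_greenland":
            return replace(self, terms_y=self.terms_y - {"xm"})
        if assumption == "petersen":
            return replace(self, terms_y=self.terms_y - {"l2", "xl"})
        raise InvalidInputError(
            f"unknown identification assumption {assumption!r}; "
            f"expected one of {_ASSUMPTIONS}"
        )

    def with_full_y(self) -> "SEMSpec":
        """Return the spec with the unconstrained (saturated) outcome-term set."""
        return replace(self, terms_y=Y_TERMS)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "m": self.m,
            "y": self.y,
            "l": self.l,
            "c": list(self.c),
            "terms_m": sorted(self.terms_m),
            "terms_y": sorted(self.terms_y),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SEMSpec":
        kwargs = dict(d)
        unknown = set(kwargs) - {"x", "m", "y", "l", "c", "terms_m", "terms_y"}
        if unknown:
            raise InvalidInputError(f"unknown SEMSpec keys: {sorted(unknown)}")
        for key in ("x", "m", "y", "l"):
            if key not in kwargs:
                raise InvalidInputError(f"SEMSpec config is missing key {key!r}")
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SEMSpec":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SEMParameters:
    """Full coefficient set of the three-equation system.

    Coefficients of terms absent from a given :class:`SEMSpec` are
    identically zero.  ``sigma2_*`` are the error variances and ``rho`` the
    correlation between the mediator- and outcome-equation errors (zero in
    any fitted model; nonzero only as a data-generating device representing
    unmeasured mediator--outcome confounding).

    The ``*_c`` fields are tuples with one coefficient per baseline
    covariate, in the order of ``SEMSpec.c``.
    """

    gamma0: float = 0.0
    gamma_x: float = 0.0
    gamma_c: tuple[float, ...] = ()
    alpha0: float = 0.0
    alpha_x: float = 0.0
    alpha_l: float = 0.0
    alpha_xl: float = 0.0
    alpha_c: tuple[float, ...] = ()
    beta0: float = 0.0
    beta_x: float = 0.0
    beta_m: float = 0.0
    beta_l: float = 0.0
    beta_mm: float = 0.0
    beta_ll: float = 0.0
    beta_xl: float = 0.0
    beta_xm: float = 0.0
    beta_c: tuple[float, ...] = ()
    sigma2_l: float = 1.0
    sigma2_m: float = 1.0
    sigma2_y: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma_c", "alpha_c", "beta_c"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        lengths = {len(self.gamma_c), len(self.alpha_c), len(self.beta_c)}
        if len(lengths) != 1:
            raise InvalidInputError(
                "gamma_c, alpha_c and beta_c must have one entry per covariate "
                f"(got lengths {sorted(lengths)})"
            )
        for name in ("sigma2_l", "sigma2_m", "sigma2_y"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not abs(self.rho) < 1:
            raise InvalidInputError("|rho| must be < 1")

    @property
    def n_covariates(self) -> int:
        return len(self.gamma_c)

    # conditional means of the structural equations ---------------------
    def l_mean(self, x, c) -> np.ndarray:
        """E(L | X=x, C=c); ``c`` is an (n, k) array."""
        return self.gamma0 + self.gamma_x * np.asarray(x, float) + np.asarray(c, float) @ np.asarray(self.gamma_c)

    def m_mean(self, x, l, c) -> np.ndarray:
        """E(M | X=x, L=l, C=c)."""
        x = np.asarray(x, float)
        l = np.asarray(l, float)
        return (
            self.alpha0
            + self.alpha_x * x
            + (self.alpha_l + self.alpha_xl * x) * l
            + np.asarray(c, float) @ np.asarray(self.alpha_c)
        )

    def y_mean(self, x, m, l, c) -> np.ndarray:
        """E(Y | X=x, M=m, L=l, C=c)."""
        x = np.asarray(x, float)
        m = np.asarray(m, float)
        l = np.asarray(l, float)
        return (
            self.beta0
            + self.beta_x * x
            + (self.beta_m + self.beta_xm * x) * m
            + self.beta_mm * m * m
            + (self.beta_l + self.beta_xl * x) * l
            + self.beta_ll * l * l
            + np.asarray(c, float) @ np.asarray(self.beta_c)
        )


# ----------------------------------------------------------------------
# mapping from (equation, term) to SEMParameters field
_FIELD_MAP = {
    "l": {"const": "gamma0", "x": "gamma_x"},
    "m": {"const": "alpha0", "x": "alpha_x", "l": "alpha_l", "xl": "alpha_xl"},
    "y": {
        "const": "beta0",
        "x": "beta_x",
        "m": "beta_m",
        "l": "beta_l",
        "m2": "beta_mm",
        "l2": "beta_ll",
        "xl": "beta_xl",
        "xm": "beta_xm",
    },
}
_C_FIELD = {"l": "gamma_c", "m": "alpha_c", "y": "beta_c"}
_SIGMA_FIELD = {"l": "sigma2_l", "m": "sigma2_m", "y": "sigma2_y"}


def equation_terms(eq: str, spec: SEMSpec) -> list[str]:
    """Canonical ordered term list of one equation's design matrix.

    Covariate terms are named by their column name; all other terms use the
    flag names (``const``, ``x``, ``m``, ``l``, ``m2``, ``l2``, ``xl``,
    ``xm``).
    """
    if eq == "l":
        # the L equation always regresses on exposure and covariates
        return ["const", "x", *spec.c]
    if eq == "m":
        names = ["const", "x", "l"]
        if "c" in spec.terms_m:
            names += list(spec.c)
        if "xl" in spec.terms_m:
            names.append("xl")
        return names
    if eq == "y":
        names = ["const", "x", "m", "l"]
        if "c" in spec.terms_y:
            names += list(spec.c)
        for t in ("m2", "l2", "xl", "xm"):
            if t in spec.terms_y:
                names.append(t)
        return names
    raise ValueError(f"unknown equation {eq!r}")


def _column_pool(data: pd.DataFrame, spec: SEMSpec) -> dict[str, np.ndarray]:
    x = data[spec.x].to_numpy(float)
    m = data[spec.m].to_numpy(float)
    l = data[spec.l].to_numpy(float)
    pool = {
        "const": np.ones(len(data)),
        "x": x,
        "m": m,
        "l": l,
        "m2": m * m,
        "l2": l * l,
        "xl": x * l,
        "xm": x * m,
    }
    for name in spec.c:
        pool[name] = data[name].to_numpy(float)
    return pool


def _design(eq: str, data: pd.DataFrame, spec: SEMSpec):
    """Build (term names, X matrix, response vector) for one equation."""
    pool = _column_pool(data, spec)
    names = equation_terms(eq, spec)
    X = np.column_stack([pool[t] for t in names])
    response = {"l": spec.l, "m": spec.m, "y": spec.y}[eq]
    return names, X, data[response].to_numpy(float)


def _check_rank(X: np.ndarray, names: Sequence[str], eq: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise CollinearityError(
            f"design matrix of the {eq}-equation is rank deficient; "
            f"offending columns: {', '.join(bad)}"
        )


def _validate_table(data: pd.DataFrame, spec: SEMSpec) -> None:
    used = [spec.x, spec.m, spec.y, spec.l, *spec.c]
    missing_cols = [col for col in used if col not in data.columns]
    if missing_cols:
        raise InvalidInputError(f"columns not found in data: {missing_cols}")
    na_cols = [col for col in used if data[col].isna().any()]
    if na_cols:
        raise MissingDataError(
            f"missing values in columns {na_cols}; perform complete-case "
            f"filtering explicitly first, e.g. data.dropna(subset={used!r}), "
            "so that the analysis sample size is explicit"
        )
    xvals = set(np.unique(data[spec.x].to_numpy()))
    if not xvals <= {0, 1}:
        raise InvalidInputError(
            f"exposure column {spec.x!r} must be coded 0/1, found values "
            f"{sorted(xvals)[:6]}"
        )
    if len(xvals) < 2:
        raise InvalidInputError(
            f"exposure column {spec.x!r} must contain both 0 and 1"
        )


def _fit_equation(eq: str, data: pd.DataFrame, spec: SEMSpec):
    names, X, y = _design(eq, data, spec)
    if len(y) <= X.shape[1]:
        raise InvalidInputError(
            f"n={len(y)} rows is too small to fit the {eq}-equation "
            f"({X.shape[1]} coefficients)"
        )
    _check_rank(X, names, eq)
    res = sm.OLS(y, X).fit()
    return names, res


# ----------------------------------------------------------------------
@dataclass
class FittedSEM:
    """Equation-wise least-squares estimates of the system.

    Attributes
    ----------
    spec, params
        The specification and point estimates (``params.rho`` fixed at 0;
        coefficients of absent terms are 0).
    coef_names
        ``(equation, term)`` labels of the stacked coefficient vector.
    theta
        Stacked coefficient estimates, same order as ``coef_names``.
    coef_cov
        Joint coefficient covariance, block-diagonal across equations
        (classical OLS covariance per equation; cross-equation blocks are 0
        under the independent-error assumption).
    residuals
        Per-equation residual vectors, keyed ``"l"/"m"/"y"``.
    covariate_rows
        Observed covariate table, shape (n, k), retained for empirical
        regression standardization; shape (1, 0) when there are no
        covariates.
    """

    spec: SEMSpec
    params: SEMParameters
    coef_names: tuple[tuple[str, str], ...]
    theta: np.ndarray
    coef_cov: np.ndarray
    n: int
    residuals: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_rows: np.ndarray = field(default_factory=lambda: np.zeros((1, 0)))

    def params_from_theta(self, theta: np.ndarray) -> SEMParameters:
        """Rebuild a :class:`SEMParameters` from a stacked coefficient vector.

        Residual variances and ``rho`` are carried over from the point fit;
        only the regression coefficients vary.  Used by the delta method.
        """
        k = len(self.spec.c)
        c_coefs = {eq: [0.0] * k for eq in ("l", "m", "y")}
        scalars: dict[str, float] = {}
        for (eq, term), value in zip(self.coef_names, theta):
            fld = _FIELD_MAP[eq].get(term)
            if fld is not None:
                scalars[fld] = float(value)
            else:
                c_coefs[eq][self.spec.c.index(term)] = float(value)
        return replace(
            self.params,
            gamma_c=tuple(c_coefs["l"]),
            alpha_c=tuple(c_coefs["m"]),
            beta_c=tuple(c_coefs["y"]),
            **scalars,
        )

    @classmethod
    def from_params(
        cls,
        spec: SEMSpec,
        params: SEMParameters,
        covariate_rows: np.ndarray | None = None,
        n: int = 0,
        coef_cov: np.ndarray | None = None,
    ) -> "FittedSEM":
        """Construct a degenerate fit directly from known parameters.

        Useful for evaluating estimators at true parameter values without
        any data (the covariance defaults to all zeros).
        """
        if params.n_covariates != len(spec.c):
            raise InvalidInputError(
                f"params carry {params.n_covariates} covariate coefficients "
                f"but spec declares {len(spec.c)} covariates"
            )
        names: list[tuple[str, str]] = []
        values: list[float] = []
        for eq in ("l", "m", "y"):
            c_arr = getattr(params, _C_FIELD[eq])
            for term in equation_terms(eq, spec):
                names.append((eq, term))
                fld = _FIELD_MAP[eq].get(term)
                if fld is not None:
                    values.append(float(getattr(params, fld)))
                else:
                    values.append(float(c_arr[spec.c.index(term)]))
        theta = np.array(values)
        if coef_cov is None:
            coef_cov = np.zeros((len(theta), len(theta)))
        if covariate_rows is None:
            covariate_rows = np.zeros((1, len(spec.c)))
        return cls(
            spec=spec,
            params=params,
            coef_names=tuple(names),
            theta=theta,
            coef_cov=np.asarray(coef_cov, float),
            n=n,
            residuals={},
            covariate_rows=np.asarray(covariate_rows, float),
        )


def fit_sem(data: pd.DataFrame, spec: SEMSpec) -> FittedSEM:
    """Fit the recursive SEM by equation-wise ordinary least squares.

    Residual variances use the unbiased n − p denominator.  Raises
    :class:`~medsem.errors.MissingDataError` on missing values (complete-case
    filtering is the caller's responsibility), an invalid-input error on a
    non-binary exposure, and :class:`~medsem.errors.CollinearityError` naming
    the offending columns on a rank-deficient design.
    """
    _validate_table(data, spec)
    names_all: list[tuple[str, str]] = []
    theta_parts: list[np.ndarray] = []
    cov_blocks: list[np.ndarray] = []
    residuals: dict[str, np.ndarray] = {}
    scalars: dict[str, float] = {}
    c_coefs: dict[str, list[float]] = {}
    k = len(spec.c)

    for eq in ("l", "m", "y"):
        names, res = _fit_equation(eq, data, spec)
        names_all += [(eq, t) for t in names]
        theta_parts.append(np.asarray(res.params, float))
        cov_blocks.append(np.asarray(res.cov_params(), float))
        residuals[eq] = np.asarray(res.resid, float)
        scalars[_SIGMA_FIELD[eq]] = float(res.scale)  # ssr / (n - p)
        coefs = [0.0] * k
        for term, value in zip(names, res.params):
            fld = _FIELD_MAP[eq].get(term)
            if fld is not None:
                scalars[fld] = float(value)
            else:
                coefs[spec.c.index(term)] = float(value)
        c_coefs[eq] = coefs

    params = SEMParameters(
        gamma_c=tuple(c_coefs["l"]),
        alpha_c=tuple(c_coefs["m"]),
        beta_c=tuple(c_coefs["y"]),
        rho=0.0,
        **scalars,
    )
    covariate_rows = (
        data[list(spec.c)].to_numpy(float) if spec.c else np.zeros((1, 0))
    )
    return FittedSEM(
        spec=spec,
        params=params,
        coef_names=tuple(names_all),
        theta=np.concatenate(theta_parts),
        coef_cov=block_diag(*cov_blocks),
        n=len(data),
        residuals=residuals,
        covariate_rows=covariate_rows,
    )
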