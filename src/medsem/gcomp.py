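"""Monte Carlo g-computation of mediation estimands and the nonparametric
bootstrap.

:func:`mc_estimands` approximates the same mediation-formula integrals that
the ``combine`` module evaluates in closed form.  For each leg
``(x, x') in {(1,1), (1,0), (0,0)}`` and each covariate row it draws

* ``l  ~ Normal(mu_L(x, c),  sigma_l^2)`` -- the confounder under exposure x,
* ``l' ~ Normal(mu_L(x', c), sigma_l^2)`` -- an independent copy under x',
* ``m  ~ Normal(mu_M(x', l', c), sigma_m^2)`` -- the mediator under x',

and accumulates the fitted conditional outcome mean ``E(Y | x, m, l, c)``
rather than simulating ``Y`` itself (Rao-Blackwellization: the estimands are
means of linear/quadratic functions, so evaluating the conditional mean is
unbiased and strictly reduces Monte Carlo variance).  Drawing ``l`` and
``l'`` independently is valid because the outcome equation contains no
``L*M`` product.  PNDE = leg(1,0) - leg(0,0), TNIE = leg(1,1) - leg(1,0),
TCE = leg(1,1) - leg(0,0); ``tnie = tce - pnde`` therefore holds exactly.
CDE(m) repeats the construction with the mediator fixed, drawing only ``l``.

``n_mc`` counts total counterfactual draws, allocated by cycling over the
observed covariate rows.  Each leg uses its own named child stream of the
seed so legs are independent; the seed is mandatory.

:func:`bootstrap` resamples raw rows with replacement and refits everything
per replicate for any estimator in the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import combine as _combine
from .errors import MedSEMError, SettingsError
from .sem_core import FittedSEM, SEMSpec, fit_sem

__all__ = [
    "MCSettings",
    "BootstrapSettings",
    "BootstrapResult",
    "mc_estimands",
    "bootstrap",
    "combination_estimator",
    "mc_estimator",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class MCSettings:
    """Monte Carlo settings; the seed is required for reproducibility."""

    seed: int
    n_mc: int = 100_000
    cde_m_level: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SettingsError("MCSettings.seed is mandatory")
        if self.n_mc < 1000:
            raise SettingsError(f"n_mc must be >= 1000, got {self.n_mc}")


@dataclass(frozen=True)
class BootstrapSettings:
    seed: int
    n_boot: int = 1000
    ci_type: str = "percentile"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SettingsError("BootstrapSettings.seed is mandatory")
        if self.n_boot < 199:
            raise SettingsError(f"n_boot must be >= 199, got {self.n_boot}")
        if self.ci_type != "percentile":
            raise SettingsError("only percentile bootstrap CIs are supported")


# ----------------------------------------------------------------------
def _leg_y(params, c_rows, x, xp, n_mc, rng, share_l=False):
    """Mean and MC-SE of E{Y(x, M(x'))} approximated with n_mc draws."""
    idx = np.arange(n_mc) % len(c_rows)
    c = c_rows[idx]
    sd_l = math.sqrt(params.sigma2_l)
    sd_m = math.sqrt(params.sigma2_m)
    l = rng.normal(params.l_mean(x, c), sd_l)
    if share_l and x == xp:
        lp = l
    else:
        lp = rng.normal(params.l_mean(xp, c), sd_l)
    m = rng.normal(params.m_mean(xp, lp, c), sd_m)
    vals = params.y_mean(x, m, l, c)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_mc))


def _leg_cde(params, c_rows, x, m_level, n_mc, rng):
    """Mean and MC-SE of E{Y(x, m)} with the mediator controlled at m."""
    idx = np.arange(n_mc) % len(c_rows)
    c = c_rows[idx]
    l = rng.normal(params.l_mean(x, c), math.sqrt(params.sigma2_l))
    vals = params.y_mean(x, m_level, l, c)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_mc))


def mc_estimands(
    fit: FittedSEM, settings: MCSettings, _share_l: bool = False
) -> _combine.MediationEstimates:
    """Monte Carlo g-computation of TCE, PNDE, TNIE and CDE(m).

    Gaussian draws for L and M; non-Gaussian error models are not supported.
    Reported SEs (and the ``mc_error`` attribute) quantify Monte Carlo
    integration error only -- use :func:`bootstrap` for sampling
    uncertainty.  Same fit, settings and seed give bit-identical output.
    """
    params = fit.params
    c_rows = fit.covariate_rows
    streams = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(settings.seed).spawn(5)
    ]
    e11, s11 = _leg_y(params, c_rows, 1.0, 1.0, settings.n_mc, streams[0], _share_l)
    e10, s10 = _leg_y(params, c_rows, 1.0, 0.0, settings.n_mc, streams[1])
    e00, s00 = _leg_y(params, c_rows, 0.0, 0.0, settings.n_mc, streams[2])
    c1, sc1 = _leg_cde(params, c_rows, 1.0, settings.cde_m_level, settings.n_mc, streams[3])
    c0, sc0 = _leg_cde(params, c_rows, 0.0, settings.cde_m_level, settings.n_mc, streams[4])

    pnde, tnie = e10 - e00, e11 - e10
    vals = {"tce": e11 - e00, "pnde": pnde, "tnie": tnie, "cde": c1 - c0}
    ses = {
        "tce": math.hypot(s11, s00),
        "pnde": math.hypot(s10, s00),
        "tnie": math.hypot(s11, s10),
        "cde": math.hypot(sc1, sc0),
    }
    cis = {k: (vals[k] - _Z975 * ses[k], vals[k] + _Z975 * ses[k]) for k in vals}
    tce = vals["tce"]
    prop = tnie / tce if tce != 0 else float("nan")
    return _combine.MediationEstimates(
        tce=vals["tce"],
        pnde=vals["pnde"],
        tnie=vals["tnie"],
        cde=vals["cde"],
        cde_m_level=float(settings.cde_m_level),
        prop_mediated=prop,
        prop_mediated_unstable=not np.isfinite(prop),
        se_tce=ses["tce"],
        se_pnde=ses["pnde"],
        se_tnie=ses["tnie"],
        se_cde=ses["cde"],
        ci_tce=cis["tce"],
        ci_pnde=cis["pnde"],
        ci_tnie=cis["tnie"],
        ci_cde=cis["cde"],
        method="monte_carlo",
        assumption="as_fitted",
        mc_error={
            "leg_11": s11,
            "leg_10": s10,
            "leg_00": s00,
            "cde_1": sc1,
            "cde_0": sc0,
            "n_mc": settings.n_mc,
        },
    )


# ----------------------------------------------------------------------
@dataclass
class BootstrapResult:
    """Replicate estimates with SDs and percentile CIs per quantity."""

    estimates: pd.DataFrame
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    seed: int
    ci_type: str = "percentile"


def bootstrap(
    data: pd.DataFrame,
    spec: SEMSpec,
    estimator: Callable[[pd.DataFrame, SEMSpec], Mapping[str, float]],
    settings: BootstrapSettings,
) -> BootstrapResult:
    """Nonparametric (case-resampling) bootstrap of any estimator.

    ``estimator(data, spec)`` must return a mapping of scalar results.
    Replicate-level failures (e.g. a collinear resample) are recorded and
    excluded; a warning is raised when more than 1% of replicates fail.
    """
    rng = np.random.default_rng(settings.seed)
    n = len(data)
    rows: list[Mapping[str, float]] = []
    n_failed = 0
    for _ in range(settings.n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            rows.append(dict(estimator(sample, spec)))
        except (MedSEMError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.01 * settings.n_boot:
        warnings.warn(
            f"{n_failed}/{settings.n_boot} bootstrap replicates failed and "
            "were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    if not rows:
        raise MedSEMError("all bootstrap replicates failed")
    est = pd.DataFrame(rows)
    se = {k: float(est[k].std(ddof=1)) for k in est.columns}
    ci = {
        k: tuple(float(v) for v in np.percentile(est[k].to_numpy(), [2.5, 97.5]))
        for k in est.columns
    }
    return BootstrapResult(
        estimates=est,
        se=se,
        ci=ci,
        n_boot=settings.n_boot,
        n_failed=n_failed,
        seed=settings.seed,
        ci_type=settings.ci_type,
    )


def combination_estimator(
    assumption: str = "auto", cde_m_level: float = 0.0
) -> Callable[[pd.DataFrame, SEMSpec], dict[str, float]]:
    """Bootstrap-ready wrapper: fit the SEM and combine its coefficients."""

    def estimator(data: pd.DataFrame, spec: SEMSpec) -> dict[str, float]:
        est = _combine.combine_general(fit_sem(data, spec), assumption, cde_m_level)
        return {"tce": est.tce, "pnde": est.pnde, "tnie": est.tnie, "cde": est.cde}

    return estimator


def mc_estimator(
    settings: MCSettings,
) -> Callable[[pd.DataFrame, SEMSpec], dict[str, float]]:
    """Bootstrap-ready wrapper: refit and rerun the Monte Carlo g-formula."""

    def estimator(data: pd.DataFrame, spec: SEMSpec) -> dict[str, float]:
        est = mc_estimands(fit_sem(data, spec), settings)
        return {"tce": est.tce, "pnde": est.pnde, "tnie": est.tnie, "cde": est.cde}

    return estimator
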