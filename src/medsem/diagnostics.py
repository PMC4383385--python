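"""Identification diagnostics: which parametric assumption is tenable?

With an exposure-induced intermediate confounder, natural direct and
indirect effects are identified either when there is no exposure--mediator
interaction on the outcome (beta_xm = 0) or when the controlled direct
effect does not vary with M(0) (beta_ll = beta_xl = 0).  Fitting the
*unconstrained* associational outcome model -- with all of M^2, L^2, X*L and
X*M -- and testing those coefficients indicates which constraint the data
are compatible with.

:func:`check_identification` reports a single-coefficient Wald (t) test for
beta_xm, a 2-df joint F test for (beta_xl, beta_ll), per-term p-values, and
a recommendation.  Classical (non-robust) OLS standard errors are used.  No
multiple-testing correction is applied across the two hypotheses: they
select between model parameterizations rather than flag discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sem_core import SEMSpec, _fit_equation, _validate_table

__all__ = ["IdentificationReport", "check_identification", "recommend"]


@dataclass
class IdentificationReport:
    """Evidence for each identification assumption from the saturated
    outcome model."""

    p_beta_xm: float
    p_joint_xl_ll: float
    p_beta_xl: float
    p_beta_ll: float
    table: pd.DataFrame  # term, estimate, se, p_value
    recommendation: str
    alpha: float

    def to_dict(self) -> dict:
        return {
            "p_beta_xm": self.p_beta_xm,
            "p_joint_xl_ll": self.p_joint_xl_ll,
            "p_beta_xl": self.p_beta_xl,
            "p_beta_ll": self.p_beta_ll,
            "alpha": self.alpha,
            "recommendation": self.recommendation,
            "coefficients": self.table.to_dict(orient="records"),
        }

    def table_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def recommend(p_beta_xm: float, p_joint_xl_ll: float, alpha: float = 0.05) -> str:
    """Decision rule mapping the two p-values to a recommendation.

    Rejecting beta_xm = 0 excludes the no-interaction assumption; rejecting
    beta_xl = beta_ll = 0 jointly excludes the constant-CDE assumption.
    """
    reject_xm = p_beta_xm < alpha
    reject_joint = p_joint_xl_ll < alpha
    if reject_xm and reject_joint:
        return "neither_admissible"
    if reject_xm:
        return "petersen"
    if reject_joint:
        return "robins_greenland"
    return "both_admissible"


def check_identification(
    data: pd.DataFrame, spec: SEMSpec, alpha: float = 0.05
) -> IdentificationReport:
    """Fit the unconstrained outcome model and test the identifying
    constraints.

    The outcome term set is upgraded internally to the full
    {x, m, l, c, m2, l2, xl, xm}; the mediator/confounder equations are not
    involved.  ``neither_admissible`` triggers a warning because the natural
    effects are then not identified under either supported option.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    full = spec.with_full_y()
    _validate_table(data, full)
    names, res = _fit_equation("y", data, full)

    p_xm = float(res.pvalues[names.index("xm")])
    p_xl = float(res.pvalues[names.index("xl")])
    p_ll = float(res.pvalues[names.index("l2")])
    R = np.zeros((2, len(names)))
    R[0, names.index("xl")] = 1.0
    R[1, names.index("l2")] = 1.0
    p_joint = float(res.f_test(R).pvalue)

    table = pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(res.params, float),
            "se": np.asarray(res.bse, float),
            "p_value": np.asarray(res.pvalues, float),
        }
    )
    rec = recommend(p_xm, p_joint, alpha)
    if rec == "neither_admissible":
        warnings.warn(
            "both identifying constraints are rejected: natural direct and "
            "indirect effects are not identified under either supported "
            "assumption",
            UserWarning,
            stacklevel=2,
        )
    return IdentificationReport(
        p_beta_xm=p_xm,
        p_joint_xl_ll=p_joint,
        p_beta_xl=p_xl,
        p_beta_ll=p_ll,
        table=table,
        recommendation=rec,
        alpha=alpha,
    )
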