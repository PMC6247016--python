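"""Linear mixed-effects modeling of a longitudinal metric.

Fits y_ij = X'_ij beta + Z_ij b_i + eps_ij grouped by subject: fixed
effects describe population-average trends (time, group, sex,
interactions), random effects b_i ~ N(0, Sigma) describe per-subject
departures (random intercepts, optionally random slopes on time), and
eps_ij ~ N(0, sigma^2) is residual noise.  Estimation is REML by default
(ML behind a flag); statsmodels' ``mixedlm`` is the engine.

The coefficient table reports, per fixed effect, the estimate, its
standard error, the Z-score, and a two-tailed P value of the Z-score
against the standard normal.  Categorical terms are treatment-coded
against the lexicographically first level and labeled "name [T.level]".
Non-convergence is a reported state (``converged=False``), not an
exception: boundary fits are routine in longitudinal microbiome data.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_formats import SampleMetadata

logger = logging.getLogger(__name__)

_IDENTIFIER = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass
class LMEModelSpec:
    """Model specification for :func:`fit_lme`.

    ``fixed_effect_columns`` are metadata columns entering X_ij as main
    effects, in user order; ``interactions`` are pairs of those columns.
    The state column (time) always enters as a fixed effect unless a
    ``formula_override`` is given.  ``include_random_slope`` puts the
    state column in Z_ij alongside the intercept.
    """

    response: str
    fixed_effect_columns: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    include_random_slope: bool = False
    formula_override: str | None = None


@dataclass
class LMEResult:
    """Fixed-effect coefficient table plus variance components.

    ``fixed_effects`` columns: Estimate, SE, Z-score, P-value, indexed by
    treatment-coded term labels.  Variance components are the random
    intercept variance, the random slope variance and the
    intercept-slope covariance (elements of Sigma; NaN when no random
    slope was fit), and the residual variance sigma^2.
    """

    fixed_effects: pd.DataFrame
    intercept_variance: float
    slope_variance: float
    intercept_slope_covariance: float
    residual_variance: float
    n_subjects: int
    n_observations: int
    converged: bool
    formula: str

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table followed by the four variance-component rows."""
        fe = self.fixed_effects.copy()
        fe.insert(0, "model", "Fixed effects")
        rand = pd.DataFrame(
            {
                "model": "Random effects",
                "Estimate": [
                    self.intercept_variance,
                    self.slope_variance,
                    self.intercept_slope_covariance,
                    self.residual_variance,
                ],
                "SE": np.nan,
                "Z-score": np.nan,
                "P-value": np.nan,
            },
            index=[
                "Intercept (subject ID)",
                "Slope (change per state)",
                "Covariance (intercept, time)",
                "Residual error",
            ],
        )
        return pd.concat([fe, rand])


def _quote(column: str) -> str:
    return column if _IDENTIFIER.match(column) else f"Q('{column}')"


def lme_formula(spec: LMEModelSpec, state_column: str, columns: list[str] | None = None) -> str:
    """Deterministic model formula: intercept, main effects in user order,
    declared interactions, then time.  ``formula_override`` passes through
    verbatim."""
    if spec.formula_override is not None:
        return spec.formula_override
    if columns is not None:
        for col in [spec.response, *spec.fixed_effect_columns,
                    *(c for pair in spec.interactions for c in pair), state_column]:
            if col not in columns:
                raise ValueError(f"unknown column {col!r} in model specification")
    terms = [_quote(c) for c in spec.fixed_effect_columns]
    terms += [f"{_quote(a)}:{_quote(b)}" for a, b in spec.interactions]
    terms.append(_quote(state_column))
    return f"{_quote(spec.response)} ~ " + " + ".join(terms)


def _clean_term(name: str) -> str:
    """patsy 'delivery[T.vaginal]:diet[T.fd]' -> 'delivery [T.vaginal]:diet [T.fd]'."""
    name = re.sub(r"Q\('([^']*)'\)", r"\1", name)
    name = re.sub(r"(\S)\[T\.", r"\1 [T.", name)
    return "(Intercept)" if name == "Intercept" else name


def fit_lme(
    metadata: SampleMetadata,
    spec: LMEModelSpec,
    reml: bool = True,
) -> LMEResult:
    """Fit the specified mixed model grouped by subject.

    Requires >=2 subjects with >=2 observations each and a non-constant
    numeric response.  A singular or non-converged fit is returned with
    ``converged=False`` and a warning recommending dropping the random
    slope rather than raising.
    """
    df = metadata.longitudinal_frame(extra_required=[spec.response]).copy()
    df = df[df[spec.response].notna()]
    y = df[spec.response].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"response {spec.response!r} is constant")
    counts = df.groupby(metadata.subject_column).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 subjects with >=2 observations each")

    formula = lme_formula(spec, metadata.state_column, columns=list(df.columns))
    re_formula = f"~{_quote(metadata.state_column)}" if spec.include_random_slope else "~1"
    groups = df[metadata.subject_column].astype(str)

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=groups, re_formula=re_formula)
        fitted = model.fit(reml=reml)
    for w in caught:
        if issubclass(w.category, (ConvergenceWarning, RuntimeWarning)):
            converged = False
    if not getattr(fitted, "converged", True):
        converged = False
    if not converged:
        logger.warning(
            "mixed-model fit did not converge cleanly; consider dropping the "
            "random slope or rescaling the state column"
        )

    fe_names = list(fitted.fe_params.index)
    est = fitted.fe_params.to_numpy(dtype=float)
    se = fitted.bse.loc[fe_names].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {"Estimate": est, "SE": se, "Z-score": z, "P-value": p},
        index=[_clean_term(n) for n in fe_names],
    )

    cov_re = np.asarray(fitted.cov_re, dtype=float)
    intercept_var = float(cov_re[0, 0]) if cov_re.size else 0.0
    if spec.include_random_slope and cov_re.shape == (2, 2):
        slope_var = float(cov_re[1, 1])
        cov_is = float(cov_re[0, 1])
    else:
        slope_var, cov_is = float("nan"), float("nan")

    return LMEResult(
        fixed_effects=fixed,
        intercept_variance=intercept_var,
        slope_variance=slope_var,
        intercept_slope_covariance=cov_is,
        residual_variance=float(fitted.scale),
        n_subjects=int(groups.nunique()),
        n_observations=int(len(df)),
        converged=converged,
        formula=formula,
    )
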