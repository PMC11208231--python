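"""Multivariate two-level mixed models for group differences and
brain-behaviour associations.

Outcomes of related tests are stacked into long format (one row per subject
x test) and analysed together in one linear mixed model with a subject-level
random intercept, which absorbs the within-subject correlation between
tests.  The fixed part of the group-difference model is

    value ~ Test + Group + Group x Test

parameterised here as ``value ~ 0 + C(test) + C(test):lbp`` so that each
``C(test)[t]:lbp`` coefficient *is* the per-test LBP - control difference
with its own standard error.  Association models replace the group
indicator with a continuous clinical predictor, giving per-muscle slopes;
significant pooled associations are re-fitted within each group
(stratified analysis).

Estimation is by REML; inference is Wald with normal critical values
(CI = beta +/- 1.96 * SE), and no multiple-testing adjustment is applied —
the shared multivariate model is relied on to temper multiplicity.
Residual variance is homogeneous across the tests of a family by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .mapping import MUSCLES
from .synth import CLINICAL_TESTS

__all__ = [
    "CoefficientEstimate",
    "ModelFamily",
    "ConvergenceError",
    "default_families",
    "stack_long",
    "fit_group_model",
    "fit_association_model",
    "stratified_association",
    "render_tables",
]

Z_95 = 1.96
ALPHA = 0.05


class ConvergenceError(RuntimeError):
    """Mixed-model optimisation failed; carries the optimizer diagnostics."""


@dataclass(frozen=True)
class CoefficientEstimate:
    """One per-test contrast: group difference or association slope."""

    test: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class ModelFamily:
    """A named set of test labels analysed together in one model."""

    name: str
    tests: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tests) == 0:
            raise ValueError(f"model family {self.name!r} has no tests")


def default_families(muscles: Sequence[str] = MUSCLES) -> dict[str, ModelFamily]:
    """The seven analysis families: four motor-map models (muscles as the
    Test variable) and three clinical models."""
    return {
        "area": ModelFamily("area", tuple(f"area:{m}" for m in muscles)),
        "cog_ml": ModelFamily("cog_ml", tuple(f"cog_x:{m}" for m in muscles)),
        "cog_ap": ModelFamily("cog_ap", tuple(f"cog_y:{m}" for m in muscles)),
        "cog_vert": ModelFamily("cog_vert", tuple(f"cog_z:{m}" for m in muscles)),
        "qst_pain": ModelFamily(
            "qst_pain", ("temporal_summation", "ppt", "cpm_rel", "cpm_abs")
        ),
        "sensory_accuracy": ModelFamily(
            "sensory_accuracy", ("two_point", "graphaesthesia", "vibration")
        ),
        "motor_test": ModelFamily("motor_test", ("path", "angular_near", "time_near")),
    }


def stack_long(outcomes: pd.DataFrame, family: ModelFamily) -> pd.DataFrame:
    """Wide outcome table -> long records (subject, group, test, value).

    Missing values are dropped, not imputed; the mixed model analyses the
    available rows by likelihood.
    """
    missing_cols = [t for t in family.tests if t not in outcomes.columns]
    if missing_cols:
        raise KeyError(f"outcome columns not found: {missing_cols}")
    id_vars = ["subject"] + (["group"] if "group" in outcomes.columns else [])
    long = outcomes.melt(
        id_vars=id_vars, value_vars=list(family.tests), var_name="test", value_name="value"
    )
    return long.dropna(subset=["value"]).reset_index(drop=True)


def _wald(beta: float, se: float) -> tuple[float, float, float]:
    if se <= 0:
        return beta, beta, 1.0
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta - Z_95 * se, beta + Z_95 * se, max(p, np.finfo(float).tiny)


def _extract(result, prefix: str, tests: Sequence[str], flags: tuple[str, ...]) -> list[CoefficientEstimate]:
    out = []
    for t in tests:
        name = f"C(test)[{t}]:{prefix}"
        if name not in result.params.index:
            continue
        beta = float(result.params[name])
        se = float(result.bse[name])
        lo, hi, p = _wald(beta, se)
        out.append(CoefficientEstimate(t, beta, se, lo, hi, p, flags))
    return out


def _degenerate_contrasts(
    long: pd.DataFrame, value_col: str, by: str
) -> list[CoefficientEstimate]:
    """Zero-variance data: report raw mean differences with SE 0, flagged."""
    out = []
    for t, sub in long.groupby("test", sort=False):
        means = sub.groupby(by)[value_col].mean()
        beta = float(means.get(1.0, 0.0) - means.get(0.0, 0.0)) if set(means.index) <= {0.0, 1.0} else 0.0
        out.append(CoefficientEstimate(t, beta, 0.0, beta, beta, 1.0, ("singular_fit",)))
    return out


def _fit_mixed(formula: str, long: pd.DataFrame):
    """REML fit with optimizer retries and a boundary fallback.

    When the subject-intercept variance is estimated at (or pushed to) zero
    the REML optimizer may report non-convergence; in that limit the mixed
    model reduces exactly to OLS on the same fixed effects, which is then
    used and flagged ``random_intercept_boundary``.
    """
    errors: list[str] = []
    for method in ("lbfgs", "powell", "cg"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                model = smf.mixedlm(formula, long, groups=long["subject"])
                result = model.fit(reml=True, method=method)
            except Exception as exc:  # singular design, optimizer failure, ...
                errors.append(f"{method}: {exc}")
                continue
        if result.converged and np.all(np.isfinite(result.bse.to_numpy())):
            singular = any(
                "boundary" in str(w.message).lower() or "singular" in str(w.message).lower()
                for w in caught
            )
            return result, ("singular_fit",) if singular else ()
        errors.append(
            f"{method}: " + ("non-finite standard errors" if result.converged else "did not converge")
        )
    try:
        ols = smf.ols(formula, long).fit()
    except Exception as exc:
        raise ConvergenceError(
            "mixed-model fit failed: " + "; ".join(errors) + f"; OLS fallback: {exc}"
        ) from exc
    return ols, ("random_intercept_boundary",)


def fit_group_model(long: pd.DataFrame) -> list[CoefficientEstimate]:
    """Per-test LBP - control differences from the stacked mixed model.

    ``long`` needs columns subject, group ("LBP"/"control"), test, value.
    Returns one :class:`CoefficientEstimate` per test, in the order the
    tests appear.
    """
    _require_columns(long, ("subject", "group", "test", "value"))
    if long["value"].isna().any():
        long = long.dropna(subset=["value"])
    counts = long.groupby("group")["subject"].nunique()
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("fit_group_model needs at least 2 subjects in each group")
    df = long.copy()
    df["lbp"] = (df["group"] == "LBP").astype(float)
    tests = list(dict.fromkeys(df["test"]))
    if _zero_residual_variance(df, "lbp"):
        return _degenerate_contrasts(df, "value", "lbp")
    result, flags = _fit_mixed("value ~ 0 + C(test) + C(test):lbp", df)
    return _extract(result, "lbp", tests, flags)


def fit_association_model(
    long: pd.DataFrame, predictor: str = "predictor"
) -> list[CoefficientEstimate]:
    """Per-test slopes of a clinical predictor on a multivariate map outcome.

    ``long`` needs columns subject, test, value and the predictor column
    (one value per subject, repeated over its tests).
    """
    _require_columns(long, ("subject", "test", "value", predictor))
    df = long.dropna(subset=["value", predictor]).copy()
    if df.empty:
        raise ValueError("no complete rows to fit")
    if float(np.var(df.groupby("subject")[predictor].first())) == 0.0:
        raise ValueError(f"predictor {predictor!r} has no variance across subjects")
    df = df.rename(columns={predictor: "_pred"})
    tests = list(dict.fromkeys(df["test"]))
    result, flags = _fit_mixed("value ~ 0 + C(test) + C(test):_pred", df)
    return _extract(result, "_pred", tests, flags)


def stratified_association(
    long: pd.DataFrame, group: str, predictor: str = "predictor"
) -> list[CoefficientEstimate]:
    """Re-fit a (significant) pooled association within one group."""
    _require_columns(long, ("group",))
    sub = long[long["group"] == group]
    if sub["subject"].nunique() < 3:
        raise ValueError(f"group {group!r} has fewer than 3 subjects")
    return fit_association_model(sub, predictor=predictor)


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"long table is missing columns: {missing}")


def _zero_residual_variance(df: pd.DataFrame, contrast_col: str) -> bool:
    resid = df.groupby(["test", contrast_col])["value"].transform(lambda v: v - v.mean())
    return bool(np.allclose(resid, 0.0, atol=1e-12))


# -- reporting -----------------------------------------------------------

def estimates_to_frame(
    estimates: Mapping[str, Sequence[CoefficientEstimate]]
) -> pd.DataFrame:
    rows = []
    for family, ests in estimates.items():
        for e in ests:
            rows.append(
                {
                    "family": family,
                    "test": e.test,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                    "flags": ";".join(e.flags),
                }
            )
    return pd.DataFrame(
        rows, columns=["family", "test", "beta", "se", "ci_low", "ci_high", "p", "flags"]
    )


def render_tables(
    estimates: Mapping[str, Sequence[CoefficientEstimate]],
    title: str = "Group differences (LBP - control)",
    predictor: str | None = None,
) -> str:
    """Plain-text report tables: beta (SE), 95 % CI, p; significant rows
    (p < 0.05) are marked with ``*``.  Two-point-discrimination association
    coefficients are presented x 5, matching the 5 mm step of the test."""
    scale = 5.0 if predictor == "two_point" else 1.0
    lines = [title, "=" * len(title)]
    if predictor is not None and scale != 1.0:
        lines.append(f"(coefficients x {scale:g}: predictor steps in units of {scale:g})")
    for family, ests in estimates.items():
        lines.append("")
        lines.append(f"[{family}]")
        lines.append(f"{'test':<28}{'beta (SE)':>22}{'95% CI':>26}{'p':>10}")
        for e in ests:
            b, s, lo, hi = (x * scale for x in (e.beta, e.se, e.ci_low, e.ci_high))
            mark = " *" if e.p < ALPHA else ""
            lines.append(
                f"{e.test:<28}{f'{b:.3f} ({s:.3f})':>22}"
                f"{f'[{lo:.3f}, {hi:.3f}]':>26}{e.p:>10.3f}{mark}"
            )
    return "\n".join(lines) + "\n"
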