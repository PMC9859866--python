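"""Group-level summaries and inference on per-sample SEM burdens.

The burden comparison mirrors the standard twin-cohort analysis: the natural
log of the per-sample SEM count is modelled with a linear mixed model,

    ln(count) ~ group + covariates,  random intercept per family,

fitted by REML; the group (case vs control) effect is assessed with a Wald
test. Samples with a zero count in the requested direction are excluded from
that direction's model (ln 0 is undefined; no pseudo-count offset is used,
so summary quantiles match the raw-count quantiles exactly under the
monotone log transform). When the family random-effect variance estimate
collapses to the zero boundary the model degenerates to OLS; we then refit
with family-cluster-robust standard errors and flag the fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from semscan.io_model import SampleSheet, ValidationError

_DIRECTIONS = ("hypo", "hyper")


def _check_direction(direction: str) -> str:
    if direction not in _DIRECTIONS:
        raise ValidationError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return direction


def _ln_column(direction: str) -> str:
    return f"ln_{direction}"


def _merged(burden: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    return burden.merge(sheet.table, on="sample_id", how="inner", validate="one_to_one")


@dataclass
class GroupSummary:
    group: str
    direction: str
    n: int  # samples with a positive count in this direction
    n_zero: int  # samples excluded for a zero count
    median: float
    q1: float
    q3: float


@dataclass
class BurdenModelResult:
    direction: str
    estimate: float  # fixed effect of case vs control on ln-burden
    se: float
    p_value: float
    covariates: tuple[str, ...]
    n_obs: int
    n_families: int
    method: str  # 'mixed_reml' or 'ols_cluster'
    converged: bool


def summarize_burden(burden: pd.DataFrame, sheet: SampleSheet, direction: str) -> list[GroupSummary]:
    """Median/Q1/Q3 of ln(count) per group, linear-interpolation quantiles.

    Zero-count samples are excluded from the quantiles and reported in
    n_zero. Groups are 'case' and 'control'; an empty group is an error.
    """
    _check_direction(direction)
    df = _merged(burden, sheet)
    col = _ln_column(direction)
    out = []
    for group in ("case", "control"):
        sub = df[df["group"] == group]
        if sub.empty:
            raise ValidationError(f"no samples in group {group!r}")
        ln = sub[col].dropna().to_numpy(dtype=float)
        if len(ln) == 0:
            raise ValidationError(f"group {group!r} has no positive {direction} counts")
        q1, med, q3 = np.quantile(ln, [0.25, 0.5, 0.75])
        out.append(
            GroupSummary(
                group=group,
                direction=direction,
                n=len(ln),
                n_zero=int(len(sub) - len(ln)),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    return out


def compare_burden_mixed(
    burden: pd.DataFrame,
    sheet: SampleSheet,
    direction: str,
    covariates: tuple[str, ...] = ("sex",),
) -> BurdenModelResult:
    """Mixed-effects comparison of ln-burden between cases and controls.

    Fits ln(count) ~ group + covariates with a family random intercept by
    REML and reports the Wald test on the group coefficient. Falls back to
    OLS with family-cluster-robust errors (with a warning) when the
    random-intercept variance hits the zero boundary or the fit fails.
    """
    _check_direction(direction)
    col = _ln_column(direction)
    df = _merged(burden, sheet)
    df = df[df["group"].isin(["case", "control"])].dropna(subset=[col]).copy()
    for g in ("case", "control"):
        if (df["group"] == g).sum() < 4:
            raise ValidationError(f"need >=4 positive-count samples in group {g!r} for direction {direction}")
    df["is_case"] = (df["group"] == "case").astype(float)
    df = df.rename(columns={col: "ln_burden"})

    terms = ["is_case"] + list(covariates)
    formula = "ln_burden ~ " + " + ".join(terms)
    n_families = df["family_id"].nunique()

    mixed_ok = False
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["family_id"])
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
            re_var = float(np.asarray(fit.cov_re)[0, 0])
            resid_var = float(fit.scale)
            if np.isfinite(fit.bse["is_case"]) and re_var > 1e-8 * max(resid_var, 1e-12):
                mixed_ok = True
                result = BurdenModelResult(
                    direction=direction,
                    estimate=float(fit.params["is_case"]),
                    se=float(fit.bse["is_case"]),
                    p_value=float(fit.pvalues["is_case"]),
                    covariates=tuple(covariates),
                    n_obs=int(fit.nobs),
                    n_families=n_families,
                    method="mixed_reml",
                    converged=bool(fit.converged),
                )
        except Exception:
            mixed_ok = False

    if not mixed_ok:
        warnings.warn(
            "family random-effect variance at zero boundary (or mixed fit failed); "
            "falling back to OLS with family-cluster-robust errors",
            stacklevel=2,
        )
        ols = smf.ols(formula, df).fit(
            cov_type="cluster", cov_kwds={"groups": df["family_id"]}, use_t=True
        )
        result = BurdenModelResult(
            direction=direction,
            estimate=float(ols.params["is_case"]),
            se=float(ols.bse["is_case"]),
            p_value=float(ols.pvalues["is_case"]),
            covariates=tuple(covariates),
            n_obs=int(ols.nobs),
            n_families=n_families,
            method="ols_cluster",
            converged=True,
        )
    return result


def paired_signed_rank(
    burden: pd.DataFrame,
    sheet: SampleSheet,
    direction: str,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank on within-pair ln-burden differences.

    Uses complete discordant pairs only (one case, one control, both with
    positive counts); differences are case minus control. Exact null
    distribution for n <= 25 pairs. All-zero differences give p = 1 with a
    warning.
    """
    _check_direction(direction)
    col = _ln_column(direction)
    df = _merged(burden, sheet).set_index("sample_id")
    pairs = sheet.discordant_pairs()
    diffs = []
    for _, row in pairs.iterrows():
        a = df[col].get(row["case_id"], np.nan)
        b = df[col].get(row["control_id"], np.nan)
        if np.isfinite(a) and np.isfinite(b):
            diffs.append(a - b)
    if len(diffs) < 5:
        raise ValidationError(f"need >=5 complete discordant pairs, got {len(diffs)}")
    diffs = np.asarray(diffs)
    if np.all(diffs == 0):
        warnings.warn("all within-pair differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if len(diffs) <= 25 else "auto"
    res = scipy.stats.wilcoxon(diffs, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
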