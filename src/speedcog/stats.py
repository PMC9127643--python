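"""Comparison statistics: effect sizes, regressions, and weighted norms.

The device comparison uses Cohen *d* (standardized mean difference,
touch screen minus keyboard, pooled SD) with a normal-approximation 95% CI,
Pearson correlations of each score with age within device group, and Cohen
*q* (difference of Fisher-z transformed correlations, keyboard minus touch)
to compare the age correlations across device types.  Distraction effects
are estimated by ordinary least squares with age as a covariate.
Population norms are survey-weighted age-group means with linearization
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .records import AGE_GROUP_EDGES, IntegrityError, SpeedcogError, age_group_label


class DegenerateInputError(SpeedcogError):
    """An input has no variance (or weights sum to zero) where variation is required."""


class CollinearityError(SpeedcogError):
    """The regression design matrix is rank deficient."""


_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectSizeResult:
    """Device comparison for one score: group summaries, d with CI, r's, q."""

    score_name: str
    mean_keyboard: float
    sd_keyboard: float
    n_keyboard: int
    mean_touch: float
    sd_touch: float
    n_touch: int
    d: float
    d_ci_low: float
    d_ci_high: float
    r_keyboard: float
    r_touch: float
    q: float


def cohen_d(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Cohen d for two independent groups from summary statistics.

    d = (m2 - m1) / s_p with the (n-1)-weighted pooled SD; the 95% CI is
    d +/- 1.96 * SE with SE^2 = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)).
    Group 1 is the reference (keyboard, in the device tables), so a positive
    d means group 2 (touch screen) has the higher mean.
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("cohen_d needs n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise DegenerateInputError("cohen_d needs positive SDs")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    d = (m2 - m1) / math.sqrt(pooled_var)
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return d, d - _Z95 * se, d + _Z95 * se


def cohen_d_from_samples(x1, x2) -> tuple[float, float, float]:
    """Cohen d computed from the raw group samples (ddof=1 SDs)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohen_d(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
    )


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateInputError("pearson_r needs equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson_r inputs must be non-constant")
    return float(scipy.stats.pearsonr(x, y).statistic)


def cohen_q(r1: float, r2: float) -> float:
    """Difference of Fisher-z transformed correlations, atanh(r1) - atanh(r2).

    When comparing age correlations across device types, r1 is the keyboard
    group and r2 the touch-screen group.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise DegenerateInputError(f"correlation must satisfy |r| < 1, got {r}")
    return math.atanh(r1) - math.atanh(r2)


def ols_regression(outcome: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS of ``outcome`` on ``predictors`` plus an intercept.

    Complete cases only; conventional (non-robust) SEs; two-sided p-values
    from the t distribution with n - p - 1 degrees of freedom.  Returns a
    tidy frame indexed by term with columns b, se, p, n.  Rank deficiency
    raises CollinearityError naming an offending column.
    """
    data = pd.concat([outcome.rename("__y__"), predictors], axis=1).dropna()
    y = data["__y__"].astype(float)
    X = data.drop(columns="__y__").astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateInputError(f"n={n} too small for {p} predictors")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        offender = _find_collinear_column(Xc)
        raise CollinearityError(f"design matrix is rank deficient (column: {offender})")
    fit = sm.OLS(y, Xc).fit()
    out = pd.DataFrame({"b": fit.params, "se": fit.bse, "p": fit.pvalues})
    out["n"] = n
    return out


def _find_collinear_column(X: pd.DataFrame) -> str:
    base = X.iloc[:, [0]].to_numpy()
    for col in X.columns[1:]:
        cand = np.column_stack([base, X[col].to_numpy()])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            return str(col)
        base = cand
    return str(X.columns[-1])


def partial_correlation(x, y, controls: pd.DataFrame | None = None) -> float:
    """Pearson correlation of x and y after removing the controls by OLS.

    With an empty control set this reduces exactly to ``pearson_r(x, y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or controls.shape[1] == 0:
        return pearson_r(x, y)
    C = sm.add_constant(controls.astype(float), has_constant="add").to_numpy()
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("residual variance is zero after controls")
    return float(np.corrcoef(rx, ry)[0, 1])


def weighted_group_norms(
    scores,
    weights,
    ages,
    edges: tuple[int, ...] = AGE_GROUP_EDGES,
) -> pd.DataFrame:
    """Survey-weighted mean score with 95% CI per age group.

    Weighted mean xbar_w = sum(w x)/sum(w); SE^2 = sum(w^2 (x - xbar_w)^2)
    / (sum w)^2 (linearization form); CI = xbar_w +/- 1.96 SE.  Groups of
    size 1 report the mean with NaN CI bounds.  Rows with missing scores
    are dropped; a group whose weights sum to zero raises
    DegenerateInputError.
    """
    frame = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "weight": np.asarray(weights, dtype=float),
            "age": np.asarray(ages, dtype=float),
        }
    ).dropna(subset=["score"])
    if (frame["weight"] < 0).any():
        raise IntegrityError("negative weights")
    labels = [age_group_label(e) for e in edges]
    frame["age_group"] = [age_group_label(a, edges) for a in frame["age"]]
    rows = []
    for label in labels:
        grp = frame.loc[frame["age_group"] == label]
        if grp.empty:
            rows.append(
                {
                    "age_group": label,
                    "weighted_mean": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_unweighted": 0,
                    "sum_weights": 0.0,
                }
            )
            continue
        w = grp["weight"].to_numpy()
        x = grp["score"].to_numpy()
        sw = w.sum()
        if sw <= 0:
            raise DegenerateInputError(f"weights sum to zero in group {label}")
        mean_w = float((w * x).sum() / sw)
        if len(grp) >= 2:
            se = math.sqrt(float((w**2 * (x - mean_w) ** 2).sum()) / sw**2)
            lo, hi = mean_w - _Z95 * se, mean_w + _Z95 * se
        else:
            lo = hi = np.nan
        rows.append(
            {
                "age_group": label,
                "weighted_mean": mean_w,
                "ci_low": lo,
                "ci_high": hi,
                "n_unweighted": len(grp),
                "sum_weights": float(sw),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedComparison:
    """Within-person device comparison of one score."""

    score_name: str
    n_pairs: int
    n_dropped: int
    mean_diff: float  # touch - keyboard
    paired_d: float | None  # mean diff / SD of diffs; None if SD == 0
    cross_device_r: float


def within_person_device_comparison(
    scores: pd.DataFrame, score_name: str = "score"
) -> PairedComparison:
    """Paired comparison for respondents who completed both devices.

    ``scores`` has columns respondent_id, device_type, and ``score_name``.
    Each respondent may contribute at most one score per device; duplicates
    raise IntegrityError.  Respondents missing either device are dropped
    (counted in ``n_dropped``).
    """
    if scores.duplicated(subset=["respondent_id", "device_type"]).any():
        raise IntegrityError("duplicate device entries for a respondent")
    wide = scores.pivot(
        index="respondent_id", columns="device_type", values=score_name
    )
    for col in ("keyboard", "touchscreen"):
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide.dropna(subset=["keyboard", "touchscreen"])
    n_dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise DegenerateInputError("need >= 3 complete pairs")
    diffs = (complete["touchscreen"] - complete["keyboard"]).to_numpy()
    sd = diffs.std(ddof=1)
    return PairedComparison(
        score_name=score_name,
        n_pairs=len(complete),
        n_dropped=n_dropped,
        mean_diff=float(diffs.mean()),
        paired_d=float(diffs.mean() / sd) if sd > 0 else None,
        cross_device_r=pearson_r(complete["keyboard"], complete["touchscreen"]),
    )


def device_effect_table(
    scores: pd.DataFrame, respondents: pd.DataFrame, score_cols: list[str]
) -> pd.DataFrame:
    """Between-person device comparison table (one row per score).

    ``scores`` holds one session per respondent with a device_type column;
    age is merged in from ``respondents``.  Each row carries group means,
    SDs, ns, Cohen d with CI, the per-group age correlations, and Cohen q
    (keyboard minus touch).
    """
    merged = scores.merge(
        respondents[["respondent_id", "age"]], on="respondent_id", how="inner"
    )
    kb = merged.loc[merged["device_type"] == "keyboard"]
    tc = merged.loc[merged["device_type"] == "touchscreen"]
    rows = []
    for col in score_cols:
        k = kb[col].dropna()
        t = tc[col].dropna()
        d, lo, hi = cohen_d(
            k.mean(), k.std(ddof=1), len(k), t.mean(), t.std(ddof=1), len(t)
        )
        rk = pearson_r(kb.dropna(subset=[col])["age"], k)
        rt = pearson_r(tc.dropna(subset=[col])["age"], t)
        res = EffectSizeResult(
            score_name=col,
            mean_keyboard=float(k.mean()),
            sd_keyboard=float(k.std(ddof=1)),
            n_keyboard=len(k),
            mean_touch=float(t.mean()),
            sd_touch=float(t.std(ddof=1)),
            n_touch=len(t),
            d=d,
            d_ci_low=lo,
            d_ci_high=hi,
            r_keyboard=rk,
            r_touch=rt,
            q=cohen_q(rk, rt),
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def distraction_regression_table(
    scores: pd.DataFrame,
    respondents: pd.DataFrame,
    environment: pd.DataFrame,
    score_cols: list[str],
    env_cols: list[str],
) -> pd.DataFrame:
    """Regress each score on the binary environment fields, controlling for age.

    Returns a tidy frame with columns outcome, term, b, se, p, n covering
    the environment terms (age and intercept rows are retained under their
    own term names).
    """
    merged = scores.merge(
        respondents[["respondent_id", "age"]], on="respondent_id"
    ).merge(environment, on=["respondent_id", "session_index"], how="inner")
    # a distractor nobody (or everybody) reported carries no information and
    # would make the design matrix singular
    usable = [c for c in env_cols if merged[c].nunique() > 1]
    frames = []
    for col in score_cols:
        fit = ols_regression(merged[col], merged[[*usable, "age"]])
        tidy = fit.reset_index(names="term")
        tidy.insert(0, "outcome", col)
        frames.append(tidy)
    return pd.concat(frames, ignore_index=True)
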