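"""Longitudinal statistics for LDP descriptors.

Nonparametric exploratory layer (box-whisker summaries with 5/95% whiskers,
Kruskal-Wallis and Mann-Whitney tests at alpha = 0.05, Gaussian-kernel
marginal densities) plus a linear mixed model for the gender contrast:

    response ~ 1 + t_c + gender + t_c:gender,   random: ~ 1 + t_c | subject

with t_c the centred timepoint (for MRI1..4, t_c in {-1.5, -0.5, 0.5, 1.5}),
so the gender fixed effect is the group offset evaluated midway between MRI2
and MRI3.  Female is the reference level; the male coefficient is negative
when the male subgroup sits lower.  Fitted by REML with Wald 95% CIs.

Raw p-values are reported without multiple-testing correction; the printed
alpha = 0.05 applies test-wise.  Quantiles use linear interpolation of order
statistics throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "BoxSummary",
    "MixedModelResult",
    "box_summary",
    "kruskal_wallis",
    "mann_whitney",
    "marginal_density",
    "fit_longitudinal_model",
    "normality_report",
]

ALPHA = 0.05


@dataclasses.dataclass
class BoxSummary:
    """Five-number box-whisker summary with 5/95% whiskers."""

    median: float
    q25: float
    q75: float
    whisker_low: float  # 5% quantile
    whisker_high: float  # 95% quantile
    outliers: np.ndarray  # points outside the whiskers
    n: int


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Median, IQR, 5/95% whiskers and outliers of a sample.

    Quantiles are linear interpolations of the order statistics (numpy's
    default ``linear`` method).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_summary needs at least one value")
    q05, q25, med, q75, q95 = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95])
    outliers = v[(v < q05) | (v > q95)]
    return BoxSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(q05),
        whisker_high=float(q95),
        outliers=outliers,
        n=int(v.size),
    )


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    A fully degenerate input (every value identical across all groups)
    returns (0, 1) by convention instead of erroring.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def mann_whitney(
    g1: Sequence[float], g2: Sequence[float], two_sided: bool = True
) -> tuple[float, float]:
    """Mann-Whitney U with tie handling.

    The p-value is exact when both groups have <= 8 observations and no ties
    occur, otherwise the tie-corrected normal approximation is used.  Two
    identical degenerate samples return p = 1.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alternative = "two-sided" if two_sided else "greater"
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def marginal_density(
    values: Sequence[float],
    bandwidth: float | str | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate on an explicit grid.

    The grid spans the data extended by three bandwidths each side so that
    the density integrates to 1 within 1e-3 (trapezoidal rule).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("density estimation needs at least two values")
    if np.std(v) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    kde = sps.gaussian_kde(v, bw_method=bandwidth)
    bw = float(kde.factor * np.std(v, ddof=1))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, n_grid)
    return grid, kde(grid)


@dataclasses.dataclass
class MixedModelResult:
    """Fixed and random effects of the longitudinal gender model."""

    response: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p
    random_intercept_var: float
    random_slope_var: float
    random_corr: float
    residual_var: float
    n_subjects: int
    n_observations: int
    converged: bool
    singular: bool
    method: str = "REML, Wald CIs"

    @property
    def gender_offset(self) -> float:
        """Male-vs-female offset evaluated at the centred timepoint t_c = 0."""
        return float(self.fixed_effects.loc["gender", "estimate"])

    def gender_offset_ci(self) -> tuple[float, float]:
        row = self.fixed_effects.loc["gender"]
        return float(row["ci_low"]), float(row["ci_high"])


def fit_longitudinal_model(
    data: pd.DataFrame, response: str = "A", reml: bool = True
) -> MixedModelResult:
    """Linear mixed model for the gender difference in a descriptor over time.

    ``data`` needs columns ``subject_id, timepoint, gender`` and the response
    (``A`` or ``C``), with >= 2 subjects per gender and >= 2 timepoints per
    subject.  The centred timepoint is computed from the unique timepoint
    values present.  Returns Wald 95% CIs; non-convergence and a singular
    random-effects covariance are reported via flags, not exceptions.
    """
    df = data.copy()
    required = {"subject_id", "timepoint", "gender", response}
    if not required <= set(df.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    genders = set(df["gender"].unique())
    if not genders <= {"F", "M"} or len(genders) != 2:
        raise ValueError("data must contain exactly the genders F and M")
    per_gender = df.groupby("gender")["subject_id"].nunique()
    if (per_gender < 2).any():
        raise ValueError("need at least 2 subjects per gender")
    per_subject = df.groupby("subject_id")["timepoint"].nunique()
    if (per_subject < 2).any():
        raise ValueError("need at least 2 timepoints per subject")

    tps = np.sort(df["timepoint"].unique())
    df["t_c"] = df["timepoint"] - tps.mean()
    df["gender_male"] = (df["gender"] == "M").astype(float)
    df = df.rename(columns={response: "_y"})

    model = smf.mixedlm(
        "_y ~ t_c + gender_male + t_c:gender_male",
        df,
        groups=df["subject_id"],
        re_formula="~t_c",
    )
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=reml)
        params = result.fe_params
        se = result.bse_fe
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                singular = True
    z = sps.norm.ppf(1 - ALPHA / 2)
    terms = {
        "Intercept": "intercept",
        "t_c": "time",
        "gender_male": "gender",
        "t_c:gender_male": "time:gender",
    }
    fe = pd.DataFrame(
        {
            "estimate": [params[k] for k in terms],
            "se": [se[k] for k in terms],
        },
        index=list(terms.values()),
    )
    fe["ci_low"] = fe["estimate"] - z * fe["se"]
    fe["ci_high"] = fe["estimate"] + z * fe["se"]
    fe["p"] = 2 * sps.norm.sf(np.abs(fe["estimate"] / fe["se"]))

    cov_re = np.asarray(result.cov_re)
    var_int = float(cov_re[0, 0])
    var_slope = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0
    if cov_re.shape[0] > 1 and var_int > 0 and var_slope > 0:
        corr = float(cov_re[0, 1] / np.sqrt(var_int * var_slope))
    else:
        corr = float("nan")
        singular = True
    if min(var_int, var_slope) <= 0:
        singular = True

    return MixedModelResult(
        response=response,
        fixed_effects=fe,
        random_intercept_var=var_int,
        random_slope_var=var_slope,
        random_corr=corr,
        residual_var=float(result.scale),
        n_subjects=int(df["subject_id"].nunique()),
        n_observations=int(len(df)),
        converged=bool(result.converged),
        singular=singular,
    )


def normality_report(values: Sequence[float]) -> pd.DataFrame:
    """Optional normality diagnostics (Shapiro-Wilk, Anderson-Darling,
    Lilliefors); informative only — they never gate the nonparametric route."""
    from statsmodels.stats.diagnostic import lilliefors

    v = np.asarray(values, dtype=float)
    sw_stat, sw_p = sps.shapiro(v)
    ad = sps.anderson(v, dist="norm", method="interpolate")
    lf_stat, lf_p = lilliefors(v, dist="norm")
    return pd.DataFrame(
        [
            {"test": "shapiro_wilk", "statistic": float(sw_stat), "p_value": float(sw_p)},
            {
                "test": "anderson_darling",
                "statistic": float(ad.statistic),
                "p_value": float(ad.pvalue),
            },
            {"test": "lilliefors", "statistic": float(lf_stat), "p_value": float(lf_p)},
        ]
    )
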