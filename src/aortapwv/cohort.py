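"""Cohort-level statistics: the age+sex reference model for PWV,
residual-adjusted correlations, Bland-Altman agreement and the paired
Wilcoxon comparison of the arrival-time algorithms.

The reference model is ordinary least squares

    PWV = beta0 + beta_age * age + beta_male * male + eps,  eps ~ N(0, sigma)

with male coded 1 and female 0. "Adjusted" correlations are Pearson
correlations between the residuals of both variables after regressing
each on age and sex, so they measure association beyond the shared aging
and sex effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AorticReferenceModel",
    "ReferenceModelResults",
    "fit_reference_model",
    "adjusted_correlation",
    "AdjustedCorrelation",
    "bland_altman",
    "BlandAltmanResult",
    "compare_methods_wilcoxon",
]


PWV_COLUMNS = {"xcor": "pwv_xcor", "ttf": "pwv_ttf", "half_peak": "pwv_half_peak"}


def _male_indicator(df: pd.DataFrame) -> np.ndarray:
    if "male" in df:
        return df["male"].to_numpy(dtype=float)
    if "sex" in df:
        return (df["sex"].astype(str).str.lower() == "male").to_numpy(dtype=float)
    raise ValueError("cohort table needs a 'male' (0/1) or 'sex' column")


class AorticReferenceModel:
    """Age- and sex-dependent linear reference model for aortic PWV."""

    def __init__(self, age: np.ndarray, male: np.ndarray, pwv: np.ndarray):
        self.age = np.asarray(age, dtype=float)
        self.male = np.asarray(male, dtype=float)
        self.pwv = np.asarray(pwv, dtype=float)
        if not (len(self.age) == len(self.male) == len(self.pwv)):
            raise ValueError("age, male and pwv must align")
        if len(self.age) < 4:
            raise ValueError("need at least 4 subjects to fit the model")
        if len(np.unique(self.male)) < 2:
            raise ValueError(
                "single-sex cohort: the male coefficient is not estimable"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, method: str = "xcor"
    ) -> "AorticReferenceModel":
        col = PWV_COLUMNS.get(method, method)
        if col not in df:
            raise KeyError(f"no PWV column {col!r} in the cohort table")
        sub = df[np.isfinite(df[col])]
        return cls(sub["age"].to_numpy(), _male_indicator(sub), sub[col].to_numpy())

    def fit(self) -> "ReferenceModelResults":
        X = sm.add_constant(np.column_stack([self.age, self.male]))
        res = sm.OLS(self.pwv, X).fit()
        # augmented fit for the age-by-sex interaction
        Xi = sm.add_constant(
            np.column_stack([self.age, self.male, self.age * self.male])
        )
        res_i = sm.OLS(self.pwv, Xi).fit()
        ci = res.conf_int(alpha=0.05)
        return ReferenceModelResults(
            beta0=float(res.params[0]),
            beta_age=float(res.params[1]),
            beta_male=float(res.params[2]),
            sigma=float(np.sqrt(res.scale)),
            conf_int={
                "beta0": tuple(ci[0]),
                "beta_age": tuple(ci[1]),
                "beta_male": tuple(ci[2]),
            },
            interaction_pvalue=float(res_i.pvalues[3]),
            nobs=int(res.nobs),
            _sm_results=res,
        )


@dataclass
class ReferenceModelResults:
    """OLS estimates of the PWV reference model."""

    beta0: float
    beta_age: float
    beta_male: float
    sigma: float  # residual sd, sqrt(SSR / (n - 3))
    conf_int: dict[str, tuple[float, float]]
    interaction_pvalue: float
    nobs: int
    _sm_results: object = None

    def predict(self, age: float | np.ndarray, male: int | np.ndarray) -> np.ndarray:
        """Reference PWV (m/s) for given age (years) and sex (male=1)."""
        return self.beta0 + self.beta_age * np.asarray(age) + self.beta_male * np.asarray(male)

    def summary(self) -> str:
        lines = [
            f"PWV reference model (n = {self.nobs})",
            f"  PWV = {self.beta0:.2f} + {self.beta_age:.3f}*age + "
            f"{self.beta_male:.2f}*male  (m/s)",
            f"  residual sd sigma = {self.sigma:.2f} m/s",
        ]
        for name in ("beta0", "beta_age", "beta_male"):
            lo, hi = self.conf_int[name]
            lines.append(f"  {name:<9} 95% CI [{lo:8.4f}, {hi:8.4f}]")
        lines.append(f"  age x sex interaction p = {self.interaction_pvalue:.3f}")
        return "\n".join(lines)


def fit_reference_model(df: pd.DataFrame, method: str = "xcor") -> ReferenceModelResults:
    """Fit the age+sex reference regression on a cohort table."""
    return AorticReferenceModel.from_dataframe(df, method).fit()


@dataclass
class AdjustedCorrelation:
    x: str
    y: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]


def adjusted_correlation(
    df: pd.DataFrame,
    x: str,
    y: str,
    covariates: tuple[str, ...] = ("age", "male"),
) -> AdjustedCorrelation:
    """Pearson correlation between covariate-adjusted residuals.

    Each of ``x`` and ``y`` is regressed on the covariates (with
    intercept); the residual vectors are then correlated. With an empty
    covariate tuple this reduces exactly to the plain Pearson correlation.
    The p-value uses n - 2 degrees of freedom on the residual vectors and
    is therefore approximate in the adjusted case.
    """
    cols = {"male": _male_indicator(df)} if "male" in covariates and "male" not in df else {}
    work = df.assign(**cols)
    used = [x, y, *covariates]
    sub = work[used].dropna()
    if len(sub) < 4:
        raise ValueError("need at least 4 complete observations")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if covariates:
        Z = sm.add_constant(sub[list(covariates)].to_numpy(dtype=float))
        xv = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        yv = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return AdjustedCorrelation(
        x=x, y=y, r=float(r), p=float(p), n=len(sub), covariates=tuple(covariates)
    )


@dataclass
class BlandAltmanResult:
    """Agreement between two observers/methods on paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray
    diffs: np.ndarray

    def summary(self) -> str:
        return (
            f"Bland-Altman (n = {self.n}): mean difference "
            f"{self.mean_diff:.2f}, sd {self.sd_diff:.2f}, limits of "
            f"agreement [{self.loa_low:.2f}, {self.loa_high:.2f}]"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.means, self.diffs, "o", ms=4)
        ax.axhline(self.mean_diff, color="k")
        for v in (self.loa_low, self.loa_high):
            ax.axhline(v, color="k", ls="--")
        ax.set_xlabel("mean of the paired measurements")
        ax.set_ylabel("difference (obs2 - obs1)")
        return ax


def bland_altman(obs1: np.ndarray, obs2: np.ndarray) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sd)."""
    obs1 = np.asarray(obs1, dtype=float)
    obs2 = np.asarray(obs2, dtype=float)
    if obs1.shape != obs2.shape or obs1.ndim != 1:
        raise ValueError("obs1 and obs2 must be equal-length 1-D arrays")
    if len(obs1) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = obs2 - obs1
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=len(diffs),
        means=(obs1 + obs2) / 2.0,
        diffs=diffs,
    )


def compare_methods_wilcoxon(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    exact_threshold: int = 25,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Uses the exact null distribution for n <= ``exact_threshold`` non-zero
    differences and the normal approximation with continuity correction
    above. Identical pairs throughout are rejected (statistic undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    d = b - a
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if len(d) <= exact_threshold else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.pvalue)
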