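"""Normative comparison of a single patient profile against fitted norms.

The multivariate statistic is Hotelling's T^2 adapted for single-case
normative comparisons,

    T2 = [n/(n+1)] * [(n-p)/((n-1)p)] * (yhat - x)' C^{-1} (yhat - x)

referred to an F distribution with (p, df2) degrees of freedom, where n is
the number of participants in the norm group, p the number of tests, x the
patient's scores, yhat the covariate-matched predicted normative profile,
and C the combined (within + between study) covariance. df2 is the
multilevel-adjusted denominator df (observations - studies - fixed effects
- 1), replacing the classical n - p.

The clinical decision rule is one-sided: a patient is flagged as deviating
only if the sum of standardized deviations is in the impaired direction
(negative, lower-is-worse) and the two-sided p-value does not exceed 0.10,
which targets an overall false positive rate of 0.05 under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NumericalError


@dataclass
class PatientProfile:
    """A patient's covariates and complete score vector on the modeled tests.

    Covariates must already be on the norm group's centered scale (use the
    norm group's :class:`~mnc.data.CenteringInfo`, never recenter a single
    patient). Scores must be complete: if the patient did not complete some
    tests, refit the model to the completed subset first.
    """

    covariates: dict = field(default_factory=dict)
    scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise InputError(
                "patient scores contain missing/non-finite values; refit the "
                "model to the tests the patient completed"
            )


def _worst_conditioned_pair(C: np.ndarray) -> tuple[int, int]:
    d = np.sqrt(np.diag(C))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = C / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(R)), R.shape)
    return int(min(i, j)) + 1, int(max(i, j)) + 1


def t2_norm(x, y_hat, C, n: int, df2: int,
            df_scaling: str = "participants") -> tuple[float, float]:
    """Adapted Hotelling T^2 and its two-sided p-value.

    Parameters
    ----------
    x, y_hat : array-like, length p
        Patient scores and covariate-matched predicted normative profile.
    C : (p, p) array
        Combined covariance of the norm population (within + between).
    n : int
        Number of participants in the norm group (total, across studies).
    df2 : int
        Adjusted denominator degrees of freedom.
    df_scaling : {"participants", "adjusted"}
        Which df convention feeds the scaling constants. The stated
        convention ("participants") keeps n in (n-p)/((n-1)p) and only
        replaces the F denominator df by ``df2``; "adjusted" instead uses
        the classical identity with ``df2`` playing the role of n-1, i.e.
        scale (df2-p+1)/(df2*p) referred to F(p, df2-p+1). The two agree
        to O(1/n) for the large norm groups this method targets.
    """
    x = np.asarray(x, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    C = np.asarray(C, float)
    p = x.size
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite patient score")
    if n <= p:
        raise NumericalError(f"norm group size n={n} must exceed p={p}")
    if df2 < 1:
        raise NumericalError(f"denominator df must be >= 1, got {df2}")
    d = y_hat - x
    try:
        sol = np.linalg.solve(C, d)
        if np.linalg.cond(C) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        i, j = _worst_conditioned_pair(C)
        raise NumericalError(
            f"combined covariance is (near-)singular; worst-conditioned "
            f"test pair: ({i}, {j})"
        ) from None
    if df_scaling == "participants":
        scale = (n / (n + 1.0)) * ((n - p) / ((n - 1.0) * p))
        f_df2 = df2
    elif df_scaling == "adjusted":
        scale = (n / (n + 1.0)) * ((df2 - p + 1.0) / (df2 * p))
        f_df2 = df2 - p + 1
    else:
        raise ValueError("df_scaling must be 'participants' or 'adjusted'")
    t2 = float(scale * d @ sol)
    p_value = float(stats.f.sf(t2, p, f_df2))
    return t2, p_value


def univariate_comparisons(x, y_hat, C, n: int, df2: int, alpha: float = 0.05,
                           ) -> pd.DataFrame:
    """Per-test one-sided normative t comparisons (lower scores = impaired).

    ``t = (x_m - yhat_m) / sqrt(C_mm * (n+1)/n)`` referred to a t
    distribution with the adjusted df; flagged at ``alpha`` (uncorrected)
    and at ``alpha/p`` (Bonferroni).
    """
    x = np.asarray(x, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    C = np.asarray(C, float)
    p = x.size
    cdiag = np.diag(C)
    if np.any(cdiag <= 0):
        raise NumericalError("non-positive variance on the diagonal of C")
    t = (x - y_hat) / np.sqrt(cdiag * (n + 1.0) / n)
    p_one = stats.t.cdf(t, df2)
    return pd.DataFrame(
        {
            "test": np.arange(1, p + 1),
            "t": t,
            "p_one_sided": p_one,
            "significant": p_one <= alpha,
            "significant_bonferroni": p_one <= alpha / p,
        }
    ).set_index("test")


def one_sided_decision(sum_std_dev: float, p_two_sided: float,
                       threshold: float = 0.10) -> bool:
    """Two-criterion one-sided rule: deviating iff the summed standardized
    deviation is negative (impaired direction) and p <= threshold."""
    return bool(sum_std_dev < 0 and p_two_sided <= threshold)


@dataclass
class ComparisonResult:
    """Outcome of one multivariate normative comparison."""

    t2: float
    df1: int
    df2: int
    p_value: float                     # two-sided
    deviations: np.ndarray             # x - yhat
    standardized_deviations: np.ndarray
    sum_std_dev: float
    decision_two_sided: bool
    decision_one_sided: bool
    univariate: pd.DataFrame
    n: int
    alpha: float = 0.05
    one_sided_threshold: float = 0.10

    @property
    def any_univariate(self) -> bool:
        """Familywise: at least one uncorrected univariate rejection."""
        return bool(self.univariate["significant"].any())

    @property
    def any_univariate_bonferroni(self) -> bool:
        return bool(self.univariate["significant_bonferroni"].any())

    def summary(self) -> str:
        ptxt = "< 0.001" if self.p_value < 0.001 else f"= {self.p_value:.3f}"
        lines = [
            f"T2({self.df1}, {self.df2}) = {self.t2:.2f}, p {ptxt}",
            f"sum of standardized deviations: {self.sum_std_dev:.2f}",
            f"two-sided decision (alpha={self.alpha}): "
            + ("deviating" if self.decision_two_sided else "not deviating"),
            f"one-sided decision (negative sum and p <= "
            f"{self.one_sided_threshold}): "
            + ("deviating" if self.decision_one_sided else "not deviating"),
            "",
            "univariate comparisons (one-sided, lower = impaired):",
            self.univariate.to_string(
                float_format=lambda v: f"{v:.4f}",
                formatters={
                    "significant": lambda b: " *" if b else "  ",
                    "significant_bonferroni": lambda b: " *" if b else "  ",
                },
            ),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "t2": self.t2,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "deviations": self.deviations.tolist(),
            "standardized_deviations": self.standardized_deviations.tolist(),
            "sum_std_dev": self.sum_std_dev,
            "decision_two_sided": self.decision_two_sided,
            "decision_one_sided": self.decision_one_sided,
            "any_univariate": self.any_univariate,
            "any_univariate_bonferroni": self.any_univariate_bonferroni,
            "univariate": self.univariate.reset_index().to_dict(orient="records"),
            "n": self.n,
            "alpha": self.alpha,
            "one_sided_threshold": self.one_sided_threshold,
        }


def compare_profile(x, y_hat, C, n: int, df2: int, alpha: float = 0.05,
                    one_sided_threshold: float = 0.10) -> ComparisonResult:
    """Assemble the full multivariate + univariate comparison."""
    x = np.asarray(x, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    C = np.asarray(C, float)
    p = x.size
    if df2 <= p:
        raise NumericalError(
            f"adjusted df ({df2}) must exceed the number of tests ({p}) "
            "for the F reference distribution"
        )
    t2, p_value = t2_norm(x, y_hat, C, n, df2)
    dev = x - y_hat
    std_dev = dev / np.sqrt(np.diag(C))
    sum_std = float(std_dev.sum())
    uni = univariate_comparisons(x, y_hat, C, n, df2, alpha=alpha)
    return ComparisonResult(
        t2=t2,
        df1=p,
        df2=df2,
        p_value=p_value,
        deviations=dev,
        standardized_deviations=std_dev,
        sum_std_dev=sum_std,
        decision_two_sided=bool(p_value <= alpha),
        decision_one_sided=one_sided_decision(sum_std, p_value, one_sided_threshold),
        univariate=uni,
        n=n,
        alpha=alpha,
        one_sided_threshold=one_sided_threshold,
    )
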