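"""Results object: estimates, uncertainties, norms and patient comparison."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparison import ComparisonResult, PatientProfile, compare_profile
from .data import CenteringInfo
from .errors import NumericalError

__all__ = ["MultilevelNormativeResults"]


@dataclass
class MultilevelNormativeResults:
    """Fitted three-level normative model.

    Attributes
    ----------
    gamma : ndarray, p x (1 + c)
        Fixed effects: column 0 intercepts, then one slope column per
        covariate.
    sigma_within : ndarray, p x p
        Unrestricted within-study residual covariance.
    sigma_between : ndarray, length p
        Between-study intercept variances (diagonal between covariance).
    gamma_cov : ndarray
        GLS covariance of the fixed effects (vec by covariate-major order).
    """

    gamma: np.ndarray
    sigma_within: np.ndarray
    sigma_between: np.ndarray
    llf: float
    converged: bool
    n_obs: int
    n_participants: int
    n_studies: int
    covariates: tuple = ()
    estimate_between: bool = True
    gamma_cov: np.ndarray | None = None
    covariate_ranges: dict = field(default_factory=dict)
    n_optimizer_tries: int = 1
    centering: CenteringInfo | None = None
    test_names: dict = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------------

    @property
    def p(self) -> int:
        return self.sigma_within.shape[0]

    @property
    def k_fe(self) -> int:
        """Number of estimated fixed effects q = p * (1 + #covariates)."""
        return self.p * (1 + len(self.covariates))

    def adjusted_df(self) -> int:
        """Denominator df: observations - (studies + fixed effects + 1).

        This is the multilevel adjustment replacing the classical n - p: with
        missing data and nesting, observations are neither complete nor
        independent.
        """
        df = self.n_obs - (self.n_studies + self.k_fe + 1)
        if df <= self.p:
            raise NumericalError(
                f"adjusted df {df} <= p {self.p}: the F reference "
                "distribution for the comparison is undefined"
            )
        return int(df)

    @property
    def combined_covariance(self) -> np.ndarray:
        """C = Sigma_w + diag(sigma_b2): covariance of a new participant
        from a new study, used for all normative comparisons."""
        return self.sigma_within + np.diag(self.sigma_between)

    # -- norms ---------------------------------------------------------------

    def _covariate_vector(self, covariates) -> np.ndarray:
        if isinstance(covariates, dict):
            vals = [covariates[c] for c in self.covariates]
        else:
            vals = list(np.asarray(covariates, float).ravel())
            if len(vals) != len(self.covariates):
                raise ValueError(
                    f"expected {len(self.covariates)} covariates "
                    f"{self.covariates}, got {len(vals)}"
                )
        for name, v in zip(self.covariates, vals):
            lo, hi = self.covariate_ranges.get(name, (-np.inf, np.inf))
            if not lo <= v <= hi:
                warnings.warn(
                    f"covariate {name}={v} outside the norm group's observed "
                    f"range [{lo:.3g}, {hi:.3g}]; prediction extrapolates",
                    stacklevel=3,
                )
        return np.asarray(vals, float)

    def predict_profile(self, covariates=()) -> np.ndarray:
        """Predicted normative profile for given (centered) covariates:
        ``yhat_m = gamma_m0 + sum_c gamma_mc * covariate_c``."""
        u = np.concatenate([[1.0], self._covariate_vector(covariates)])
        return self.gamma @ u

    def compare(self, patient, alpha: float = 0.05,
                one_sided_threshold: float = 0.10) -> ComparisonResult:
        """Multivariate + univariate normative comparison for one patient.

        ``patient`` is a :class:`~mnc.comparison.PatientProfile` (covariates
        already on the norm group's centered scale) or a plain score vector
        when the model has no covariates.
        """
        if isinstance(patient, PatientProfile):
            x = patient.scores
            y_hat = self.predict_profile(patient.covariates)
        else:
            x = np.asarray(patient, float).ravel()
            if self.covariates:
                raise ValueError(
                    "model has covariates; pass a PatientProfile so the "
                    "norms can be covariate-matched"
                )
            y_hat = self.predict_profile(())
        if x.size != self.p:
            raise ValueError(f"patient has {x.size} scores, model has p={self.p}")
        return compare_profile(
            x, y_hat, self.combined_covariance,
            n=self.n_participants, df2=self.adjusted_df(),
            alpha=alpha, one_sided_threshold=one_sided_threshold,
        )

    # -- presentation ----------------------------------------------------------

    @property
    def fe_params(self) -> pd.DataFrame:
        cols = ["intercept"] + list(self.covariates)
        return pd.DataFrame(self.gamma, columns=cols,
                            index=pd.RangeIndex(1, self.p + 1, name="test"))

    @property
    def bse(self) -> pd.DataFrame:
        """Standard errors of the fixed effects (GLS information)."""
        if self.gamma_cov is None:
            raise ValueError("no fixed-effect covariance available")
        se = np.sqrt(np.diag(self.gamma_cov)).reshape(
            1 + len(self.covariates), self.p
        ).T
        cols = ["intercept"] + list(self.covariates)
        return pd.DataFrame(se, columns=cols,
                            index=pd.RangeIndex(1, self.p + 1, name="test"))

    def summary(self) -> str:
        icc = self.sigma_between / (
            np.diag(self.sigma_within) + self.sigma_between
        )
        lines = [
            "Multilevel multivariate normative model (FIML)",
            "=" * 54,
            f"tests: {self.p}   studies: {self.n_studies}   "
            f"participants: {self.n_participants}   scores: {self.n_obs}",
            f"log-likelihood: {self.llf:.3f}   converged: {self.converged}",
            f"fixed effects: {self.k_fe}   adjusted df: "
            f"{self.n_obs - (self.n_studies + self.k_fe + 1)}",
            "",
            "Fixed effects (per test):",
            self.fe_params.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "Within-study residual variances (diagonal of Sigma_w):",
            np.array2string(np.diag(self.sigma_within), precision=3),
            "Between-study intercept variances (sigma_b2):",
            np.array2string(self.sigma_between, precision=3),
            "ICC per test (between / total):",
            np.array2string(icc, precision=3),
        ]
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        tril = np.tril_indices(self.p)
        payload = {
            "p": self.p,
            "covariates": list(self.covariates),
            "gamma": self.gamma.tolist(),
            "sigma_within_tril": self.sigma_within[tril].tolist(),
            "sigma_between": self.sigma_between.tolist(),
            "llf": self.llf,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "n_studies": self.n_studies,
            "estimate_between": self.estimate_between,
            "covariate_ranges": {k: list(v) for k, v in self.covariate_ranges.items()},
            "n_optimizer_tries": self.n_optimizer_tries,
            "test_names": {str(k): v for k, v in self.test_names.items()},
        }
        if self.centering is not None:
            payload["centering"] = {
                "age_mean": self.centering.age_mean,
                "education_mean": self.centering.education_mean,
                "gender_coding": self.centering.gender_coding,
            }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MultilevelNormativeResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        p = payload["p"]
        sw = np.zeros((p, p))
        tril = np.tril_indices(p)
        sw[tril] = payload["sigma_within_tril"]
        sw = sw + np.tril(sw, -1).T
        centering = None
        if "centering" in payload:
            c = payload["centering"]
            from .data import coerce_coding_keys

            centering = CenteringInfo(
                age_mean=c["age_mean"], education_mean=c["education_mean"],
                gender_coding=coerce_coding_keys(c.get("gender_coding", {})),
            )
        return cls(
            gamma=np.asarray(payload["gamma"], float),
            sigma_within=sw,
            sigma_between=np.asarray(payload["sigma_between"], float),
            llf=payload["llf"],
            converged=payload["converged"],
            n_obs=payload["n_obs"],
            n_participants=payload["n_participants"],
            n_studies=payload["n_studies"],
            covariates=tuple(payload["covariates"]),
            estimate_between=payload["estimate_between"],
            covariate_ranges={
                k: tuple(v) for k, v in payload.get("covariate_ranges", {}).items()
            },
            n_optimizer_tries=payload.get("n_optimizer_tries", 1),
            centering=centering,
            test_names={int(k): v for k, v in payload.get("test_names", {}).items()},
        )
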