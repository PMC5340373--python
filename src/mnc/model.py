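"""Model class: FIML estimation of the three-level normative model."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import likelihood as lk
from .data import NormativeData, pair_coverage
from .errors import ConfigError
from .results import MultilevelNormativeResults

logger = logging.getLogger(__name__)


class MultilevelNormativeModel:
    """Three-level model for an aggregated normative database.

    Tests are nested in participants, participants in studies. Each test has
    its own fixed intercept and covariate slopes (slopes common to all
    studies); participant residuals have an unrestricted within-study
    covariance ``Sigma_w`` shared across studies; study intercept errors are
    independent across tests with per-test variances ``sigma_b2``
    (between-study covariances fixed at zero). Estimated by full-information
    maximum likelihood, so tests missing by design are handled under
    ignorable missingness.

    Parameters
    ----------
    data : NormativeData or pandas.DataFrame
        Long-format normative database (one row per test score). Covariates
        are expected to be centered (see :func:`mnc.center_covariates`).
    covariates : sequence of str
        Covariate columns entering every test's mean model. May be empty
        for the classical no-covariate comparison.
    estimate_between : bool
        If False, the between-study variances are fixed at zero both in
        fitting and in the combined covariance (the "neglecting between
        study variance" model).
    """

    def __init__(self, data, covariates=("age", "gender", "education"),
                 estimate_between: bool = True):
        if isinstance(data, pd.DataFrame):
            data = NormativeData(data)
        if not isinstance(data, NormativeData):
            raise ConfigError("data must be a NormativeData or DataFrame")
        self.data = data
        self.covariates = tuple(covariates)
        self.estimate_between = bool(estimate_between)
        self.p = data.p
        self.n_design = 1 + len(self.covariates)
        self.k_fe = self.p * self.n_design

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs):
        return cls(NormativeData(frame), **kwargs)

    def fit(self, start=None, maxiter: int = 1000, tol: float = 1e-8,
            gtol: float = 1e-5, restarts: int = 3,
            seed: int = 0) -> MultilevelNormativeResults:
        """Maximize the FIML likelihood.

        ``tol`` is the relative log-likelihood change declaring convergence;
        on failure the optimizer is restarted up to ``restarts`` times from
        jittered starting values and the best point found is returned with
        ``converged=False`` if none succeeded.
        """
        lk.check_estimability(pair_coverage(self.data).counts)
        frame = self.data.frame
        blocks = lk.prepare_blocks(
            lk.build_blocks(frame, self.covariates), self.p, self.n_design
        )
        transform = lk.ParamTransform(self.p, self.estimate_between)

        if start is None:
            _, sw0, sb0 = lk.starting_values(frame, self.p, self.covariates)
        else:
            sw0, sb0 = start
        theta0 = transform.pack(np.asarray(sw0, float), np.asarray(sb0, float))

        rng = np.random.default_rng(seed)
        best = None
        converged = False
        n_tries = 0
        theta_try = theta0
        for attempt in range(restarts + 1):
            n_tries += 1
            res = minimize(
                lk.profiled_nll_grad,
                theta_try,
                args=(blocks, transform, self.n_design),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": tol, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                converged = True
                best = res if res.fun <= best.fun else best
                break
            logger.warning(
                "FIML optimizer did not converge (attempt %d: %s); restarting",
                attempt + 1, res.message,
            )
            theta_try = theta0 + rng.normal(scale=0.05, size=theta0.size)

        nll, gamma, gls_info = lk.profiled_nll_grad(
            best.x, blocks, transform, self.n_design,
            want_grad=False, return_gamma=True, return_gls=True,
        )
        sigma_within, sigma_between, _ = transform.unpack(best.x)
        # treat boundary-small between variances as exactly zero
        sigma_between = np.where(sigma_between < 1e-6, 0.0, sigma_between)

        cov_ranges = {}
        if self.covariates:
            per_part = frame.groupby(["study", "ID"], sort=False)[
                list(self.covariates)
            ].first()
            cov_ranges = {
                c: (float(per_part[c].min()), float(per_part[c].max()))
                for c in self.covariates
            }

        return MultilevelNormativeResults(
            gamma=gamma,
            sigma_within=sigma_within,
            sigma_between=sigma_between,
            llf=-float(nll),
            converged=converged,
            n_obs=self.data.n_obs,
            n_participants=self.data.n_participants,
            n_studies=self.data.n_studies,
            covariates=self.covariates,
            estimate_between=self.estimate_between,
            gamma_cov=np.linalg.pinv(gls_info),
            covariate_ranges=cov_ranges,
            n_optimizer_tries=n_tries,
            centering=self.data.centering,
            test_names=self.data.test_names,
        )
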