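"""Synthetic normative databases and Monte Carlo calibration experiments.

The generator draws data from the same three-level model the package fits:
per-test intercepts and covariate effects, equicorrelated within-study
residuals, independent per-test study intercept errors, and block
missingness by design (each study administers a fixed-size subset of tests,
chosen so that every pair of tests co-occurs in at least one study).

Defaults reproduce the stated simulation world: 10 tests, 30 studies of 50
participants, intercept 20, effects (age -0.125/yr, gender 0.5, education
1.25), within-study variance 25 with correlation 0.4, between-study
variance 5 (ICC 5/30 ~ 0.167). A deviating patient has two total standard
deviations (2*sqrt(within+between) = 2*sqrt(30) ~ 10.95 by default)
subtracted from the first ``n_deviations`` tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.proportion import proportion_confint

from .comparison import PatientProfile
from .data import NormativeData
from .errors import ConfigError, NumericalError
from .model import MultilevelNormativeModel

logger = logging.getLogger(__name__)

METHODS = ("multivariate", "univariate_uncorrected", "univariate_bonferroni")


@dataclass
class SimulationConfig:
    """One Monte Carlo condition.

    ``n_per_study`` is either an int (balanced) or a ``(mean, sd)`` pair:
    study sizes are then drawn from Normal(mean, sd), rounded, floored at 5.
    ``patient_covariates`` is ``"random"`` (drawn like a norm participant)
    or ``"average"`` (all centered covariates zero).
    """

    p: int = 10
    n_studies: int = 30
    n_per_study: int | tuple = 50
    intercept: float = 20.0
    age_effect: float = -0.125
    gender_effect: float = 0.5
    education_effect: float = 1.25
    within_variance: float = 25.0
    within_correlation: float = 0.4
    between_variance: float = 5.0
    missing_fraction: float = 0.0
    n_deviations: int = 0
    deviation_sds: float = 2.0
    replications: int = 1000
    alpha_univariate: float = 0.05
    multivariate_threshold: float = 0.10
    estimate_between: bool = True
    patient_covariates: str = "random"
    rerun_nonconverged: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError("missing_fraction must be in [0, 1)")
        if not 0 <= self.n_deviations <= self.p:
            raise ConfigError("n_deviations must be in 0..p")
        if self.within_variance < 0 or self.between_variance < 0:
            raise ConfigError("variances must be >= 0")
        if not -1 < self.within_correlation < 1:
            raise ConfigError("within_correlation must be in (-1, 1)")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        if self.patient_covariates not in ("random", "average"):
            raise ConfigError("patient_covariates must be 'random' or 'average'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(
                f"unknown config key(s) {sorted(unknown)}; "
                f"allowed: {sorted(allowed)}"
            )
        if isinstance(d.get("n_per_study"), list):
            d = {**d, "n_per_study": tuple(d["n_per_study"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["n_per_study"], tuple):
            d["n_per_study"] = list(d["n_per_study"])
        return d

    # -- generative truth ----------------------------------------------------

    @property
    def sigma_within_true(self) -> np.ndarray:
        v, r = self.within_variance, self.within_correlation
        return v * ((1 - r) * np.eye(self.p) + r * np.ones((self.p, self.p)))

    @property
    def sigma_between_true(self) -> np.ndarray:
        return np.full(self.p, self.between_variance)

    @property
    def effects(self) -> np.ndarray:
        return np.array([self.age_effect, self.gender_effect, self.education_effect])

    @property
    def deviation_magnitude(self) -> float:
        """Shift applied to affected tests: ``deviation_sds`` total SDs."""
        return self.deviation_sds * math.sqrt(
            self.within_variance + self.between_variance
        )


def make_missing_design(p: int, K: int, fraction: float) -> np.ndarray:
    """K x p boolean design: which tests each study administers.

    Each study gets exactly ``b = round(p*(1-fraction))`` tests, assigned by
    a deterministic greedy pair-covering rule: each study is seeded with the
    least-covered test pair and grown by the test adding the most uncovered
    pairs. Guarantees every pair of tests co-occurs in at least one study
    (raises if infeasible) and makes the overall missing fraction exact.
    """
    if fraction == 0:
        return np.ones((K, p), dtype=bool)
    b = round(p * (1 - fraction))
    if abs(b - p * (1 - fraction)) > 1e-9:
        raise ConfigError(
            f"p*(1-fraction) = {p * (1 - fraction):.3f} is not a whole "
            "number of tests per study"
        )
    if b < 2:
        raise ConfigError("fewer than 2 tests per study: pairs cannot co-occur")
    need, have = math.comb(p, 2), K * math.comb(b, 2)
    if have < need:
        raise ConfigError(
            f"cannot cover all {need} test pairs: {K} studies x "
            f"C({b},2) = {have} pair slots (deficit {need - have})"
        )

    counts = np.zeros((p, p), dtype=int)
    design = np.zeros((K, p), dtype=bool)
    for k in range(K):
        # least-covered pair (lexicographic tie-break) seeds the block
        best_pair, best_cnt = None, None
        for i in range(p):
            for j in range(i + 1, p):
                if best_cnt is None or counts[i, j] < best_cnt:
                    best_pair, best_cnt = (i, j), counts[i, j]
        block = list(best_pair)
        while len(block) < b:
            best_t, best_key = None, None
            for t in range(p):
                if t in block:
                    continue
                new_uncovered = sum(counts[t, u] == 0 for u in block)
                total = sum(counts[t, u] for u in block)
                key = (-new_uncovered, total, t)
                if best_key is None or key < best_key:
                    best_t, best_key = t, key
            block.append(best_t)
        for a_i, i in enumerate(block):
            for j in block[a_i + 1:]:
                counts[i, j] += 1
                counts[j, i] += 1
        design[k, block] = True

    off = counts[np.triu_indices(p, 1)]
    if (off == 0).any():
        raise ConfigError(
            "greedy assignment failed to cover all test pairs; "
            "increase the number of studies or tests per study"
        )
    return design


def _chol_or_zero(M: np.ndarray) -> np.ndarray:
    """Cholesky factor, or zeros for the degenerate no-variance case."""
    if np.allclose(M, 0.0):
        return np.zeros_like(M)
    return np.linalg.cholesky(M)


def _draw_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    """Centered covariates: age ~ N(0, 15^2) years, gender +-1 equiprobable,
    education ~ N(0, 1.5^2) level units."""
    age = rng.normal(0.0, 15.0, n)
    gender = rng.choice([-1.0, 1.0], n)
    education = rng.normal(0.0, 1.5, n)
    return np.column_stack([age, gender, education])


def _study_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.n_per_study, (tuple, list)):
        mean, sd = config.n_per_study
        sizes = np.maximum(np.rint(rng.normal(mean, sd, config.n_studies)), 5)
        return sizes.astype(int)
    return np.full(config.n_studies, int(config.n_per_study))


def simulate_norm_data(config: SimulationConfig, rng=None) -> NormativeData:
    """Draw one normative database from the configured truth."""
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    p = config.p
    design = make_missing_design(p, config.n_studies, config.missing_fraction)
    sizes = _study_sizes(config, rng)
    chol_w = _chol_or_zero(config.sigma_within_true)
    sb_sd = math.sqrt(config.between_variance)

    frames = []
    for k in range(config.n_studies):
        n = sizes[k]
        S = np.flatnonzero(design[k])
        nu = rng.normal(0.0, sb_sd, p) if sb_sd > 0 else np.zeros(p)
        cov = _draw_covariates(rng, n)
        eps = rng.standard_normal((n, p)) @ chol_w.T
        scores = (
            config.intercept
            + cov @ config.effects[:, None] * np.ones(p)
            + nu
            + eps
        )
        frames.append(
            pd.DataFrame(
                {
                    "study": k + 1,
                    "ID": np.repeat(np.arange(1, n + 1), S.size),
                    "age": np.repeat(cov[:, 0], S.size),
                    "gender": np.repeat(cov[:, 1], S.size),
                    "education": np.repeat(cov[:, 2], S.size),
                    "test": np.tile(S + 1, n),
                    "score": scores[:, S].ravel(),
                }
            )
        )
    return NormativeData(pd.concat(frames, ignore_index=True))


def simulate_patient(config: SimulationConfig, n_deviations: int | None = None,
                     rng=None) -> PatientProfile:
    """Draw a patient from the null model, then subtract the deviation
    magnitude (2 total SDs by default) from the first ``n_deviations`` tests.

    The patient comes from a fresh (unobserved) study, so the residual
    covariance is the combined Sigma_w + diag(sigma_b2).
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    if n_deviations is None:
        n_deviations = config.n_deviations
    if not 0 <= n_deviations <= config.p:
        raise ConfigError("n_deviations must be in 0..p")
    if config.patient_covariates == "average":
        cov = np.zeros(3)
    else:
        cov = _draw_covariates(rng, 1)[0]
    total_cov = config.sigma_within_true + np.diag(config.sigma_between_true)
    resid = _chol_or_zero(total_cov) @ rng.standard_normal(config.p)
    scores = config.intercept + float(cov @ config.effects) + resid
    scores[:n_deviations] -= config.deviation_magnitude
    return PatientProfile(
        covariates={"age": cov[0], "gender": cov[1], "education": cov[2]},
        scores=scores,
    )


@dataclass
class SimulationResult:
    """Aggregated Monte Carlo rates for one condition."""

    config: SimulationConfig
    n_replications: int
    n_used: int
    n_nonconverged: int
    rates: dict          # method -> rejection fraction
    ci: dict             # method -> (lo, hi) binomial 95% CI
    unreliable: bool = False

    @property
    def kind(self) -> str:
        return "false_positive_rate" if self.config.n_deviations == 0 else "sensitivity"

    def to_rows(self, condition: str = "") -> list[dict]:
        return [
            {
                "condition": condition,
                "method": m,
                "kind": self.kind,
                "rate": self.rates[m],
                "ci_low": self.ci[m][0],
                "ci_high": self.ci[m][1],
                "replications": self.n_used,
                "nonconverged": self.n_nonconverged,
                "unreliable": self.unreliable,
            }
            for m in METHODS
        ]


def _one_replicate(config: SimulationConfig, rep: int, attempt: int = 0):
    """Generate a database + patient, fit, compare. Returns flag triple or
    None if the fit did not converge."""
    spawn = (rep,) if attempt == 0 else (rep, attempt)
    ss = np.random.SeedSequence(config.seed, spawn_key=spawn)
    rng = np.random.default_rng(ss)
    data = simulate_norm_data(config, rng)
    patient = simulate_patient(config, rng=rng)
    model = MultilevelNormativeModel(
        data, estimate_between=config.estimate_between
    )
    try:
        res = model.fit(seed=int(ss.generate_state(1)[0] % (2**31)))
    except (np.linalg.LinAlgError, NumericalError):
        return None
    if not res.converged:
        return None
    import warnings

    with warnings.catch_warnings():
        # a randomly drawn patient can fall just outside the sample's
        # covariate range; extrapolation warnings are expected here
        warnings.simplefilter("ignore", UserWarning)
        cmp = res.compare(
            patient,
            alpha=config.alpha_univariate,
            one_sided_threshold=config.multivariate_threshold,
        )
    return (
        cmp.decision_one_sided,
        cmp.any_univariate,
        cmp.any_univariate_bonferroni,
    )


def run_condition(config: SimulationConfig, n_jobs: int = 1,
                  progress: bool = False) -> SimulationResult:
    """Run one Monte Carlo condition.

    Replicate seeds are derived from the master seed by counter, so results
    are identical for any ``n_jobs`` and bit-identical across runs with the
    same config.
    """
    reps = range(config.replications)
    if n_jobs == 1:
        raw = []
        for r in reps:
            raw.append(_one_replicate(config, r))
            if progress and (r + 1) % 50 == 0:
                logger.info("replicate %d/%d", r + 1, config.replications)
    else:
        raw = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(config, r) for r in reps
        )

    if config.rerun_nonconverged:
        for r, out in enumerate(raw):
            attempt = 1
            while out is None and attempt <= 5:
                out = _one_replicate(config, r, attempt=attempt)
                attempt += 1
            raw[r] = out

    flags = [out for out in raw if out is not None]
    n_bad = config.replications - len(flags)
    n_used = len(flags)
    arr = np.array(flags, dtype=bool).reshape(n_used, 3)
    rates, ci = {}, {}
    for i, m in enumerate(METHODS):
        count = int(arr[:, i].sum()) if n_used else 0
        rates[m] = count / n_used if n_used else float("nan")
        ci[m] = (
            tuple(proportion_confint(count, n_used, alpha=0.05, method="wilson"))
            if n_used
            else (float("nan"), float("nan"))
        )
    unreliable = n_bad > 0.10 * config.replications
    if unreliable:
        logger.warning(
            "condition unreliable: %d/%d replicates failed to converge",
            n_bad, config.replications,
        )
    return SimulationResult(
        config=config,
        n_replications=config.replications,
        n_used=n_used,
        n_nonconverged=n_bad,
        rates=rates,
        ci=ci,
        unreliable=unreliable,
    )


def paper_suite(replications: int = 1000, seed: int = 0,
                ) -> list[tuple[str, SimulationConfig]]:
    """All reported simulation conditions: study 1 (between variance
    estimated vs neglected), study 2 (0/40/70% missing x 0/1/2/5/9
    deviations), and the follow-ups (ICC 0.4, unbalanced study sizes,
    20 tests at 70% missing, 5 tests at 60%, 20 studies at 40%)."""
    base = SimulationConfig(replications=replications, seed=seed)
    suite: list[tuple[str, SimulationConfig]] = [
        ("sim1_between_estimated", base),
        ("sim1_between_neglected", replace(base, estimate_between=False)),
    ]
    for miss in (0.0, 0.4, 0.7):
        for dev in (0, 1, 2, 5, 9):
            suite.append(
                (
                    f"sim2_miss{int(miss * 100):02d}_dev{dev}",
                    replace(base, missing_fraction=miss, n_deviations=dev),
                )
            )
    for miss in (0.0, 0.4, 0.7):
        suite.append(
            (
                f"icc04_miss{int(miss * 100):02d}",
                replace(base, between_variance=17.0, missing_fraction=miss),
            )
        )
    suite += [
        ("unbalanced_n50sd10_miss70",
         replace(base, n_per_study=(50, 10), missing_fraction=0.7)),
        ("unbalanced_n25sd5_miss70",
         replace(base, n_per_study=(25, 5), missing_fraction=0.7)),
        ("tests20_miss70",
         replace(base, p=20, missing_fraction=0.7,
                 replications=min(replications, 100))),
        ("tests5_miss60", replace(base, p=5, missing_fraction=0.6)),
        ("studies20_miss40",
         replace(base, n_studies=20, missing_fraction=0.4)),
    ]
    return suite
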