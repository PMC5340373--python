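import numpy as np
import pandas as pd
import pytest

# the printed toy example: 2 studies, 5 participants, 3 tests, 10 score rows
TABLE2_ROWS = [
    (1, 1, -2.21, -1, 3.68, 1, 0.08),
    (1, 1, -2.21, -1, 3.68, 2, 1.59),
    (1, 2, 22.79, 1, -0.32, 1, 0.72),
    (1, 2, 22.79, 1, -0.32, 2, 2.06),
    (2, 1, -25.21, 1, 0.68, 2, 0.19),
    (2, 1, -25.21, 1, 0.68, 3, 1.26),
    (2, 2, -11.21, 1, 1.68, 2, 0.04),
    (2, 2, -11.21, 1, 1.68, 3, -0.29),
    (2, 3, 3.79, -1, 0.68, 2, -0.65),
    (2, 3, 3.79, -1, 0.68, 3, -0.51),
]


@pytest.fixture
def table2_frame() -> pd.DataFrame:
    return pd.DataFrame(
        TABLE2_ROWS,
        columns=["study", "ID", "age", "gender", "education", "test", "score"],
    )


def random_long_frame(rng: np.random.Generator, p=3, n_studies=3, n_max=4,
                      covariates=True, ragged=False) -> pd.DataFrame:
    """Small random long-format dataset with participant-constant covariates.

    ``ragged=True`` lets participants within a study observe different test
    subsets (participant-level missingness).
    """
    rows = []
    for k in range(n_studies):
        study_tests = sorted(
            rng.choice(p, size=rng.integers(2, p + 1), replace=False) + 1
        )
        for j in range(rng.integers(1, n_max + 1)):
            if covariates:
                age, gender, edu = rng.normal(0, 10), rng.choice([-1.0, 1.0]), rng.normal(0, 1.5)
            else:
                age = gender = edu = 0.0
            tests = study_tests
            if ragged and len(study_tests) > 1 and rng.random() < 0.5:
                keep = rng.choice(
                    len(study_tests), size=rng.integers(1, len(study_tests) + 1),
                    replace=False,
                )
                tests = [study_tests[i] for i in sorted(keep)]
            for t in tests:
                rows.append((k + 1, j + 1, age, gender, edu, t, rng.normal()))
    df = pd.DataFrame(
        rows, columns=["study", "ID", "age", "gender", "education", "test", "score"]
    )
    # keep test indices contiguous 1..p' after random subsetting
    remap = {t: i + 1 for i, t in enumerate(sorted(df["test"].unique()))}
    df["test"] = df["test"].map(remap)
    return df


def dense_mvn_study_loglik(gamma, sigma_within, sigma_between, frame) -> float:
    """Independent brute-force oracle: assemble the full covariance of one
    study's stacked score vector row by row and evaluate the dense MVN
    log-density."""
    from scipy.stats import multivariate_normal

    frame = frame.sort_values(["ID", "test"], kind="mergesort")
    gamma = np.asarray(gamma, float)
    mu, meta = [], []
    for _, r in frame.iterrows():
        u = np.array([1.0, r["age"], r["gender"], r["education"]])[: gamma.shape[1]]
        t = int(r["test"]) - 1
        mu.append(float(gamma[t] @ u))
        meta.append((r["ID"], t))
    m = len(mu)
    cov = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            ja, ta = meta[a]
            jb, tb = meta[b]
            if ja == jb:
                cov[a, b] += sigma_within[ta, tb]
            if ta == tb:
                cov[a, b] += sigma_between[ta]
    return float(
        multivariate_normal(mean=np.array(mu), cov=cov).logpdf(
            frame["score"].to_numpy(float)
        )
    )
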