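"""Long-format normative database: container, I/O, covariate coding, coverage.

An aggregated normative database pools healthy-control data from many studies.
Each row is a single test score: (study, participant, covariates, test, score).
Tests are indexed 1..p; a study administers only a subset of tests, so scores
absent by design are simply absent rows (the long format carries no explicit
missing values).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

logger = logging.getLogger(__name__)

#: canonical column order of the long format
COLUMNS = ["study", "ID", "age", "gender", "education", "test", "score"]

COVARIATES = ["age", "gender", "education"]


def coerce_coding_keys(coding: dict) -> dict:
    """JSON round-trips dict keys as strings; restore numeric gender levels."""
    out = {}
    for k, v in coding.items():
        if isinstance(k, str):
            try:
                k = int(k)
            except ValueError:
                try:
                    k = float(k)
                except ValueError:
                    pass
        out[k] = v
    return out


@dataclass(frozen=True)
class CenteringInfo:
    """How covariates were centered/coded, so a patient can be put on the
    same scale as the norm group (never recentered on their own)."""

    age_mean: float = 0.0
    education_mean: float = 0.0
    gender_coding: dict = field(default_factory=dict)

    def apply(self, age: float, gender, education: float) -> tuple[float, float, float]:
        """Center raw patient covariates with the norm group's constants."""
        g = self.gender_coding.get(gender, gender)
        if g not in (-1, 1):
            raise IntegrityError(f"gender {gender!r} not codable with {self.gender_coding}")
        return age - self.age_mean, float(g), education - self.education_mean

    def unapply(self, age: float, gender: float, education: float):
        inverse = {v: k for k, v in self.gender_coding.items()}
        return age + self.age_mean, inverse.get(gender, gender), education + self.education_mean


@dataclass(frozen=True)
class PairCoverage:
    """Number of studies in which each pair of tests was jointly administered.

    The unrestricted within-study covariance between tests i and j is only
    estimable if some study administered both, so every off-diagonal count
    must be at least 1.
    """

    counts: np.ndarray  # p x p, symmetric; diagonal = per-test study counts

    @property
    def uncovered_pairs(self) -> list[tuple[int, int]]:
        """1-based (i, j) pairs, i < j, never administered together."""
        p = self.counts.shape[0]
        return [
            (i + 1, j + 1)
            for i in range(p)
            for j in range(i + 1, p)
            if self.counts[i, j] == 0
        ]

    @property
    def complete(self) -> bool:
        return not self.uncovered_pairs


class NormativeData:
    """Validated long-format normative dataset.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``study, ID, age, gender, education, test, score``. ``test``
        must be integers 1..p with every index present; ``ID`` is unique
        within a study only.
    test_names : dict, optional
        Mapping from test index to a human-readable name.
    centering : CenteringInfo, optional
        Set by :func:`center_covariates`; ``None`` means raw covariates.
    """

    def __init__(self, frame: pd.DataFrame, test_names: dict | None = None,
                 centering: CenteringInfo | None = None):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, COLUMNS].copy()
        if len(frame) == 0:
            raise FormatError("dataset is empty")

        try:
            frame["test"] = frame["test"].astype(int)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-integer test index: {exc}") from exc
        scores = pd.to_numeric(frame["score"], errors="coerce")
        bad = scores.index[~np.isfinite(scores)]
        if len(bad):
            raise ParseError(
                f"non-numeric or non-finite score at row {bad[0]}", row=int(bad[0])
            )
        frame["score"] = scores.astype(float)

        tests = np.sort(frame["test"].unique())
        if tests[0] != 1 or not np.array_equal(tests, np.arange(1, len(tests) + 1)):
            raise IntegrityError(
                f"test indices must be contiguous 1..p, got {tests.tolist()}"
            )

        dup = frame.duplicated(subset=["study", "ID", "test"])
        if dup.any():
            row = frame.loc[dup, ["study", "ID", "test"]].iloc[0]
            raise IntegrityError(
                "duplicate (study, participant, test) triple: "
                f"({row['study']}, {row['ID']}, {row['test']})"
            )

        self.frame = frame.reset_index(drop=True)
        self.test_names = dict(test_names or {})
        self.centering = centering

    # -- derived bookkeeping -------------------------------------------------

    @property
    def p(self) -> int:
        """Number of distinct tests."""
        return int(self.frame["test"].max())

    @property
    def n_studies(self) -> int:
        return self.frame["study"].nunique()

    @property
    def n_participants(self) -> int:
        """Total distinct participants (IDs are unique within study only)."""
        return len(self.frame.groupby(["study", "ID"], sort=False))

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def administered(self, study) -> set[int]:
        """Set of test indices that appear in the given study."""
        return set(self.frame.loc[self.frame["study"] == study, "test"].unique())

    def __repr__(self):
        return (
            f"<NormativeData p={self.p} studies={self.n_studies} "
            f"participants={self.n_participants} observations={self.n_obs}>"
        )


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc


def load_long(path, sep: str | None = None, columns: dict | None = None) -> NormativeData:
    """Read a long-format normative table (CSV, or TSV by extension).

    Parameters
    ----------
    columns : dict, optional
        Maps canonical names (``study``, ``ID``, ...) to the header names
        actually used in the file.
    """
    frame = _read_table(path, sep=sep)
    if columns:
        frame = frame.rename(columns={v: k for k, v in columns.items()})
    sidecar = Path(path).with_suffix(".json")
    test_names, centering = {}, None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        test_names = {int(k): v for k, v in meta.get("test_names", {}).items()}
        if "centering" in meta:
            c = meta["centering"]
            centering = CenteringInfo(
                age_mean=c["age_mean"],
                education_mean=c["education_mean"],
                gender_coding=coerce_coding_keys(c.get("gender_coding", {})),
            )
    data = NormativeData(frame, test_names=test_names, centering=centering)
    logger.info(
        "loaded %s: p=%d, K=%d, N=%d, N_obs=%d",
        path, data.p, data.n_studies, data.n_participants, data.n_obs,
    )
    return data


def canonical_sort(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.sort_values(["study", "ID", "test"], kind="mergesort").reset_index(drop=True)


def write_long(data: NormativeData, path, sep: str | None = None) -> None:
    """Write the dataset in canonical order; centering/test names go to a
    JSON sidecar next to the table."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    canonical_sort(data.frame).to_csv(path, sep=sep, index=False)
    meta = {}
    if data.test_names:
        meta["test_names"] = {str(k): v for k, v in data.test_names.items()}
    if data.centering is not None:
        meta["centering"] = {
            "age_mean": data.centering.age_mean,
            "education_mean": data.centering.education_mean,
            "gender_coding": data.centering.gender_coding,
        }
    if meta:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def center_covariates(
    data: NormativeData, gender_map: dict | None = None
) -> tuple[NormativeData, CenteringInfo]:
    """Center age/education on their participant-level means; contrast-code
    gender to {-1, +1}.

    Means are taken over distinct participants, not over score rows, so
    participants who completed more tests do not dominate. Rows with a
    missing covariate are dropped listwise (count logged). Idempotent:
    already-centered data comes back unchanged with zero means.
    """
    frame = data.frame
    has_cov = frame[COVARIATES].notna().all(axis=1)
    n_dropped = int((~has_cov).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing covariates (listwise)", n_dropped)
        frame = frame.loc[has_cov]

    levels = pd.unique(frame["gender"])
    if gender_map is None:
        if set(levels) <= {-1, 1, -1.0, 1.0}:
            gender_map = {lv: int(lv) for lv in levels}
        elif len(levels) == 2:
            lo, hi = sorted(levels, key=str)
            gender_map = {lo: -1, hi: 1}
        else:
            raise IntegrityError(
                f"gender has {len(levels)} levels ({levels.tolist()}); "
                "cannot contrast-code without an explicit mapping"
            )
    coded = frame["gender"].map(gender_map)
    if not set(pd.unique(coded)) <= {-1, 1}:
        raise IntegrityError(f"gender mapping {gender_map} does not yield {{-1,+1}}")

    # one row per distinct participant for the means
    per_part = frame.groupby(["study", "ID"], sort=False)[["age", "education"]].first()
    age_mean = float(per_part["age"].mean())
    edu_mean = float(per_part["education"].mean())

    out = frame.copy()
    out["age"] = frame["age"] - age_mean
    out["education"] = frame["education"] - edu_mean
    out["gender"] = coded.astype(float)

    info = CenteringInfo(
        age_mean=age_mean, education_mean=edu_mean,
        gender_coding={
            (k.item() if hasattr(k, "item") else k): int(v)
            for k, v in gender_map.items()
        },
    )
    return NormativeData(out, test_names=data.test_names, centering=info), info


def pair_coverage(data: NormativeData) -> PairCoverage:
    """Count, for each pair of tests, the studies administering both."""
    p = data.p
    counts = np.zeros((p, p), dtype=int)
    for study, block in data.frame.groupby("study", sort=False):
        idx = np.array(sorted(block["test"].unique())) - 1
        counts[np.ix_(idx, idx)] += 1
    cov = PairCoverage(counts=counts)
    if not cov.complete:
        logger.warning(
            "pair(s) never administered together (covariance inestimable): %s",
            cov.uncovered_pairs,
        )
    return cov
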