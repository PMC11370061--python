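"""Multi-source cohort assembly and linear-model batch correction.

Tables from different originating studies are concatenated, de-duplicated
and filtered (age window, at most one missing MABC2 subscale per subject).
Nuisance variance is then removed score-by-score: an ordinary least squares
model with dummy-coded originating study ID, test module, sex and diagnosis
is fit to each score, and the fitted contributions of study, module and sex
are subtracted — diagnosis-related variance is deliberately retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("md", "ac", "bl", "total")
SUBSCALE_COLUMNS = ("md", "ac", "bl")
NUISANCE_FACTORS = ("study_id", "module", "sex")
REQUIRED_COLUMNS = ("subject_id", "diagnosis", "study_id", "module", "sex", "age")


class EmptyCohortError(Exception):
    """All rows were excluded by the merge/filter step."""


class ConfoundedDesignError(Exception):
    """Batch factors are aliased and cannot be separated."""


@dataclass
class MergeResult:
    table: pd.DataFrame
    exclusions: pd.DataFrame  # columns: subject_id, reason


def merge_and_filter(
    tables: list[pd.DataFrame],
    age_range: tuple[float, float] = (3.0, 16.0),
) -> MergeResult:
    """Concatenate, de-duplicate and filter subject rows.

    Exclusion rules (each exclusion logged with its reason):
    duplicate ``subject_id`` (first occurrence kept); age outside
    ``age_range``; two or more missing subscales among (md, ac, bl).
    """
    for t in tables:
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"table lacks required columns: {missing}")
    df = pd.concat(tables, ignore_index=True)
    exclusions = []

    dup = df.duplicated(subset="subject_id", keep="first")
    for sid in df.loc[dup, "subject_id"]:
        exclusions.append({"subject_id": sid, "reason": "duplicate subject_id"})
    df = df[~dup]

    lo, hi = age_range
    bad_age = (df["age"] < lo) | (df["age"] > hi)
    for sid, age in df.loc[bad_age, ["subject_id", "age"]].itertuples(index=False):
        exclusions.append({"subject_id": sid, "reason": f"age {age:g} outside [{lo:g}, {hi:g}]"})
    df = df[~bad_age]

    n_missing = df[list(SUBSCALE_COLUMNS)].isna().sum(axis=1)
    bad_scores = n_missing >= 2
    for sid, k in df.loc[bad_scores, "subject_id"].to_frame().assign(k=n_missing[bad_scores]).itertuples(index=False):
        exclusions.append({"subject_id": sid, "reason": f"{k} missing subscales"})
    df = df[~bad_scores].reset_index(drop=True)

    for e in exclusions:
        logger.info("excluded %s: %s", e["subject_id"], e["reason"])
    if df.empty:
        raise EmptyCohortError("no subjects remain after filtering")
    return MergeResult(df, pd.DataFrame(exclusions, columns=["subject_id", "reason"]))


@dataclass
class CorrectedProfileTable:
    """Batch-corrected scores plus the audit trail of fitted coefficients."""

    table: pd.DataFrame
    correction_betas: dict = field(default_factory=dict)  # score -> {column: beta}


def _dummy_design(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies, reference = most frequent level."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        levels = df[f].value_counts().index.tolist()  # most frequent first
        for lev in levels[1:]:
            cols.append((df[f] == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


def batch_correct(
    table: pd.DataFrame,
    score_columns: tuple = SCORE_COLUMNS,
) -> CorrectedProfileTable:
    """Project study/module/sex variance out of each score.

    One OLS per score on the full cohort (diagnosis included as a covariate
    so its variance is estimated, not absorbed by the batch terms); the
    returned scores are ``y - X_batch @ beta_batch``. Rows missing a score
    are excluded from that score's fit and stay missing afterwards.
    """
    df = table.copy()
    factors = []
    for f in (*NUISANCE_FACTORS, "diagnosis"):
        if df[f].nunique() >= 2:
            factors.append(f)
        else:
            logger.warning("factor %r has a single level; dropped from the batch model", f)

    X, names = _dummy_design(df, factors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR with pivoting
        _, r, piv = __import__("scipy").linalg.qr(X, pivoting=True)
        dead = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise ConfoundedDesignError(f"aliased design columns: {dead}")

    nuis_idx = [i for i, nm in enumerate(names) if nm.split("[")[0] in NUISANCE_FACTORS]
    betas: dict[str, dict[str, float]] = {}
    for score in score_columns:
        y = df[score].to_numpy(float)
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        betas[score] = {names[i]: float(beta[i]) for i in range(len(names))}
        correction = X[:, nuis_idx] @ beta[nuis_idx]
        df.loc[:, score] = np.where(ok, y - correction, np.nan)
    return CorrectedProfileTable(df, betas)
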