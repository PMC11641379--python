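"""Region-wise group contrast of regional morphometric similarity.

For every region, regional MS is regressed on an intercept, the biomarker
group indicator (POS_POS = 1, so positive t means higher MS in the
amyloid/tau-positive group) and the cohort covariates (age, gender coded
M=1/F=0, education years, MMSE).  The group coefficient's t-statistic and
two-sided p-value are reported per region, with Benjamini-Hochberg FDR
adjustment across the 34 regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .cohort import GENDER_CODES, Group, SubjectRecord, analysed_subjects
from .stats import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "gender", "education", "mmse")


@dataclass
class RegionalContrast:
    """Per-region group-contrast statistics."""

    roi_labels: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_subjects: int
    model_df: int

    def to_frame(self) -> pd.DataFrame:
        direction = np.where(self.t >= 0, "increase", "decrease")
        return pd.DataFrame(
            {
                "roi": self.roi_labels,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "direction": direction,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_contrast(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def design_matrix(
    subjects: Sequence[SubjectRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Regression design: intercept, group indicator, then covariates."""
    rows = {}
    for rec in subjects:
        if rec.group is Group.EXCLUDED:
            raise ValueError(
                f"subject {rec.subject_id} is EXCLUDED; filter before modelling"
            )
        row = {"const": 1.0, "group": 1.0 if rec.group is Group.POS_POS else 0.0}
        for cov in covariates:
            if cov == "gender":
                row[cov] = GENDER_CODES[rec.gender]
            else:
                row[cov] = float(getattr(rec, cov))
        rows[rec.subject_id] = row
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index.name = "subject_id"
    return X


def fit_roi_model(
    ms: np.ndarray,
    subjects: Sequence[SubjectRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[float, float, float]:
    """OLS of one region's MS on the group indicator plus covariates.

    Returns ``(beta_group, t, p)`` with a two-sided p-value on n - k
    degrees of freedom.
    """
    X = design_matrix(subjects, covariates)
    y = np.asarray(ms, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("MS vector length does not match number of subjects")
    groups = X["group"].to_numpy()
    if groups.min() == groups.max():
        raise ValueError("both groups must be represented")
    if y.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} subjects for {X.shape[1]} predictors"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if np.ptp(y) == 0:
        # no variation at all: zero effect by definition, not 0/0 noise
        return 0.0, 0.0, 1.0
    res = sm.OLS(y, X).fit()
    return float(res.params["group"]), float(res.tvalues["group"]), float(
        res.pvalues["group"]
    )


def contrast_map(
    ms_table: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> RegionalContrast:
    """Fit the per-region model for every region and BH-adjust the p-values.

    ``ms_table`` is subjects x regions; EXCLUDED subjects are dropped with a
    logged count, and the remaining subject ids must match the table exactly.
    """
    kept = analysed_subjects(list(subjects))
    ids = [r.subject_id for r in kept]
    if set(ids) != set(ms_table.index):
        raise ValueError(
            "subject ids in the MS table do not match the analysed cohort"
        )
    ms = ms_table.loc[ids]
    X = design_matrix(kept, covariates)

    t = np.empty(ms.shape[1])
    p = np.empty(ms.shape[1])
    for j, roi in enumerate(ms.columns):
        _, t[j], p[j] = fit_roi_model(ms[roi].to_numpy(), kept, covariates)
    q = bh_fdr(p)
    return RegionalContrast(
        roi_labels=tuple(str(c) for c in ms.columns),
        t=t,
        p=p,
        q=q,
        n_subjects=len(kept),
        model_df=len(kept) - X.shape[1],
    )


class GroupContrast(BaseEstimator):
    """Estimator wrapper around :func:`contrast_map`.

    Parameters
    ----------
    covariates : sequence of str
        Covariate names taken from the subject records ('gender' is encoded
        M=1, F=0).

    Attributes
    ----------
    result_ : RegionalContrast
    t_, p_, q_ : ndarray, per-region statistics.
    """

    def __init__(self, covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y: Sequence[SubjectRecord]):
        self.result_ = contrast_map(X, y, self.covariates)
        self.roi_labels_ = self.result_.roi_labels
        self.t_ = self.result_.t
        self.p_ = self.result_.p
        self.q_ = self.result_.q
        return self
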