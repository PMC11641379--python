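"""Morphometric similarity networks (MSN).

For each subject, the 13 regional features are z-scored across the 34
regions, every pair of regions is correlated (Pearson) across features, and
the per-region morphometric similarity (MS) statistic is the mean absolute
off-diagonal correlation of that region with all others:

    MS_i = (1 / (N - 1)) * sum_{j != i} |r_ij|

MS_i lies in [0, 1] and summarises how similar a region's multi-feature
profile is to the rest of the cortex.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .rois import DESIKAN_KILLIANY_LH

__all__ = [
    "validate_feature_table",
    "zscore_features",
    "build_msn",
    "regional_ms",
    "MorphometricSimilarity",
    "read_feature_tables",
    "write_feature_tables",
    "write_regional_ms",
    "read_regional_ms",
]


def validate_feature_table(
    table: pd.DataFrame, roi_labels: tuple[str, ...] = DESIKAN_KILLIANY_LH
) -> pd.DataFrame:
    """Check and canonically order a regions x features table.

    Every canonical region label must be present exactly once; unknown labels
    are a hard error.  Returns the table reindexed to the canonical order.
    """
    labels = list(table.index)
    unknown = sorted(set(labels) - set(roi_labels))
    if unknown:
        raise ValueError(f"unknown ROI label(s): {unknown}")
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicated ROI label(s): {dup}")
    missing = sorted(set(roi_labels) - set(labels))
    if missing:
        raise ValueError(f"missing ROI label(s): {missing}")
    out = table.reindex(list(roi_labels))
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in feature column(s): {bad}")
    return out


def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column across regions (sample SD, ddof=1)."""
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(~(sd > 0))
    if zero.size:
        names = [str(table.columns[i]) for i in zero]
        raise ValueError(f"zero-variance feature column(s): {names}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def build_msn(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson-correlate every pair of region rows across features.

    Expects a (normalised) regions x features table with >= 2 features and
    returns the symmetric regions x regions similarity matrix with a unit
    diagonal.
    """
    values = table.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features to correlate regions")
    row_sd = values.std(axis=1, ddof=1)
    flat = np.flatnonzero(~(row_sd > 0))
    if flat.size:
        names = [str(table.index[i]) for i in flat]
        raise ValueError(f"ROI row(s) with zero variance across features: {names}")
    mat = np.corrcoef(values)
    # guard tiny floating excursions outside [-1, 1]
    np.clip(mat, -1.0, 1.0, out=mat)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=table.index, columns=table.index)


def regional_ms(network: pd.DataFrame) -> pd.Series:
    """Per-region mean absolute off-diagonal correlation."""
    mat = np.abs(network.to_numpy(dtype=float))
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("network must be square")
    off_sum = mat.sum(axis=1) - np.abs(np.diag(network.to_numpy(dtype=float)))
    return pd.Series(off_sum / (n - 1), index=network.index, name="regional_ms")


class MorphometricSimilarity(TransformerMixin, BaseEstimator):
    """Transformer mapping per-subject feature tables to regional MS vectors.

    Parameters
    ----------
    roi_labels : tuple of str
        Canonical region ordering enforced on every input table.

    Notes
    -----
    ``transform`` accepts a mapping ``subject_id -> (regions x features)
    DataFrame`` and returns a subjects x regions DataFrame of regional MS
    values.  The transformer is stateless; ``fit`` only validates.
    """

    def __init__(self, roi_labels: tuple[str, ...] = DESIKAN_KILLIANY_LH):
        self.roi_labels = roi_labels

    def fit(self, X: Mapping[str, pd.DataFrame], y=None):
        for subject_id, table in X.items():
            validate_feature_table(table, self.roi_labels)
        self.n_features_in_ = next(iter(X.values())).shape[1] if X else 0
        return self

    def transform(self, X: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        rows = {}
        for subject_id, table in X.items():
            table = validate_feature_table(table, self.roi_labels)
            net = build_msn(zscore_features(table))
            rows[subject_id] = regional_ms(net)
        out = pd.DataFrame(rows).T
        out = out.reindex(columns=list(self.roi_labels))
        out.index.name = "subject_id"
        return out

    def networks(self, X: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
        """Full per-subject similarity matrices (regions x regions)."""
        return {
            sid: build_msn(zscore_features(validate_feature_table(t, self.roi_labels)))
            for sid, t in X.items()
        }


def read_feature_tables(path) -> dict[str, pd.DataFrame]:
    """Read a long-form features TSV (subject_id, roi, feature, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "roi", "feature", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"features table missing column(s): {sorted(missing)}")
    tables: dict[str, pd.DataFrame] = {}
    for subject_id, block in df.groupby("subject_id", sort=True):
        wide = block.pivot(index="roi", columns="feature", values="value")
        tables[str(subject_id)] = validate_feature_table(wide)
    return tables


def write_feature_tables(tables: Mapping[str, pd.DataFrame], path) -> None:
    """Write per-subject feature tables to the long TSV format."""
    frames = []
    for subject_id in sorted(tables):
        long = tables[subject_id].stack().rename("value").reset_index()
        long.columns = ["roi", "feature", "value"]
        long.insert(0, "subject_id", subject_id)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_regional_ms(ms_table: pd.DataFrame, path) -> None:
    ms_table.to_csv(path, sep="\t", index=True, float_format="%.12g")


def read_regional_ms(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")
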