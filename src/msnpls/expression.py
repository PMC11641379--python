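"""Donor microarray samples to a region x gene expression matrix.

This stage mirrors the standard post-mortem microarray workflow for mapping
donor expression onto a cortical parcellation: probes are filtered on the
fraction of samples where they exceed background, one probe per gene is kept
by the differential-stability criterion (mean pairwise inter-donor Spearman
correlation of the regional profile), samples are assigned to the nearest
region centroid within a radius (with a nearest-sample fallback for regions
a donor did not sample), each donor's regional values are normalised with a
scaled robust sigmoid and min-max rescaled to [0, 1], and donors are
averaged into the final 34 x G matrix.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .rois import DESIKAN_KILLIANY_LH

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = (
    "donor_id",
    "sample_id",
    "x",
    "y",
    "z",
    "probe_id",
    "intensity",
    "above_background",
)


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing column(s): {sorted(missing)}")
    if len(samples) == 0:
        raise ValueError("empty sample table")
    return samples


def filter_probes_intensity(
    samples: pd.DataFrame, min_fraction: float = 0.5
) -> pd.Index:
    """Probes above background in at least ``min_fraction`` of all samples.

    The fraction is pooled over donors; the boundary is inclusive.
    """
    _check_samples(samples)
    frac = samples.groupby("probe_id")["above_background"].mean()
    kept = frac.index[frac >= min_fraction]
    logger.info("intensity filter retained %d / %d probes", len(kept), len(frac))
    return kept


def assign_samples_to_regions(
    samples: pd.DataFrame,
    centroids: pd.DataFrame,
    radius: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map tissue samples to regions and average intensities per donor/region.

    Each sample goes to the nearest centroid if within ``radius`` mm
    (Euclidean).  After that pass, any region with no sample for a donor
    receives that donor's single globally nearest sample as a fallback, so
    every donor covers every region.

    Returns
    -------
    assignment : DataFrame (donor_id, sample_id, roi, distance, fallback)
        One row per (sample, region) pairing actually used.
    region_means : DataFrame (donor_id, roi, probe_id, intensity)
        Mean intensity over the samples assigned to each donor/region.
    """
    _check_samples(samples)
    cent = centroids.set_index("roi") if "roi" in centroids.columns else centroids
    cent = cent.loc[:, ["x", "y", "z"]]
    unique = samples[["donor_id", "sample_id", "x", "y", "z"]].drop_duplicates(
        subset=["donor_id", "sample_id"]
    )
    dists = cdist(
        unique[["x", "y", "z"]].to_numpy(dtype=float), cent.to_numpy(dtype=float)
    )
    nearest = np.argmin(dists, axis=1)
    nearest_dist = dists[np.arange(len(unique)), nearest]
    rois = np.asarray(cent.index)

    rows = []
    for donor_id, donor_mask in unique.groupby("donor_id", sort=True).groups.items():
        loc = unique.index.get_indexer(donor_mask)
        if loc.size == 0:
            raise ValueError(f"donor {donor_id} has zero samples")
        covered: set[str] = set()
        for i in loc:
            if nearest_dist[i] <= radius:
                roi = rois[nearest[i]]
                covered.add(roi)
                rows.append(
                    {
                        "donor_id": donor_id,
                        "sample_id": unique.iloc[i]["sample_id"],
                        "roi": roi,
                        "distance": nearest_dist[i],
                        "fallback": False,
                    }
                )
        # fallback: unsampled regions get the donor's globally nearest sample
        for j, roi in enumerate(rois):
            if roi in covered:
                continue
            d = dists[loc, j]
            best = loc[int(np.argmin(d))]
            rows.append(
                {
                    "donor_id": donor_id,
                    "sample_id": unique.iloc[best]["sample_id"],
                    "roi": roi,
                    "distance": float(d.min()),
                    "fallback": True,
                }
            )
    assignment = pd.DataFrame(rows)
    n_fallback = int(assignment["fallback"].sum())
    if n_fallback:
        logger.info("%d donor-region cells filled by nearest-sample fallback", n_fallback)

    merged = samples.merge(
        assignment[["donor_id", "sample_id", "roi"]],
        on=["donor_id", "sample_id"],
        how="inner",
    )
    region_means = (
        merged.groupby(["donor_id", "roi", "probe_id"], sort=True)["intensity"]
        .mean()
        .reset_index()
    )
    return assignment, region_means


def differential_stability(profiles: pd.DataFrame, min_common: int = 3) -> float:
    """Mean pairwise inter-donor Spearman correlation of regional profiles.

    ``profiles`` is donors x regions for one probe (NaN where a donor lacks
    the region).  Donor pairs with fewer than ``min_common`` shared regions
    or with a constant profile on the shared regions are skipped (logged);
    if every pair is skipped a ValueError is raised.
    """
    values = profiles.to_numpy(dtype=float)
    n_donors = values.shape[0]
    if n_donors < 2:
        raise ValueError("differential stability needs at least 2 donors")
    corrs = []
    n_skipped = 0
    for a in range(n_donors):
        for b in range(a + 1, n_donors):
            mask = np.isfinite(values[a]) & np.isfinite(values[b])
            if mask.sum() < min_common:
                n_skipped += 1
                continue
            xa, xb = values[a, mask], values[b, mask]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                n_skipped += 1
                continue
            corrs.append(float(np.corrcoef(rankdata(xa), rankdata(xb))[0, 1]))
    if n_skipped:
        logger.debug("differential stability skipped %d donor pair(s)", n_skipped)
    if not corrs:
        raise ValueError("all donor pairs skipped; differential stability undefined")
    return float(np.mean(corrs))


def differential_stability_table(
    region_means: pd.DataFrame, min_common: int = 3
) -> pd.Series:
    """Differential stability for every probe in a donor/region mean table.

    Probes whose score is undefined (all pairs skipped) are returned as NaN
    with a logged count.
    """
    wide = region_means.pivot_table(
        index="probe_id", columns=["donor_id", "roi"], values="intensity"
    )
    donor_ids = sorted(region_means["donor_id"].unique())
    scores = {}
    n_undefined = 0
    for probe_id, row in wide.iterrows():
        prof = row.unstack(level=0).T.reindex(donor_ids)  # donors x regions
        try:
            scores[probe_id] = differential_stability(prof, min_common=min_common)
        except ValueError:
            scores[probe_id] = np.nan
            n_undefined += 1
    if n_undefined:
        logger.info("%d probe(s) with undefined differential stability", n_undefined)
    return pd.Series(scores, name="ds").rename_axis("probe_id")


def select_probe_per_gene(
    ds: pd.Series, probe_map: pd.DataFrame
) -> pd.Series:
    """Pick, per gene, the probe with the highest differential stability.

    Ties break to the lexicographically smallest probe id.  Genes whose
    probes all lack a defined score are dropped with a log message.
    Returns a Series gene_id -> probe_id.
    """
    pm = probe_map[probe_map["probe_id"].isin(ds.index)].copy()
    pm["ds"] = pm["probe_id"].map(ds)
    pm = pm[np.isfinite(pm["ds"])]
    before = probe_map["gene_id"].nunique()
    pm = pm.sort_values(["gene_id", "ds", "probe_id"], ascending=[True, False, True])
    chosen = pm.groupby("gene_id", sort=True).first()["probe_id"]
    dropped = before - len(chosen)
    if dropped:
        logger.info("%d gene(s) dropped: no retained probe with a defined score", dropped)
    return chosen


def robust_sigmoid_normalize(x, rescale: bool = True) -> np.ndarray:
    """Scaled robust sigmoid: logistic in (x - median) / (IQR / 1.35).

    The IQR/1.35 scale approximates the SD of a normal distribution, making
    the transform outlier-resistant but comparable to a z-score sigmoid.
    With ``rescale`` the result is min-max mapped onto [0, 1] over regions.
    Raises ValueError when the IQR is zero (degenerate profile).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 regional values")
    q25, q75 = np.percentile(x, [25, 75])
    iqr = q75 - q25
    if not iqr > 0:
        raise ValueError("zero IQR: profile is degenerate")
    s = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / (iqr / 1.35)))
    if not rescale:
        return s
    return (s - s.min()) / (s.max() - s.min())


def normalize_donor_block(block: pd.DataFrame) -> pd.DataFrame:
    """Robust-sigmoid normalise each gene column of one donor's region x gene
    block; degenerate (zero-IQR) genes become NaN columns (dropped for that
    donor) with a logged count."""
    out = {}
    n_degenerate = 0
    for gene in block.columns:
        col = block[gene].to_numpy(dtype=float)
        try:
            out[gene] = robust_sigmoid_normalize(col)
        except ValueError:
            out[gene] = np.full(col.shape, np.nan)
            n_degenerate += 1
    if n_degenerate:
        logger.info("%d degenerate gene profile(s) dropped for one donor", n_degenerate)
    return pd.DataFrame(out, index=block.index)


def aggregate_expression(blocks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-donor normalised blocks (NaN-aware).

    Raises if any region x gene cell has no donor coverage at all.
    """
    if not blocks:
        raise ValueError("no donor blocks to aggregate")
    donors = sorted(blocks)
    stacked = np.stack([blocks[d].to_numpy(dtype=float) for d in donors])
    coverage = np.isfinite(stacked).sum(axis=0)
    if np.any(coverage == 0):
        first = blocks[donors[0]]
        ii, jj = np.nonzero(coverage == 0)
        cells = [(str(first.index[i]), str(first.columns[j])) for i, j in zip(ii[:10], jj[:10])]
        raise ValueError(f"region x gene cell(s) with no donor coverage, e.g. {cells}")
    with np.errstate(invalid="ignore"):
        mean = np.nansum(stacked, axis=0) / coverage
    first = blocks[donors[0]]
    return pd.DataFrame(mean, index=first.index, columns=first.columns)


def prepare_expression_matrix(
    samples: pd.DataFrame,
    probe_map: pd.DataFrame,
    centroids: pd.DataFrame,
    min_fraction: float = 0.5,
    radius: float = 2.0,
    roi_labels: tuple[str, ...] = DESIKAN_KILLIANY_LH,
) -> pd.DataFrame:
    """Full preprocessing pipeline: filter, assign, select, normalise, average.

    Returns the regions x genes matrix with values in [0, 1], rows in the
    canonical region order and columns sorted by gene id.
    """
    retained = filter_probes_intensity(samples, min_fraction=min_fraction)
    filtered = samples[samples["probe_id"].isin(retained)]
    if len(filtered) == 0:
        raise ValueError("no probe survived the intensity filter")
    _, region_means = assign_samples_to_regions(filtered, centroids, radius=radius)
    ds = differential_stability_table(region_means)
    chosen = select_probe_per_gene(ds, probe_map)
    probe_to_gene = pd.Series(chosen.index.values, index=chosen.values)

    selected = region_means[region_means["probe_id"].isin(probe_to_gene.index)].copy()
    selected["gene_id"] = selected["probe_id"].map(probe_to_gene)

    blocks: dict[str, pd.DataFrame] = {}
    for donor_id, donor_block in selected.groupby("donor_id", sort=True):
        wide = donor_block.pivot(index="roi", columns="gene_id", values="intensity")
        wide = wide.reindex(index=list(roi_labels))
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()][:5].tolist()
            raise ValueError(
                f"donor {donor_id} missing regional values for gene(s) {bad}"
            )
        blocks[str(donor_id)] = normalize_donor_block(wide)
    matrix = aggregate_expression(blocks)
    return matrix.reindex(columns=sorted(matrix.columns))


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="roi")


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("roi").to_csv(path, sep="\t", float_format="%.12g")
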