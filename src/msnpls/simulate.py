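"""Synthetic cohorts, feature tables, expression data and gene sets.

The generator emulates the study conditions end to end so every pipeline
stage can be exercised offline:

* two biomarker groups with covariate distributions matching the cohort's
  published means/SDs and male/female counts, and CSF values drawn inside
  the corresponding classification regions;
* per-subject regional feature tables built from a shared-component mixing
  model: for subject s and region i the 13-feature vector is
  ``sqrt(alpha_i) * g_s + sqrt(1 - alpha_i) * eps_si`` with g_s a
  subject-level standard-normal vector.  Because regional similarity is
  correlation-based, the group effect is planted on the mixing weight alpha
  (not on feature means, which cancel under z-scoring): target regions get
  ``alpha + effect_delta`` in the positive group, which raises (or lowers)
  their expected regional MS;
* a region x gene expression matrix in which planted signal genes track a
  supplied regional pattern at a chosen signal-to-noise ratio, with signs
  split between positive and negative trackers;
* donor-level microarray-like sample tables (centroids on a coarse grid,
  jittered samples, per-donor affine distortion, one low-noise probe per
  gene plus noisier alternates, above-background flags biased toward the
  good probe) from which the expression-prep stage must recover the matrix;
* GMT gene-set collections with sets enriched for the planted signal genes
  of one sign plus uniform null sets.

All generators are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CsfMeasurement, Group, SubjectRecord, classify_csf_status
from .enrichment import GeneSet, GeneSetCollection
from .rois import DESIKAN_KILLIANY_LH, FEATURE_NAMES

#: Per-group covariate distributions: mean/SD for age, education and MMSE,
#: and the male fraction, matching the published cohort (biomarker-negative
#: n=172 with 71 males, biomarker-positive n=126 with 60 males).
DEFAULT_COVARIATE_PARAMS: dict[str, dict[str, tuple[float, float] | float]] = {
    "NEG_NEG": {
        "age": (71.05, 7.10),
        "education": (16.70, 2.38),
        "mmse": (28.85, 1.47),
        "male_fraction": 71 / 172,
    },
    "POS_POS": {
        "age": (77.18, 7.92),
        "education": (16.01, 2.54),
        "mmse": (26.06, 4.62),
        "male_fraction": 60 / 126,
    },
}


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    The defaults reproduce the study conditions: group sizes 172/126, 34
    regions x 13 features, a similarity effect planted in the two regions
    reported with increased similarity, six expression donors, and a
    moderate signal-to-noise ratio for the planted transcriptomic signal.
    """

    seed: int = 0
    n_per_group: tuple[int, int] = (172, 126)  # (NEG_NEG, POS_POS)
    regions: tuple[str, ...] = DESIKAN_KILLIANY_LH
    feature_names: tuple[str, ...] = FEATURE_NAMES
    base_alpha: float = 0.3
    effect_delta: float = 0.15
    target_rois: tuple[str, ...] = ("caudalanteriorcingulate", "lateraloccipital")
    covariate_params: Mapping[str, Mapping] = field(
        default_factory=lambda: DEFAULT_COVARIATE_PARAMS
    )
    # expression matrix
    n_genes: int = 2000
    n_signal: int = 50  # per sign
    signal_snr: float = 1.0
    # donor-level microarray emulation
    n_donors: int = 6
    samples_per_region: int = 2
    probes_per_gene: int = 2
    background_rate: float = 0.9
    region_coverage: float = 0.9
    donor_gain_range: tuple[float, float] = (0.8, 1.25)
    good_probe_noise: float = 0.1
    bad_probe_noise: float = 0.5
    # gene sets
    set_size: int = 50
    n_null_sets: int = 5
    enrichment_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.base_alpha < 1):
            raise ValueError("base_alpha must lie in [0, 1)")
        if not (0 <= self.base_alpha + abs(self.effect_delta) < 1):
            raise ValueError("base_alpha + |effect_delta| must stay below 1")
        if 2 * self.n_signal > self.n_genes:
            raise ValueError("2 * n_signal must not exceed n_genes")
        unknown = set(self.target_rois) - set(self.regions)
        if unknown:
            raise ValueError(f"unknown target ROI(s): {sorted(unknown)}")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)


def _draw_covariates(
    rng: np.random.Generator, group: Group, params: SimulationParams
) -> dict:
    cfg = params.covariate_params[group.value]
    age = float(rng.normal(*cfg["age"]))
    education = float(rng.normal(*cfg["education"]))
    mmse = int(np.clip(round(rng.normal(*cfg["mmse"])), 0, 30))
    gender = "M" if rng.random() < cfg["male_fraction"] else "F"
    if group is Group.NEG_NEG:
        csf = CsfMeasurement(float(rng.uniform(980.0, 1800.0)), float(rng.uniform(8.0, 24.0)))
    else:
        csf = CsfMeasurement(float(rng.uniform(400.0, 979.9)), float(rng.uniform(24.1, 120.0)))
    assert classify_csf_status(csf) is group
    return dict(age=max(age, 40.0), gender=gender, education=max(education, 6.0), mmse=mmse, csf=csf)


def simulate_cohort(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list[SubjectRecord], dict[str, pd.DataFrame]]:
    """Draw subject records and per-subject regional feature tables."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n_regions = len(params.regions)
    n_features = len(params.feature_names)
    target_idx = np.array([params.regions.index(r) for r in params.target_rois], dtype=int)

    records: list[SubjectRecord] = []
    tables: dict[str, pd.DataFrame] = {}
    counter = 0
    for group, n in zip((Group.NEG_NEG, Group.POS_POS), params.n_per_group):
        for _ in range(n):
            counter += 1
            sid = f"sub{counter:04d}"
            cov = _draw_covariates(rng, group, params)
            records.append(SubjectRecord(subject_id=sid, group=group, **cov))

            alpha = np.full(n_regions, params.base_alpha)
            if group is Group.POS_POS and target_idx.size:
                alpha[target_idx] = params.base_alpha + params.effect_delta
            g = rng.standard_normal(n_features)
            # Random +-1 loading per region: a component constant across all
            # regions would be removed by the per-feature z-scoring, whereas a
            # sign-flipping one survives it and yields |corr| ~ sqrt(a_i a_j),
            # which is what the regional-MS statistic (mean |r|) measures.
            loading = rng.choice([-1.0, 1.0], size=n_regions)
            eps = rng.standard_normal((n_regions, n_features))
            values = (
                (np.sqrt(alpha) * loading)[:, None] * g[None, :]
                + np.sqrt(1.0 - alpha)[:, None] * eps
            )
            tables[sid] = pd.DataFrame(
                values, index=list(params.regions), columns=list(params.feature_names)
            )
    return records, tables


def simulate_expression_matrix(
    params: SimulationParams,
    planted_pattern: Sequence[float],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region x gene matrix with planted pattern-tracking signal genes.

    Signal columns are ``sign * standardize(pattern) * snr + N(0, 1)`` noise,
    unit-rescaled to [0, 1]; null columns are pure rescaled noise.  Signal
    gene positions are drawn uniformly; signs are split equally.

    Returns the matrix and a table (gene_id, sign) of the planted genes.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    pattern = np.asarray(planted_pattern, dtype=float)
    n_regions = len(params.regions)
    if pattern.shape != (n_regions,):
        raise ValueError(f"planted pattern must have length {n_regions}")
    if not np.all(np.isfinite(pattern)) or np.ptp(pattern) == 0:
        raise ValueError("planted pattern must be finite and non-constant")
    z = (pattern - pattern.mean()) / pattern.std(ddof=1)

    G = params.n_genes
    width = len(str(G))
    gene_ids = [f"g{j + 1:0{width}d}" for j in range(G)]
    signal_pos = rng.choice(G, size=2 * params.n_signal, replace=False)
    signs = np.concatenate(
        [np.ones(params.n_signal), -np.ones(params.n_signal)]
    ).astype(int)

    values = rng.standard_normal((n_regions, G))
    for pos, sign in zip(signal_pos, signs):
        values[:, pos] += sign * z * params.signal_snr
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    values = (values - lo) / (hi - lo)

    matrix = pd.DataFrame(values, index=list(params.regions), columns=gene_ids)
    signal = pd.DataFrame(
        {"gene_id": [gene_ids[p] for p in signal_pos], "sign": signs}
    ).sort_values("gene_id", ignore_index=True)
    return matrix, signal


def region_centroid_grid(regions: Sequence[str], spacing: float = 10.0) -> pd.DataFrame:
    """Deterministic centroid coordinates on a cubic lattice >= spacing apart."""
    rows = []
    for i, roi in enumerate(regions):
        rows.append(
            {
                "roi": roi,
                "x": spacing * (i % 4),
                "y": spacing * ((i // 4) % 4),
                "z": spacing * (i // 16),
            }
        )
    return pd.DataFrame(rows)


def simulate_donor_samples(
    params: SimulationParams,
    expression: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Donor-level microarray-like observations of a ground-truth matrix.

    Each donor covers a random subset of regions (each included with
    probability ``region_coverage``, at least three), emitting
    ``samples_per_region`` samples jittered < 1 mm around the centroid.
    Probe intensities are a per-donor affine distortion of the truth plus
    Gaussian noise; probe 0 of each gene is the low-noise "good" probe and
    also the one most likely to be flagged above background.

    Returns (samples, probe_map, centroids) in the documented TSV layouts.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    regions = list(expression.index)
    genes = list(expression.columns)
    centroids = region_centroid_grid(regions)
    cent_xyz = centroids.set_index("roi")[["x", "y", "z"]]

    probe_rows = []
    for gene in genes:
        for k in range(params.probes_per_gene):
            probe_rows.append({"probe_id": f"{gene}_p{k}", "gene_id": gene})
    probe_map = pd.DataFrame(probe_rows)

    truth = expression.to_numpy(dtype=float)
    n_regions = len(regions)
    sample_frames = []
    for d in range(params.n_donors):
        donor_id = f"donor{d + 1}"
        gain = float(rng.uniform(*params.donor_gain_range))
        offset = float(rng.uniform(-0.2, 0.2))
        covered = np.flatnonzero(rng.random(n_regions) < params.region_coverage)
        if covered.size < 3:
            covered = rng.choice(n_regions, size=3, replace=False)
        sample_counter = 0
        for i in covered:
            roi = regions[i]
            base = cent_xyz.loc[roi].to_numpy(dtype=float)
            for _ in range(params.samples_per_region):
                sample_counter += 1
                sample_id = f"{donor_id}_s{sample_counter:04d}"
                coords = base + rng.uniform(-0.5, 0.5, size=3)
                for k in range(params.probes_per_gene):
                    noise_sd = params.good_probe_noise if k == 0 else params.bad_probe_noise
                    flag_rate = (
                        params.background_rate if k == 0 else params.background_rate * 0.4
                    )
                    intensity = (
                        gain * truth[i]
                        + offset
                        + rng.normal(0.0, noise_sd, size=len(genes))
                    )
                    flags = rng.random(len(genes)) < flag_rate
                    sample_frames.append(
                        pd.DataFrame(
                            {
                                "donor_id": donor_id,
                                "sample_id": sample_id,
                                "x": coords[0],
                                "y": coords[1],
                                "z": coords[2],
                                "probe_id": [f"{g}_p{k}" for g in genes],
                                "intensity": intensity,
                                "above_background": flags,
                            }
                        )
                    )
    samples = pd.concat(sample_frames, ignore_index=True)
    return samples, probe_map, centroids


def simulate_gene_sets(
    signal_genes: pd.DataFrame,
    background: Sequence[str],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """A GMT-style collection with signal-enriched and null sets.

    Per sign, one "enriched" set draws ``enrichment_fraction`` of its members
    from the same-signed planted signal genes and the remainder uniformly
    from the rest of the background; ``n_null_sets`` sets are uniform draws.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if not (0 <= params.enrichment_fraction <= 1):
        raise ValueError("enrichment_fraction must lie in [0, 1]")
    background = sorted(set(background))
    if params.set_size > len(background):
        raise ValueError("set size exceeds the background")
    bg = np.array(background)

    sets = []
    for sign, label in ((1, "enriched_plus"), (-1, "enriched_minus")):
        pool = signal_genes.loc[signal_genes["sign"] == sign, "gene_id"].tolist()
        pool = sorted(set(pool) & set(background))
        n_from_signal = min(round(params.enrichment_fraction * params.set_size), len(pool))
        chosen = set(rng.choice(pool, size=n_from_signal, replace=False)) if n_from_signal else set()
        remaining = np.array(sorted(set(background) - chosen))
        fill = params.set_size - len(chosen)
        chosen |= set(rng.choice(remaining, size=fill, replace=False))
        sets.append(GeneSet(name=label, genes=frozenset(chosen)))
    for k in range(params.n_null_sets):
        chosen = rng.choice(bg, size=params.set_size, replace=False)
        sets.append(GeneSet(name=f"null_{k + 1}", genes=frozenset(chosen)))
    return GeneSetCollection(name="synthetic_sets", sets=tuple(sets), background=frozenset(background))
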