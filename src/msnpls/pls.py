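"""One-component PLS linking a regional contrast map to gene expression.

The response y is the length-34 vector of per-region group-contrast
t-statistics; the predictors X are the 34 x G region-by-gene expression
matrix.  With a univariate response and one latent component, the PLS weight
vector has the closed form

    w  proportional to  X_s' y_c   (X_s column-standardised, y_c centred)

normalised to unit norm, with region scores t = X_s w.  A sign convention
makes corr(t, y) >= 0.  Model significance comes from permuting y; per-gene
significance from bootstrap resampling of the 34 regions: z = w_g / SE_boot,
two-sided normal p, BH-FDR, and selection of the PLS+ (z > 3) and PLS-
(z < -3) gene lists among FDR-significant genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .stats import bh_fdr

logger = logging.getLogger(__name__)

#: Relative tolerance used when counting permutation statistics that tie the
#: observed value: exact real-arithmetic ties (e.g. a full reversal of a
#: symmetric response) must count as ">= observed" under floating point.
_TIE_RTOL = 1e-12


@dataclass
class PLSModel:
    """Fitted one-component PLS with a univariate response."""

    gene_ids: tuple[str, ...]
    roi_labels: tuple[str, ...]
    weights: np.ndarray  # unit-norm, length G
    scores: np.ndarray  # region scores, length n
    r: float  # corr(scores, y), >= 0 after the sign convention
    r2: float
    sign_flipped: bool


@dataclass
class PermutationResult:
    observed_stat: float
    n_perm: int
    n_at_least_as_extreme: int
    p: float


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            tuple(str(c) for c in X.columns),
            tuple(str(i) for i in X.index),
        )
    X = np.asarray(X, dtype=float)
    return (
        X,
        tuple(f"g{j}" for j in range(X.shape[1])),
        tuple(str(i) for i in range(X.shape[0])),
    )


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(~(sd > 0)):
        raise ValueError("zero-variance column encountered during standardisation")
    return (X - X.mean(axis=0)) / sd


def fit_pls1(X, y, on_constant_gene: str = "error") -> PLSModel:
    """Fit the one-component PLS with closed-form weights.

    Parameters
    ----------
    X : (n_regions, n_genes) array or DataFrame
        Expression predictors; columns are standardised internally.
    y : length-n_regions vector
        Response (contrast t-statistics); centred internally.
    on_constant_gene : {"error", "drop"}
        Whether a zero-variance gene column aborts the fit or is dropped
        (with a log message).
    """
    Xv, gene_ids, roi_labels = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible numbers of regions")
    if not np.std(y, ddof=1) > 0:
        raise ValueError("response y is constant")
    sd = Xv.std(axis=0, ddof=1)
    constant = np.flatnonzero(~(sd > 0))
    if constant.size:
        if on_constant_gene == "drop":
            logger.info("dropping %d zero-variance gene column(s)", constant.size)
            keep = np.flatnonzero(sd > 0)
            Xv = Xv[:, keep]
            gene_ids = tuple(gene_ids[j] for j in keep)
        else:
            names = [gene_ids[j] for j in constant[:10]]
            raise ValueError(f"zero-variance gene column(s), e.g. {names}")
    Xs = _standardize_columns(Xv)
    yc = y - y.mean()
    w = Xs.T @ yc
    norm = np.linalg.norm(w)
    if not norm > 0:
        raise ValueError("degenerate cross-covariance: X'y is the zero vector")
    w = w / norm
    scores = Xs @ w
    r = float(np.corrcoef(scores, y)[0, 1])
    flipped = r < 0
    if flipped:
        w = -w
        scores = -scores
        r = -r
    return PLSModel(
        gene_ids=gene_ids,
        roi_labels=roi_labels,
        weights=w,
        scores=scores,
        r=r,
        r2=r * r,
        sign_flipped=flipped,
    )


def _pls1_stats(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sign-conventioned score-response correlation for each column of Y.

    Xs must be column-standardised; Y holds centred response columns.
    Equivalent to ``fit_pls1(X, y).r`` per column, vectorised.
    """
    W = Xs.T @ Y  # (G, k)
    T = Xs @ W  # (n, k)
    num = np.einsum("ij,ij->j", T, Y)  # = ||Xs'y||^2 >= 0
    den = np.linalg.norm(T, axis=0) * np.linalg.norm(Y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    return stat


def permutation_test(
    X, y, n_perm: int = 10_000, seed=None, chunk_size: int = 2_000
) -> PermutationResult:
    """Permutation significance of the PLS score-response correlation.

    The response entries are shuffled uniformly ``n_perm`` times and the
    one-component statistic recomputed; the p-value uses the add-one rule
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xv, _, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if not np.std(y, ddof=1) > 0:
        raise ValueError("response y is constant")
    Xs = _standardize_columns(Xv)
    yc = y - y.mean()
    observed = float(_pls1_stats(Xs, yc[:, None])[0])

    rng = np.random.default_rng(seed)
    threshold = observed - _TIE_RTOL * abs(observed)
    count = 0
    done = 0
    n = y.shape[0]
    while done < n_perm:
        k = min(chunk_size, n_perm - done)
        perms = rng.permuted(np.tile(yc, (k, 1)), axis=1).T  # (n, k)
        stats = _pls1_stats(Xs, perms)
        count += int(np.count_nonzero(stats >= threshold))
        done += k
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        observed_stat=observed, n_perm=n_perm, n_at_least_as_extreme=count, p=p
    )


def exhaustive_permutation_p(X, y, max_regions: int = 8) -> float:
    """Exact permutation p-value by full enumeration (small n only)."""
    Xv, _, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n > max_regions:
        raise ValueError(f"exhaustive enumeration limited to n <= {max_regions}")
    Xs = _standardize_columns(Xv)
    yc = y - y.mean()
    observed = float(_pls1_stats(Xs, yc[:, None])[0])
    threshold = observed - _TIE_RTOL * abs(observed)
    perms = np.array(list(itertools.permutations(range(n))))
    stats = _pls1_stats(Xs, yc[perms].T)
    return float(np.count_nonzero(stats >= threshold)) / math.factorial(n)


def bootstrap_gene_zscores(
    X,
    y,
    n_boot: int = 1_000,
    seed=None,
    min_distinct_regions: int = 3,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Bootstrap standard errors and z-scores for the PLS gene weights.

    Each replicate resamples the regions with replacement, refits the
    one-component PLS (re-standardising the resampled columns) and aligns the
    replicate weight vector's sign to the original fit.  The per-gene SE is
    the sample SD of the replicate weights; z = original weight / SE.  Genes
    with SE = 0 get z = NaN and are excluded from selection downstream.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    model = fit_pls1(X, y)
    Xv, gene_ids, _ = _as_matrix(X)
    if len(gene_ids) != model.weights.shape[0]:
        raise ValueError("constant gene columns must be dropped before bootstrapping")
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    boot = np.empty((n_boot, len(gene_ids)))
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            if np.unique(idx).size < min_distinct_regions:
                continue
            Xb = Xv[idx]
            yb = y[idx]
            sd = Xb.std(axis=0, ddof=1)
            if np.any(~(sd > 0)) or not np.std(yb, ddof=1) > 0:
                continue
            break
        else:
            raise RuntimeError(
                f"could not draw a valid bootstrap replicate in {max_retries} tries"
            )
        Xbs = (Xb - Xb.mean(axis=0)) / sd
        ybc = yb - yb.mean()
        w = Xbs.T @ ybc
        norm = np.linalg.norm(w)
        if norm > 0:
            w = w / norm
        if w @ model.weights < 0:
            w = -w
        boot[b] = w

    se = boot.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, model.weights / se, np.nan)
    n_flagged = int(np.count_nonzero(~(se > 0)))
    if n_flagged:
        logger.info("%d gene(s) with zero bootstrap SE flagged (z undefined)", n_flagged)
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "weight": model.weights, "se": se, "z": z}
    )


def select_gene_sets(
    scores: pd.DataFrame, z_threshold: float = 3.0, q_threshold: float = 0.05
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Derive per-gene p/q values and the signed significant gene lists.

    p = 2 * (1 - Phi(|z|)); q = BH over all genes with a defined z.  PLS+ is
    {z > z_threshold and q < q_threshold}, PLS- is {z < -z_threshold and
    q < q_threshold}; both lists are sorted by |z| descending.  Returns the
    two lists and the annotated score table (columns p, q, set added).
    """
    out = scores.copy()
    if len(out) == 0:
        out["p"] = np.array([], dtype=float)
        out["q"] = np.array([], dtype=float)
        out["set"] = np.array([], dtype=object)
        return [], [], out
    z = out["z"].to_numpy(dtype=float)
    defined = np.isfinite(z)
    p = np.full(z.shape, np.nan)
    p[defined] = 2.0 * sps.norm.sf(np.abs(z[defined]))
    q = np.full(z.shape, np.nan)
    if defined.any():
        q[defined] = bh_fdr(p[defined])
    significant = defined & (q < q_threshold)
    plus_mask = significant & (z > z_threshold)
    minus_mask = significant & (z < -z_threshold)
    labels = np.where(plus_mask, "PLS_PLUS", np.where(minus_mask, "PLS_MINUS", "NONE"))
    out["p"] = p
    out["q"] = q
    out["set"] = labels

    def _ranked(mask: np.ndarray) -> list[str]:
        sub = out.loc[mask, ["gene_id", "z"]]
        sub = sub.reindex(sub["z"].abs().sort_values(ascending=False, kind="mergesort").index)
        return sub["gene_id"].tolist()

    return _ranked(plus_mask), _ranked(minus_mask), out


class PLSAssociation(BaseEstimator):
    """One-component PLS with permutation and bootstrap inference.

    Parameters
    ----------
    n_perm : int
        Number of response permutations for model significance.
    n_boot : int
        Number of region bootstrap replicates for the gene z-scores.
    z_threshold, q_threshold : float
        Selection cut-offs for the PLS+/PLS- gene lists.
    random_state : int or None
        Seeds two independent child streams (permutations, bootstrap).

    Attributes
    ----------
    model_ : PLSModel
    weights_, scores_ : ndarray
    r_, r2_ : float
    permutation_ : PermutationResult;  permutation_p_ : float
    gene_scores_ : DataFrame (gene_id, weight, se, z, p, q, set)
    pls_plus_, pls_minus_ : list of gene ids sorted by |z| descending
    """

    def __init__(
        self,
        n_perm: int = 10_000,
        n_boot: int = 1_000,
        z_threshold: float = 3.0,
        q_threshold: float = 0.05,
        random_state=None,
    ):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.z_threshold = z_threshold
        self.q_threshold = q_threshold
        self.random_state = random_state

    def fit(self, X, y):
        seq = np.random.SeedSequence(self.random_state)
        perm_seed, boot_seed = seq.spawn(2)
        self.model_ = fit_pls1(X, y)
        self.weights_ = self.model_.weights
        self.scores_ = self.model_.scores
        self.r_ = self.model_.r
        self.r2_ = self.model_.r2
        self.permutation_ = permutation_test(
            X, y, n_perm=self.n_perm, seed=perm_seed
        )
        self.permutation_p_ = self.permutation_.p
        raw = bootstrap_gene_zscores(X, y, n_boot=self.n_boot, seed=boot_seed)
        self.pls_plus_, self.pls_minus_, self.gene_scores_ = select_gene_sets(
            raw, self.z_threshold, self.q_threshold
        )
        return self
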