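"""Quantitative site-level preprocessing and differential testing.

The pipeline mirrors standard label-free phosphoproteomic practice: each
sample is divided by its median intensity and log2-transformed, sites with
too many missing values are dropped, the remainder is completed by
k-nearest-neighbour imputation, and two-class differences are tested with a
SAM-style moderated statistic

    d_i = (mean_2 - mean_1) / (s_i + s0)

whose fudge factor ``s0`` damps the inflation of ``d`` at small per-site
standard errors.  The null distribution of ``d`` comes from group-label
permutations and yields a per-site permutation FDR (q-value); a site is
called significant when ``q < fdr_threshold`` and the absolute log2 fold
change reaches the fold-change threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("phosmap")

__all__ = [
    "QuantMatrix",
    "normalize_log2",
    "filter_missing",
    "impute_knn",
    "sam_differential",
]


@dataclass
class QuantMatrix:
    """A site x sample quantity matrix (NaN marks missing values).

    ``values`` rows are site ids, columns sample ids.  ``groups`` maps each
    sample to its class label (required for differential testing).
    ``log2_transformed`` flags whether values are raw intensities or
    normalised log2 quantities.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without group labels: {sorted(missing)}")
        if not self.log2_transformed:
            if (self.values <= 0).any().any():
                bad = self.values.stack()[self.values.stack() <= 0]
                site, sample = bad.index[0]
                raise ValueError(
                    f"nonpositive raw intensity at site {site!r}, sample {sample!r}"
                )


def normalize_log2(matrix: QuantMatrix) -> QuantMatrix:
    """Divide each sample by its median present value, then log2.

    Missing entries stay missing.  Raises on nonpositive values (naming the
    site and sample) and on all-missing samples.
    """
    if matrix.log2_transformed:
        raise ValueError("matrix is already log2-transformed")
    values = matrix.values
    out = values.copy().astype(float)
    for sample in values.columns:
        col = values[sample]
        present = col.dropna()
        if present.empty:
            raise ValueError(f"sample {sample!r} has no present values")
        out[sample] = np.log2(col / present.median())
    return replace(matrix, values=out, log2_transformed=True)


def filter_missing(
    matrix: QuantMatrix, max_missing_fraction: float = 0.5
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Drop sites whose missing fraction exceeds the threshold.

    A site is removed iff ``missing / n_samples > max_missing_fraction``
    (strictly greater, so a site exactly at the threshold survives).
    Returns the filtered matrix plus a removal report.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.values.isna().mean(axis=1)
    removed = frac[frac > max_missing_fraction]
    report = pd.DataFrame(
        {"site_id": removed.index, "missing_fraction": removed.to_numpy()}
    )
    kept = matrix.values.loc[frac <= max_missing_fraction]
    return replace(matrix, values=kept), report


def impute_knn(matrix: QuantMatrix, k: int = 10) -> QuantMatrix:
    """Complete the matrix by k-nearest-neighbour imputation over sites.

    For each missing cell (site i, sample s) the candidate neighbours are
    the other sites that have a value in ``s`` and share at least one
    observed sample with site i; distance is the root mean squared
    difference over the commonly observed samples.  The cell becomes the
    mean of the k nearest neighbours' values in ``s`` (all valid neighbours,
    with a warning, when fewer than k exist) and falls back to the site mean
    when no valid neighbour exists.  Observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values
    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n_sites, _ = X.shape
    too_sparse = obs.sum(axis=1) < 2
    if too_sparse.any():
        bad = values.index[too_sparse][0]
        raise ValueError(
            f"site {bad!r} has fewer than 2 present values; run filter_missing first"
        )
    out = X.copy()
    warned = False
    for i in range(n_sites):
        miss_cols = np.flatnonzero(~obs[i])
        if miss_cols.size == 0:
            continue
        shared = obs & obs[i]  # per-site mask of samples shared with i
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X - X[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff ** 2).sum(axis=1) / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for s in miss_cols:
            valid = np.isfinite(dist) & obs[:, s]
            idx = np.flatnonzero(valid)
            if idx.size == 0:
                out[i, s] = np.nanmean(X[i])
                continue
            if idx.size < k and not warned:
                logger.warning(
                    "fewer than k=%d valid neighbours for some cells; using all", k
                )
                warned = True
            order = idx[np.lexsort((idx, dist[idx]))][:k]
            out[i, s] = X[order, s].mean()
    completed = pd.DataFrame(out, index=values.index, columns=values.columns)
    return replace(matrix, values=completed)


# -- SAM-style two-class permutation test -------------------------------------


def _group_stats(X: np.ndarray, mask1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (mean2 - mean1, pooled standard error s_i)."""
    X1, X2 = X[:, mask1], X[:, ~mask1]
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


def _d_stat(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    return np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the percentile of s minimizing the coefficient of
    variation of d = r/(s + s0) across bins of s (the original SAM rule)."""
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = max(3, min(100, len(s) // 20))
    quantiles = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = _d_stat(r, s, s0)
        spread = []
        for b in range(n_bins):
            db = d[bins == b]
            if db.size >= 2:
                mad = np.median(np.abs(db - np.median(db))) / 0.64
                spread.append(mad)
        spread = np.asarray(spread)
        if spread.size < 2 or spread.mean() == 0:
            continue
        cv = spread.std(ddof=1) / spread.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(
    n_samples: int, n_group1: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct group-1 sample masks: exhaustive when few, sampled otherwise."""
    total = math.comb(n_samples, n_group1)
    if total <= n_perm:
        masks = []
        for combo in itertools.combinations(range(n_samples), n_group1):
            m = np.zeros(n_samples, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
        return masks
    seen: set[tuple[int, ...]] = set()
    masks = []
    while len(masks) < n_perm:
        combo = tuple(sorted(rng.choice(n_samples, size=n_group1, replace=False)))
        if combo in seen:
            continue
        seen.add(combo)
        m = np.zeros(n_samples, dtype=bool)
        m[list(combo)] = True
        masks.append(m)
    return masks


def sam_differential(
    matrix: QuantMatrix,
    n_perm: int = 1000,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class unpaired SAM test on a complete log2 matrix.

    Returns one row per site with the log2 fold change (group2 - group1
    mean), the moderated ``d`` statistic, the permutation q-value and the
    significance call (``q < fdr_threshold`` and
    ``|log2_fc| >= log2(fc_threshold)``).  The q-value at a site is the
    smallest estimated FDR over all |d| cutoffs that call the site:
    median permutation exceedance count over observed call count, clipped
    to [0, 1].  Deterministic under ``seed``.
    """
    if matrix.groups is None:
        raise ValueError("group labels are required for differential testing")
    if not matrix.log2_transformed:
        raise ValueError("run normalize_log2 first")
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; run impute_knn first")
    groups = matrix.groups.reindex(values.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    mask1 = (groups == labels[0]).to_numpy()
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    X = values.to_numpy(dtype=float)
    r, s = _group_stats(X, mask1)
    s0 = _choose_s0(r, s)
    d_obs = _d_stat(r, s, s0)

    rng = np.random.default_rng(seed)
    masks = _label_permutations(n1 + n2, n1, n_perm, rng)
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")  # descending |d|
    sorted_abs = abs_obs[order]
    n_sites = len(d_obs)
    # observed calls at the cutoff |d| = sorted_abs[rank]
    calls_obs = np.arange(1, n_sites + 1)
    exceed = np.empty((len(masks), n_sites))
    for b, m in enumerate(masks):
        rb, sb = _group_stats(X, m)
        db = np.sort(np.abs(_d_stat(rb, sb, s0)))
        # count of permuted |d| >= each observed cutoff
        exceed[b] = len(db) - np.searchsorted(db, sorted_abs, side="left")
    false_calls = np.median(exceed, axis=0)
    fdr_at_rank = np.clip(false_calls / calls_obs, 0.0, 1.0)
    # q at rank = min FDR over all less-stringent cutoffs (ranks >= this one)
    q_sorted = np.minimum.accumulate(fdr_at_rank[::-1])[::-1]
    q = np.empty(n_sites)
    q[order] = q_sorted

    log2_fc = r  # group2 - group1 difference of log2 means
    significant = (q < fdr_threshold) & (np.abs(log2_fc) >= np.log2(fc_threshold))
    return pd.DataFrame(
        {
            "site_id": values.index,
            "log2_fc": log2_fc,
            "d_statistic": d_obs,
            "q_value": q,
            "significant": significant,
        }
    ).set_index("site_id")
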