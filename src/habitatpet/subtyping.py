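"""Imaging-subtype discovery by consensus clustering of MSI features.

Patients are compared with the Spearman distance (1 minus the rank
correlation of their feature profiles) and clustered with partitioning
around medoids (PAM).  Consensus clustering repeats PAM on random patient
subsamples for each candidate k; the consensus matrix records how often each
pair co-clusters when co-sampled.  The number of subtypes is chosen from the
CDF of consensus values: k is increased while the relative gain in area
under the CDF curve remains above an elbow threshold.  Medoid profiles allow
assigning new cohorts to the discovered subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConsensusResult",
    "spearman_distance",
    "pam",
    "consensus_cluster",
    "select_k_by_cdf",
    "assign_subtype",
    "consensus_cdf_area",
]


def _rank_rows(X: np.ndarray) -> np.ndarray:
    R = np.empty_like(X, dtype=np.float64)
    for i in range(X.shape[0]):
        R[i] = rankdata(X[i])
    return R


def spearman_distance(features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Spearman distances d(a, b) = 1 - rho(rank(a), rank(b)).

    Rows are patients, columns features (at least 3).  The result is
    symmetric with zero diagonal and values in [0, 2].  A patient whose
    feature vector is constant has undefined ranks and raises an error
    naming the row.
    """
    X = features.to_numpy(dtype=np.float64) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 patients and >= 3 features")
    const = np.ptp(X, axis=1) == 0
    if const.any():
        bad = np.where(const)[0]
        raise ValueError(f"constant feature vector for patient row(s) {bad.tolist()}")
    R = _rank_rows(X)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R * R).sum(axis=1))
    rho = (R @ R.T) / np.outer(norm, norm)
    d = 1.0 - np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def pam(D: np.ndarray, k: int, max_swaps: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD initialisation (greedy cost reduction) followed by
    SWAP steps: at each step the single (medoid, non-medoid) exchange with
    the largest cost decrease is applied, until no exchange improves the
    total within-cluster distance or ``max_swaps`` is reached.  Returns
    (labels 0..k-1, medoid indices); clusters are non-empty whenever the
    matrix has at least k distinct points.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        d_near = np.minimum(d_near, D[:, best])
    # SWAP
    medoids = np.array(medoids)
    for _ in range(max_swaps):
        Dm = D[:, medoids]
        order = np.argsort(Dm, axis=1)
        d1 = Dm[np.arange(n), order[:, 0]]
        near = order[:, 0]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            affected = near == mi
            for h in non_medoids:
                dh = D[:, h]
                new_d = np.where(affected, np.minimum(d2, dh), np.minimum(d1, dh))
                delta = d1.sum() - new_d.sum()
                if delta > best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # medoids belong to their own cluster
    return labels.astype(int), medoids


@dataclass
class ConsensusResult:
    """Output of consensus clustering over a k range."""

    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    medoid_features: np.ndarray
    n_resamples: int
    subsample_fraction: float
    seed: int
    feature_names: list[str] = field(default_factory=list)


def _scale01(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def consensus_cdf_area(consensus: np.ndarray, grid: int = 101) -> float:
    """Trapezoid area under the empirical CDF of the upper-triangle
    consensus values, evaluated on a uniform grid over [0, 1]."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    xs = np.linspace(0.0, 1.0, grid)
    cdf = np.searchsorted(np.sort(vals), xs, side="right") / len(vals)
    return float(np.trapezoid(cdf, xs))


def select_k_by_cdf(consensus_by_k: dict[int, np.ndarray],
                    elbow_threshold: float = 0.10) -> tuple[int, dict[int, float], dict[int, float]]:
    """Choose the number of clusters from consensus CDF areas.

    Delta(k) is A(k) for the smallest k and the relative gain
    (A(k) - A(k-1)) / A(k-1) afterwards; the chosen k is the largest with
    Delta(k) above ``elbow_threshold`` (ties toward smaller k by
    construction).  Degenerate identical matrices across k fall back to the
    smallest k with a warning.
    """
    ks = sorted(consensus_by_k)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate k values")
    areas = {k: consensus_cdf_area(consensus_by_k[k]) for k in ks}
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    passing = [k for k in ks if delta[k] > elbow_threshold]
    if not passing:
        warnings.warn("no k exceeds the elbow threshold; falling back to the smallest k")
        return ks[0], areas, delta
    return max(passing), areas, delta


def consensus_cluster(features: np.ndarray | pd.DataFrame,
                      k_range: tuple[int, ...] = (2, 3, 4, 5),
                      n_resamples: int = 500,
                      subsample_fraction: float = 0.8,
                      seed: int = 0,
                      elbow_threshold: float = 0.10) -> ConsensusResult:
    """Consensus clustering of per-patient MSI feature vectors.

    Features are min-max scaled to [0, 1] across the cohort (so ranking
    within a patient's profile is not dominated by count-scale features)
    and compared with the Spearman distance.  For each k, PAM runs on
    ``n_resamples`` random subsamples of ``subsample_fraction`` of the
    patients; consensus(a, b) is the fraction of co-sampled draws in which
    a and b co-clustered.  Final labels come from PAM on (1 - consensus) at
    the CDF-selected k; medoid rows of the original feature matrix are kept
    for assigning new cohorts.  Deterministic given ``seed``.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    ks = tuple(sorted(k_range))
    if n < 2 * max(ks):
        raise ValueError(f"need at least {2 * max(ks)} patients for k up to {max(ks)}")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    D = spearman_distance(_scale01(X))
    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_fraction * n))

    consensus_by_k: dict[int, np.ndarray] = {}
    subsets = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]
    ever = np.zeros(n, dtype=bool)
    for idx in subsets:
        ever[idx] = True
    if not ever.all():
        raise ValueError("some patients were never subsampled; raise n_resamples")
    for k in ks:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for idx in subsets:
            labels, _ = pam(D[np.ix_(idx, idx)], k)
            tog[np.ix_(idx, idx)] += 1
            for lab in range(k):
                mem = idx[labels == lab]
                co[np.ix_(mem, mem)] += 1
        never = tog == 0
        if never.any():
            warnings.warn(f"{int(never.sum() - n)} patient pairs never co-sampled; "
                          "their consensus is 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus_by_k[k] = cons

    chosen_k, areas, delta = select_k_by_cdf(consensus_by_k, elbow_threshold)
    labels, med_idx = pam(1.0 - consensus_by_k[chosen_k], chosen_k)
    # relabel clusters 0..k-1 by decreasing size for stable reporting
    ids, cnt = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-cnt, kind="stable")]
    lut = {int(o): r for r, o in enumerate(order)}
    labels = np.array([lut[int(v)] for v in labels])
    med_idx = med_idx[order]
    return ConsensusResult(
        k_range=ks, consensus=consensus_by_k, cdf_areas=areas, delta_area=delta,
        chosen_k=chosen_k, labels=labels, medoid_indices=med_idx,
        medoid_features=X[med_idx], n_resamples=n_resamples,
        subsample_fraction=subsample_fraction, seed=seed,
        feature_names=feature_names,
    )


def assign_subtype(new_features: np.ndarray | pd.DataFrame,
                   result: ConsensusResult) -> np.ndarray:
    """Assign new patients to the nearest medoid by Spearman distance.

    Ties break toward the lower cluster id.  If ``new_features`` is a
    DataFrame its columns must match the training feature names.
    """
    if isinstance(new_features, pd.DataFrame):
        if list(new_features.columns) != result.feature_names:
            raise ValueError("feature names do not match the fitted result")
        Xn = new_features.to_numpy(dtype=np.float64)
    else:
        Xn = np.asarray(new_features, dtype=np.float64)
    M = result.medoid_features
    Rn = _rank_rows(Xn)
    Rm = _rank_rows(M)
    Rn = Rn - Rn.mean(axis=1, keepdims=True)
    Rm = Rm - Rm.mean(axis=1, keepdims=True)
    nn = np.sqrt((Rn * Rn).sum(axis=1))
    nm = np.sqrt((Rm * Rm).sum(axis=1))
    if (nn == 0).any():
        raise ValueError("constant feature vector in new cohort")
    rho = (Rn @ Rm.T) / np.outer(nn, nm)
    d = 1.0 - rho
    return np.argmin(d, axis=1)
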