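"""Two-level habitat discovery.

The four harmonized channels (windowed CT, CT entropy, SUV, SUV entropy) are
fused into a composite stack; each patient's tumor is over-segmented into
superpixels by k-means on intensity + spatial coordinates; 40 first-order
statistics (10 per channel) summarize each superpixel; and superpixels pooled
across the cohort are clustered into population-level habitats with Louvain
community detection on a shared-nearest-neighbor graph.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io_preproc import ImageVolume, TumorMask, check_same_grid, local_entropy, ct_lung_window

__all__ = [
    "FusedStack",
    "SuperpixelMap",
    "preprocess_case",
    "fuse_channels",
    "oversegment",
    "superpixel_features",
    "population_cluster",
    "render_habitat_map",
    "CHANNEL_NAMES",
    "STAT_NAMES",
    "FEATURE_COLUMNS",
]

CHANNEL_NAMES = ("ct_norm", "ct_entropy", "suv_norm", "suv_entropy")
#: The 10 first-order statistics extracted per channel (40 features total).
STAT_NAMES = ("skewness", "kurtosis", "mean", "median", "q1", "q2",
              "iqr", "sd", "variance", "energy")
FEATURE_COLUMNS = [f"{s}_{c}" for c in CHANNEL_NAMES for s in STAT_NAMES]

#: SUV values are clipped to this ceiling before [0, 1] scaling.
SUV_CEILING = 20.0

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FusedStack:
    """Four [0, 1]-scaled channels plus their voxelwise-sum composite."""

    channels: dict[str, np.ndarray]
    composite: np.ndarray
    mask: TumorMask

    def channel_matrix(self) -> np.ndarray:
        """Tumor-voxel intensities as an (n_voxels, 4) matrix in canonical
        channel order."""
        m = self.mask.data
        return np.column_stack([self.channels[c][m] for c in CHANNEL_NAMES])


@dataclass
class SuperpixelMap:
    """Integer over-segmentation: 0 outside the tumor, 1..S inside."""

    labels: np.ndarray
    patient_id: str = ""

    @property
    def n_superpixels(self) -> int:
        return int(self.labels.max())


def fuse_channels(ct_norm: ImageVolume, ct_ent: ImageVolume,
                  suv: ImageVolume, suv_ent: ImageVolume,
                  mask: TumorMask, entropy_bins: int = 32) -> FusedStack:
    """Scale the four channels to [0, 1] with fixed cohort windows and sum
    them into the composite.

    CT is assumed already lung-windowed to [0, 1]; SUV is clipped at
    ``SUV_CEILING`` and divided by it; entropy maps are divided by their
    maximum attainable value log2(``entropy_bins``).
    """
    check_same_grid(ct_norm, ct_ent, suv, suv_ent, mask)
    emax = np.log2(entropy_bins)
    channels = {
        "ct_norm": np.clip(ct_norm.data, 0.0, 1.0),
        "ct_entropy": np.clip(ct_ent.data / emax, 0.0, 1.0),
        "suv_norm": np.clip(suv.data, 0.0, SUV_CEILING) / SUV_CEILING,
        "suv_entropy": np.clip(suv_ent.data / emax, 0.0, 1.0),
    }
    composite = sum(channels[c] for c in CHANNEL_NAMES)
    return FusedStack(channels=channels, composite=composite, mask=mask)


def preprocess_case(ct: ImageVolume, pet_suv: ImageVolume, mask: TumorMask,
                    window_center: float = -400.0, window_width: float = 1500.0,
                    entropy_radius: int = 1, entropy_bins: int = 32) -> FusedStack:
    """Harmonize one co-registered case into a fused 4-channel stack.

    ``pet_suv`` must already be in SUV units (see
    :func:`habitatpet.io_preproc.compute_suv`).  Entropy maps are computed on
    the windowed CT and on the [0, 1]-scaled SUV so the two texture channels
    share an intensity convention.
    """
    check_same_grid(ct, pet_suv, mask)
    ctw = ct_lung_window(ct, window_center, window_width)
    suv01 = ImageVolume(np.clip(pet_suv.data, 0, SUV_CEILING) / SUV_CEILING,
                        pet_suv.spacing, pet_suv.origin, "NORMALIZED")
    # fixed (0, 1) bin range: both inputs live on fixed harmonized scales, so
    # entropy bins are identical across patients (no per-patient batch shift)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ct_ent = local_entropy(ctw, entropy_radius, entropy_bins, value_range=(0.0, 1.0))
        suv_ent = local_entropy(suv01, entropy_radius, entropy_bins, value_range=(0.0, 1.0))
    return fuse_channels(ctw, ct_ent, pet_suv, suv_ent, mask, entropy_bins)


def _merge_small(labels: np.ndarray, feats: dict[int, np.ndarray],
                 min_size: int) -> np.ndarray:
    """Merge labels smaller than ``min_size`` into the 26-adjacent label with
    the nearest feature centroid.  Isolated fragments with no neighbor are
    kept as-is."""
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_size]
        if len(small) == 0:
            break
        merged_any = False
        # smallest first so tiny slivers are absorbed before larger ones
        for lab in small[np.argsort(counts[np.isin(ids, small)])]:
            sel = labels == lab
            if not sel.any():
                continue
            ring = ndimage.binary_dilation(sel, _STRUCT26) & ~sel
            neigh = np.unique(labels[ring])
            neigh = neigh[(neigh > 0)]
            if len(neigh) == 0:
                continue
            d = [np.linalg.norm(feats[lab] - feats[n]) for n in neigh]
            target = int(neigh[int(np.argmin(d))])
            labels[sel] = target
            n_old, n_new = int(sel.sum()), int((labels == target).sum())
            feats[target] = (feats[target] * (n_new - n_old)
                             + feats[lab] * n_old) / n_new
            del feats[lab]
            merged_any = True
        if not merged_any:
            break
    return labels


def oversegment(stack: FusedStack, n_superpixels: int | None = None,
                compactness: float = 0.2, min_size: int = 10,
                target_size: int = 100, seed: int = 0,
                patient_id: str = "") -> SuperpixelMap:
    """Over-segment the tumor into superpixels.

    k-means with Euclidean distance on vectors (lam*x, lam*y, lam*z,
    c1..c4) restricted to tumor voxels, where lam = ``compactness`` divided
    by the equivalent superpixel diameter (SLIC-style spatial weighting).
    Clusters are split into 26-connected components and components smaller
    than ``min_size`` voxels are merged into the adjacent superpixel with
    nearest centroid.  The result partitions the mask exactly and is
    deterministic given ``seed``.

    ``n_superpixels`` defaults to max(10, round(n_tumor_voxels /
    ``target_size``)).
    """
    mask = stack.mask.data
    n_vox = int(mask.sum())
    if n_superpixels is None:
        n_superpixels = max(10, int(round(n_vox / target_size)))
    if n_superpixels < 1:
        raise ValueError("n_superpixels must be >= 1")
    n_superpixels = min(n_superpixels, n_vox)

    coords = np.argwhere(mask).astype(np.float64)
    intens = stack.channel_matrix()
    if n_superpixels == 1:
        labels = np.zeros(mask.shape, dtype=np.int32)
        labels[mask] = 1
        return SuperpixelMap(labels=labels, patient_id=patient_id)

    equiv_diam = (n_vox / n_superpixels) ** (1.0 / 3.0)
    lam = compactness / equiv_diam
    X = np.column_stack([coords * lam, intens])
    km = KMeans(n_clusters=n_superpixels, n_init=3, random_state=seed)
    assign = km.fit_predict(X)

    # split k-means clusters into 26-connected components
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_id = 1
    feats: dict[int, np.ndarray] = {}
    cvol = np.zeros(mask.shape, dtype=np.int32)
    cvol[mask] = assign + 1
    for k in range(1, n_superpixels + 1):
        comp, n_comp = ndimage.label(cvol == k, structure=_STRUCT26)
        for c in range(1, n_comp + 1):
            sel = comp == c
            labels[sel] = next_id
            vox = np.argwhere(sel).astype(np.float64)
            ch = np.column_stack([stack.channels[name][sel] for name in CHANNEL_NAMES])
            feats[next_id] = np.concatenate([vox.mean(0) * lam, ch.mean(0)])
            next_id += 1

    labels = _merge_small(labels, feats, min_size)
    # dense relabel 1..S
    ids = np.unique(labels[labels > 0])
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    labels = lut[labels]
    if len(ids) < n_superpixels // 2:
        warnings.warn(f"merging reduced superpixels to {len(ids)} "
                      f"(target {n_superpixels})")
    return SuperpixelMap(labels=labels, patient_id=patient_id)


def _first_order_stats(x: np.ndarray) -> list[float]:
    """The 10 first-order statistics of a voxel-intensity sample.

    Skewness and excess kurtosis of (near-)constant samples are 0 by
    convention so feature tables stay finite; energy is the mean squared
    intensity; sd/variance are population (ddof=0) moments; q2 duplicates
    the median by construction of the canonical statistic list.
    """
    x = np.asarray(x, dtype=np.float64)
    mean = float(x.mean())
    var = float(x.var())
    if var < 1e-24:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess kurtosis
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return [skew, kurt, mean, float(med), float(q1), float(med),
            float(q3 - q1), float(np.sqrt(var)), var, float(np.mean(x * x))]


def superpixel_features(stack: FusedStack, spmap: SuperpixelMap) -> pd.DataFrame:
    """Extract the 40 first-order features (10 statistics x 4 channels) per
    superpixel.

    Returns one row per superpixel with ``patient_id``, ``superpixel_id`` and
    the 40 feature columns in canonical order.
    """
    labels = spmap.labels
    n_sp = spmap.n_superpixels
    rows = []
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    starts = np.searchsorted(sorted_labels, np.arange(1, n_sp + 2))
    chans = {c: stack.channels[c].ravel() for c in CHANNEL_NAMES}
    for s in range(1, n_sp + 1):
        idx = order[starts[s - 1]:starts[s]]
        if len(idx) == 0:
            raise ValueError(f"superpixel {s} is empty")
        row: list[float] = []
        for c in CHANNEL_NAMES:
            row.extend(_first_order_stats(chans[c][idx]))
        rows.append(row)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.insert(0, "superpixel_id", np.arange(1, n_sp + 1))
    df.insert(0, "patient_id", spmap.patient_id)
    return df


def population_cluster(features: pd.DataFrame, knn: int = 20,
                       resolution: float = 0.6,
                       snn_prune: float = 1.0 / 15.0,
                       seed: int = 0) -> np.ndarray:
    """Cluster pooled superpixels into population-level habitats.

    Features are z-scored across the pool; a k-nearest-neighbor graph
    (Euclidean) is reweighted by shared-nearest-neighbor Jaccard overlap,
    edges below ``snn_prune`` are dropped, and Louvain community detection
    (with the given resolution) yields habitat ids, relabeled 1..K by
    decreasing community size.  Deterministic given ``seed``.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    n = X.shape[0]
    if n <= knn:
        raise ValueError(f"need more than knn={knn} superpixels, got {n}")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    nn = NearestNeighbors(n_neighbors=knn + 1).fit(Z)
    _, ind = nn.kneighbors(Z)  # includes self in column 0
    neigh_sets = [set(row) for row in ind]
    edges, weights = [], []
    for i in range(n):
        for j in ind[i][1:]:
            j = int(j)
            if j < i and i in neigh_sets[j]:
                continue  # already added from j's list
            inter = len(neigh_sets[i] & neigh_sets[j])
            union = len(neigh_sets[i] | neigh_sets[j])
            w = inter / union
            if w >= snn_prune:
                edges.append((i, j))
                weights.append(w)

    ig.set_random_number_generator(_random.Random(seed))
    g = ig.Graph(n=n, edges=edges)
    part = g.community_multilevel(weights=weights, resolution=resolution)
    memb = np.asarray(part.membership)
    # relabel by decreasing community size, ids 1..K
    ids, counts = np.unique(memb, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    lut = {int(old): rank + 1 for rank, old in enumerate(order)}
    return np.array([lut[int(m)] for m in memb], dtype=np.int32)


def render_habitat_map(spmap: SuperpixelMap, habitat_ids: np.ndarray) -> ImageVolume:
    """Paint per-superpixel habitat ids back onto the voxel grid."""
    habitat_ids = np.asarray(habitat_ids)
    if len(habitat_ids) != spmap.n_superpixels:
        raise ValueError("need one habitat id per superpixel")
    lut = np.zeros(spmap.n_superpixels + 1, dtype=np.int32)
    lut[1:] = habitat_ids
    return ImageVolume(lut[spmap.labels], (1.0, 1.0, 1.0), modality="LABEL")
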