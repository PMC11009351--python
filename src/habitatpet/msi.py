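"""Multiregional spatial interaction (MSI) matrix and its 92 features.

The MSI matrix is a co-occurrence table over habitat labels: for every tumor
voxel, each of its 26-connected neighbors (voxels whose edges or corners
touch) contributes a count to the cell indexed by the two labels.  A reserved
border label (index 0) covers non-tumor voxels adjacent to the tumor, so the
matrix also records how much of each habitat touches the tumor boundary.

From the matrix and the habitat map, 92 features are derived for the
canonical K = 8 habitats: 4 second-order texture statistics of the
normalized matrix (contrast, homogeneity, correlation, energy), 8 absolute
subregion volumes, 8 subregion-border interactions, 28 pairwise subregion
interactions, and the same 44 volume/interaction quantities in normalized
form (percent volume; interactions as fractions of the total unordered
interaction count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_preproc import ImageVolume, TumorMask

__all__ = [
    "MSIMatrix",
    "ConventionalPETMetrics",
    "add_border_label",
    "build_msi_matrix",
    "msi_second_order",
    "extract_msi_features",
    "msi_feature_names",
    "conventional_pet_metrics",
    "OUTSIDE",
    "BORDER",
]

#: Sentinel for voxels that take no part in counting (outside tumor+border).
OUTSIDE = -1
#: Reserved label for the tumor border ring (matrix index 0).
BORDER = 0

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# the 26 neighbor offsets (all nonzero 3-D offsets with |d| <= 1)
_OFFSETS = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]


@dataclass
class MSIMatrix:
    """(K+1) x (K+1) symmetric adjacency counts; index 0 is the border."""

    counts: np.ndarray
    n_habitats: int
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k1 = self.n_habitats + 1
        if self.counts.shape != (k1, k1):
            raise ValueError(f"counts must be {k1}x{k1}")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("MSI matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class ConventionalPETMetrics:
    """Whole-tumor PET quantities used as model covariates."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float
    tumor_volume_ml: float


def add_border_label(hmap: ImageVolume | np.ndarray, mask: TumorMask) -> np.ndarray:
    """Attach the tumor-border ring to a habitat map.

    Returns an integer volume where tumor voxels keep their habitat labels
    (1..K), border voxels — non-tumor voxels 26-adjacent to at least one
    tumor voxel — carry :data:`BORDER` (0), and everything else is
    :data:`OUTSIDE` (-1).
    """
    labels = hmap.data if isinstance(hmap, ImageVolume) else np.asarray(hmap)
    m = mask.data
    if labels.shape != m.shape:
        raise ValueError("habitat map and mask shapes differ")
    if ((labels > 0) != m).any():
        raise ValueError("habitat labels must be nonzero exactly on the mask")
    ring = ndimage.binary_dilation(m, _STRUCT26) & ~m
    if not ring.any():
        raise ValueError("mask fills the grid: no border ring exists")
    out = np.full(labels.shape, OUTSIDE, dtype=np.int32)
    out[m] = labels[m]
    out[ring] = BORDER
    return out


def build_msi_matrix(labeled: np.ndarray, n_habitats: int | None = None) -> MSIMatrix:
    """Count 26-connected label co-occurrences into the MSI matrix.

    ``labeled`` holds habitat labels 1..K on tumor voxels, 0 on the border
    ring and -1 elsewhere (see :func:`add_border_label`).  For every voxel v
    with a tumor or border label and every neighbor u likewise labeled,
    counts[label(v), label(u)] is incremented — except border-border pairs,
    which are skipped.  Ordered counting in both directions makes the matrix
    symmetric by construction; the off-diagonal cell (i, j) then equals the
    number of unordered adjacent (i, j) voxel pairs.
    """
    labeled = np.asarray(labeled)
    if n_habitats is None:
        n_habitats = int(labeled.max())
    if n_habitats < 1 or not (labeled >= 1).any():
        raise ValueError("need at least one tumor voxel with a habitat label")
    if labeled.max() > n_habitats:
        raise ValueError(f"label {labeled.max()} exceeds n_habitats={n_habitats}")
    k1 = n_habitats + 1
    counts = np.zeros((k1, k1), dtype=np.int64)
    valid = labeled >= 0
    for dx, dy, dz in _OFFSETS:
        a = labeled
        b = np.roll(labeled, shift=(-dx, -dy, -dz), axis=(0, 1, 2))
        vb = np.roll(valid, shift=(-dx, -dy, -dz), axis=(0, 1, 2))
        # mask out wrap-around slabs
        edge = np.zeros(labeled.shape, dtype=bool)
        for axis, d in enumerate((dx, dy, dz)):
            if d == 1:
                sl = [slice(None)] * 3
                sl[axis] = slice(-1, None)
                edge[tuple(sl)] = True
            elif d == -1:
                sl = [slice(None)] * 3
                sl[axis] = slice(0, 1)
                edge[tuple(sl)] = True
        ok = valid & vb & ~edge
        ok &= ~((a == BORDER) & (b == BORDER))
        pa, pb = a[ok], b[ok]
        np.add.at(counts, (pa, pb), 1)
    return MSIMatrix(counts=counts, n_habitats=n_habitats)


def msi_second_order(matrix: MSIMatrix | np.ndarray) -> tuple[float, float, float, float]:
    """Contrast, homogeneity, correlation and energy of the normalized MSI
    matrix.

    With P = counts / sum(counts) over 1-based indices i, j:
    contrast = sum P(i,j) (i-j)^2; homogeneity = sum P(i,j) / (1+|i-j|);
    energy = sum P(i,j)^2; correlation = sum (i-mu_i)(j-mu_j) P(i,j) /
    (sigma_i sigma_j), with mu/sigma the marginal mean and SD.  A degenerate
    marginal (sigma_i sigma_j = 0) yields correlation 0 with a warning.
    """
    counts = matrix.counts if isinstance(matrix, MSIMatrix) else np.asarray(matrix)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty MSI matrix")
    P = counts.astype(np.float64) / total
    n = P.shape[0]
    idx = np.arange(1, n + 1, dtype=np.float64)
    I, J = np.meshgrid(idx, idx, indexing="ij")
    contrast = float((P * (I - J) ** 2).sum())
    homogeneity = float((P / (1.0 + np.abs(I - J))).sum())
    energy = float((P * P).sum())
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(idx @ pi), float(idx @ pj)
    sd_i = float(np.sqrt(((idx - mu_i) ** 2) @ pi))
    sd_j = float(np.sqrt(((idx - mu_j) ** 2) @ pj))
    if sd_i * sd_j == 0:
        warnings.warn("degenerate marginal distribution: correlation set to 0")
        correlation = 0.0
    else:
        correlation = float((P * (I - mu_i) * (J - mu_j)).sum() / (sd_i * sd_j))
    return contrast, homogeneity, correlation, energy


def msi_feature_names(n_habitats: int = 8) -> list[str]:
    """Canonical feature names MSI1..MSI{4 + 2*(2K + K(K-1)/2)} (92 for K=8)."""
    n = 4 + 2 * (2 * n_habitats + n_habitats * (n_habitats - 1) // 2)
    return [f"MSI{i}" for i in range(1, n + 1)]


def extract_msi_features(matrix: MSIMatrix, hmap: ImageVolume | np.ndarray,
                         n_habitats: int = 8) -> dict[str, float]:
    """The canonical MSI feature vector (92 named features for K = 8).

    Layout for K = 8: MSI1-4 second-order statistics; MSI5-12 absolute
    subregion volumes SR1..SR8 (voxel counts, 0 for absent habitats);
    MSI13-20 subregion-border interaction counts; MSI21-48 pairwise
    interactions SRi-SRj for i < j in row-major order; MSI49-56 percent
    volumes (summing to 100); MSI57-92 the same interactions normalized by
    the total unordered interaction count (fractions in [0, 1]).
    """
    if matrix.n_habitats != n_habitats:
        raise ValueError(f"matrix has K={matrix.n_habitats}, expected {n_habitats}")
    labels = hmap.data if isinstance(hmap, ImageVolume) else np.asarray(hmap)
    K = n_habitats
    counts = matrix.counts
    volumes = np.array([(labels == k).sum() for k in range(1, K + 1)], dtype=np.float64)
    total_vol = volumes.sum()
    if total_vol <= 0:
        raise ValueError("habitat map has no tumor voxels")

    border_inter = np.array([counts[k, 0] for k in range(1, K + 1)], dtype=np.float64)
    pair_inter = np.array([counts[i, j] for i in range(1, K + 1)
                           for j in range(i + 1, K + 1)], dtype=np.float64)
    # total unordered interaction count: all off-diagonal habitat pairs plus
    # habitat-border pairs, each counted once
    denom = border_inter.sum() + pair_inter.sum()
    denom = denom if denom > 0 else 1.0

    contrast, homogeneity, correlation, energy = msi_second_order(matrix)
    values = [contrast, homogeneity, correlation, energy]
    values += list(volumes)
    values += list(border_inter)
    values += list(pair_inter)
    values += list(100.0 * volumes / total_vol)
    values += list(border_inter / denom)
    values += list(pair_inter / denom)
    names = msi_feature_names(K)
    assert len(values) == len(names)
    return dict(zip(names, (float(v) for v in values)))


def conventional_pet_metrics(suv: ImageVolume, mask: TumorMask,
                             mtv_threshold: float = 2.5,
                             relative: bool = False) -> ConventionalPETMetrics:
    """SUVmax/mean, metabolic tumor volume, total lesion glycolysis and
    tumor volume.

    MTV is the volume (mL) of mask voxels with SUV >= ``mtv_threshold``; with
    ``relative=True`` the threshold is ``mtv_threshold`` x SUVmax (e.g. 0.4
    for the 40%-of-max rule).  TLG = MTV x mean SUV within the MTV region.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = suv.data[m]
    vox_ml = suv.voxel_volume_ml
    suv_max = float(vals.max())
    thr = mtv_threshold * suv_max if relative else mtv_threshold
    hot = vals >= thr
    mtv = float(hot.sum()) * vox_ml
    tlg = mtv * float(vals[hot].mean()) if hot.any() else 0.0
    return ConventionalPETMetrics(
        suv_max=suv_max,
        suv_mean=float(vals.mean()),
        mtv_ml=mtv,
        tlg=tlg,
        tumor_volume_ml=float(m.sum()) * vox_ml,
    )
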