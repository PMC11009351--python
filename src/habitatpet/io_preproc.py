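"""Volume I/O and multi-site CT/PET harmonization.

CT scans are normalized with a lung window, PET activity maps are converted to
body-weight standardized uptake values (SUVbw), both are resampled to a common
isotropic grid, and local-entropy texture maps are derived from the normalized
channels.  These four channels (CT, CT entropy, SUV, SUV entropy) feed habitat
discovery downstream.

Inputs are assumed co-registered: volumes that do not share a grid after
resampling are rejected rather than registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "TumorMask",
    "load_volume",
    "write_volume",
    "load_mask",
    "ct_lung_window",
    "compute_suv",
    "resample_isotropic",
    "local_entropy",
    "read_clinical",
    "write_clinical",
    "check_same_grid",
    "CLINICAL_COLUMNS",
]

#: Recognised modality tags for :class:`ImageVolume`.
MODALITIES = ("CT", "PET_ACT", "SUV", "ENTROPY", "NORMALIZED", "LABEL")

#: Canonical clinical-table header.  ``ctdna_baseline`` takes
#: {detected, not_detected, missing}; ``ctdna_clearance`` takes
#: {Persistent, Cleared, Never Detected, missing}.
CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "stage", "histology", "treatment",
    "rfs_time", "rfs_event", "os_time", "os_event",
    "ctdna_baseline", "ctdna_clearance",
]


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data
        3-D array of voxel values; must be finite everywhere.
    spacing
        Millimetres per voxel along each axis; strictly positive.
    origin
        Physical coordinate (mm) of voxel (0, 0, 0).
    modality
        One of ``CT``, ``PET_ACT``, ``SUV``, ``ENTROPY``, ``NORMALIZED``,
        ``LABEL``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.affine is None:
            aff = np.eye(4)
            aff[:3, :3] = np.diag(self.spacing)
            aff[:3, 3] = self.origin
            self.affine = aff

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class TumorMask:
    """Binary tumor segmentation sharing a grid with its image volumes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("tumor mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def load_volume(path: str | Path, modality: str = "CT") -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for a
    non-3-D image or non-finite voxels (the error names the voxel count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data=data, spacing=spacing, origin=origin,
                       modality=modality, affine=np.array(img.affine))


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI, preserving dtype bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(vol.data.dtype)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> TumorMask:
    vol = load_volume(path, modality="LABEL")
    return TumorMask(data=vol.data > 0, spacing=vol.spacing, origin=vol.origin)


def ct_lung_window(vol: ImageVolume, center: float = -400.0,
                   width: float = 1500.0) -> ImageVolume:
    """Normalize a CT volume with a lung window.

    Maps Hounsfield units linearly so that ``center - width/2`` -> 0 and
    ``center + width/2`` -> 1, clipping outside the window.  The defaults
    (-400 HU center, 1500 HU width) are a standard lung window.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    out = np.clip((vol.data.astype(np.float64) - lo) / width, 0.0, 1.0)
    return ImageVolume(out, vol.spacing, vol.origin, "NORMALIZED", np.array(vol.affine))


def compute_suv(pet: ImageVolume, injected_dose_bq: float,
                body_weight_g: float) -> ImageVolume:
    """Convert a PET activity map (Bq/mL) to body-weight SUV.

    SUVbw(v) = activity(v) / (injected_dose / body_weight), assuming tissue
    density 1 g/mL so that g/mL is dimensionless.
    """
    if injected_dose_bq <= 0:
        raise ValueError("injected dose must be > 0")
    if body_weight_g <= 0:
        raise ValueError("body weight must be > 0")
    act = pet.data.astype(np.float64)
    if (act < 0).any():
        raise ValueError(f"{int((act < 0).sum())} voxel(s) with negative activity")
    suv = act / (injected_dose_bq / body_weight_g)
    return ImageVolume(suv, pet.spacing, pet.origin, "SUV", np.array(pet.affine))


def resample_isotropic(vol: ImageVolume, target_spacing: float = 1.0,
                       is_label: bool = False) -> ImageVolume:
    """Resample a volume to an isotropic grid at ``target_spacing`` mm.

    Intensities use trilinear interpolation; label/mask volumes (``is_label``)
    use nearest-neighbor so no new label values appear.  The grid is anchored
    at the input origin and the physical extent is preserved to within one
    voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be > 0")
    if all(abs(s - target_spacing) < 1e-9 for s in vol.spacing):
        return ImageVolume(vol.data.copy(), vol.spacing, vol.origin,
                           vol.modality, np.array(vol.affine))
    new_shape = tuple(max(1, int(round(n * s / target_spacing)))
                      for n, s in zip(vol.data.shape, vol.spacing))
    zoom = [ns / n for ns, n in zip(new_shape, vol.data.shape)]
    order = 0 if is_label else 1
    out = ndimage.zoom(vol.data.astype(np.float64), zoom, order=order,
                       mode="nearest", grid_mode=True)
    out = out[: new_shape[0], : new_shape[1], : new_shape[2]]
    if is_label:
        out = out.astype(vol.data.dtype)
    spacing = (target_spacing,) * 3
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = vol.origin
    return ImageVolume(out, spacing, vol.origin, vol.modality, aff)


def _ball_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz * zz + yy * yy + xx * xx <= r * r).astype(np.int64)


def bin_indices(data: np.ndarray, n_bins: int,
                value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Assign each voxel to one of ``n_bins`` equal-width bins.

    Bins span ``value_range`` (default: the data's own min..max); the top edge
    is inclusive.  Exposed so that entropy oracles can share the binning rule.
    """
    lo, hi = value_range if value_range is not None else (float(data.min()),
                                                          float(data.max()))
    if hi <= lo:
        raise ValueError("degenerate intensity range")
    idx = np.floor((data - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def local_entropy(vol: ImageVolume, radius: int = 1, n_bins: int = 32,
                  value_range: tuple[float, float] | None = None) -> ImageVolume:
    """Shannon entropy (bits) of the local intensity histogram at each voxel.

    The histogram at voxel v pools the voxels inside a 3-D ball of the given
    radius centred on v (clipped at the volume edge) into ``n_bins`` equal
    bins spanning the volume's intensity range (or an explicit
    ``value_range``).  Output lies in [0, log2(n_bins)].

    A constant volume has no intensity range; it yields an all-zero entropy
    map with a warning.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = vol.data.astype(np.float64)
    lo, hi = value_range if value_range is not None else (float(data.min()),
                                                          float(data.max()))
    if hi <= lo:
        warnings.warn("degenerate intensity range: entropy map is all zero")
        return ImageVolume(np.zeros_like(data), vol.spacing, vol.origin,
                           "ENTROPY", np.array(vol.affine))
    idx = bin_indices(data, n_bins, (lo, hi))
    kernel = _ball_kernel(radius)
    # Per-bin occupancy counts via convolution with the ball footprint;
    # constant-0 padding means edge neighborhoods are simply smaller.
    size = ndimage.convolve(np.ones_like(idx), kernel, mode="constant", cval=0)
    ent = np.zeros(data.shape, dtype=np.float64)
    for b in range(n_bins):
        cnt = ndimage.convolve((idx == b).astype(np.int64), kernel,
                               mode="constant", cval=0)
        p = cnt / size
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    ent = np.clip(ent, 0.0, np.log2(n_bins))
    return ImageVolume(ent, vol.spacing, vol.origin, "ENTROPY", np.array(vol.affine))


def check_same_grid(*items: ImageVolume | TumorMask) -> None:
    """Reject volumes/masks that do not share shape and spacing."""
    ref = items[0]
    for it in items[1:]:
        if it.shape != ref.shape:
            raise ValueError(f"grid mismatch: shapes {ref.shape} vs {it.shape}")
        if any(abs(a - b) > 1e-6 for a, b in zip(it.spacing, ref.spacing)):
            raise ValueError(f"grid mismatch: spacings {ref.spacing} vs {it.spacing}")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical table CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id values")
    for col in ("rfs_time", "os_time"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in {col}")
    for col in ("rfs_event", "os_event"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
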