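"""Synthetic PET/CT phantoms with planted habitats, subtypes and outcomes.

Each phantom is an ellipsoidal tumor on a 64^3 millimetre grid whose voxels
are partitioned into spatially contiguous habitat blobs.  Habitat channel
means follow the qualitative phenotypes of the discovered subregions: some
habitats are dense on CT with low FDG uptake, others show high CT density and
high SUV, and the high-risk subtype mixture is enriched for the high-uptake
habitats, preferentially near the tumor border.

Cohort-level generators add subtype-linked survival times (proportional-
hazards Weibull with uniform censoring) and subtype-linked categorical ctDNA
status, so the full pipeline — habitats, spatial-interaction features,
subtyping, survival evaluation — is exercisable without patient data.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import ndimage

from .io_preproc import ImageVolume, TumorMask

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "simulate_survival",
    "simulate_ctdna",
    "simulate_clinical_cohort",
    "SUBTYPE_NAMES",
    "CTDNA_CLEARANCE_LEVELS",
]

SUBTYPE_NAMES = ("low", "intermediate", "high")
CTDNA_CLEARANCE_LEVELS = ("Persistent", "Cleared", "Never Detected")

# Per-habitat (CT HU, SUV) means and noise SDs for the default 8-habitat
# phantom.  Habitats 3-4: high CT density, low uptake and low PET entropy;
# habitats 7-8: high CT and SUV with low CT entropy.  Per-habitat SDs plant
# distinct local-texture (entropy) levels alongside the intensity levels.
_CT_MEANS_8 = (-750.0, -550.0, -150.0, -20.0, -650.0, -350.0, -80.0, 30.0)
_SUV_MEANS_8 = (0.8, 1.5, 1.0, 1.4, 4.5, 2.8, 6.0, 8.0)
_CT_SDS_8 = (70.0, 120.0, 90.0, 150.0, 110.0, 170.0, 55.0, 60.0)
_SUV_SDS_8 = (0.4, 0.7, 0.5, 0.6, 2.0, 1.3, 1.6, 1.9)

# Subtype habitat volume-fraction mixtures (rows: low, intermediate, high
# risk).  The low-risk mixture is enriched for habitats 3-4, the high-risk
# mixture for habitats 7-8.
_MIXTURES_8 = (
    (0.18, 0.18, 0.28, 0.28, 0.02, 0.02, 0.02, 0.02),
    (0.05, 0.05, 0.15, 0.15, 0.28, 0.28, 0.02, 0.02),
    (0.02, 0.02, 0.04, 0.06, 0.06, 0.06, 0.36, 0.38),
)

# Habitats grown from border-adjacent seeds, per subtype (1-based ids).
_PERIPHERAL_8 = ((), (), (4, 7))


@dataclass
class PhantomSpec:
    """Configuration of the synthetic tumor generator.

    ``subtype_mixtures`` rows are habitat volume-fraction vectors (one per
    subtype) and must each sum to 1.  ``mixture_concentration`` controls the
    per-patient Dirichlet jitter applied by :func:`generate_cohort` around
    the subtype mixture (larger = tighter).  ``peripheral_habitats`` lists,
    per subtype, habitat ids whose blobs are seeded near the tumor border.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radii: tuple[float, float, float] = (18.0, 14.0, 12.0)
    n_habitats: int = 8
    ct_means: tuple[float, ...] = _CT_MEANS_8
    suv_means: tuple[float, ...] = _SUV_MEANS_8
    ct_sds: tuple[float, ...] = _CT_SDS_8
    suv_sds: tuple[float, ...] = _SUV_SDS_8
    noise_scale: float = 1.0
    noise_corr_sigma: float = 1.2
    noise_corr_mix: float = 0.7
    ct_background: float = -820.0
    suv_background: float = 0.3
    subtype_mixtures: tuple[tuple[float, ...], ...] = _MIXTURES_8
    peripheral_habitats: tuple[tuple[int, ...], ...] = _PERIPHERAL_8
    mixture_concentration: float = 120.0

    def __post_init__(self) -> None:
        if self.n_habitats < 2:
            raise ValueError("need at least 2 habitats")
        for name in ("ct_means", "suv_means", "ct_sds", "suv_sds"):
            if len(getattr(self, name)) != self.n_habitats:
                raise ValueError(f"{name} must have one entry per habitat")
        if min(self.ct_sds) < 0 or min(self.suv_sds) < 0 or self.noise_scale < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.peripheral_habitats) < self.n_subtypes:
            self.peripheral_habitats = tuple(self.peripheral_habitats) + tuple(
                () for _ in range(self.n_subtypes - len(self.peripheral_habitats)))
        for mix in self.subtype_mixtures:
            if len(mix) != self.n_habitats:
                raise ValueError("mixture length must equal n_habitats")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture must sum to 1, got {sum(mix)}")

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_mixtures)

    @classmethod
    def four_habitat(cls, noise_scale: float = 1.0) -> "PhantomSpec":
        """A 4-habitat spec with well-separated channel means and textures,
        used for habitat-recovery benchmarking."""
        return cls(
            n_habitats=4,
            ct_means=(-750.0, -150.0, -650.0, 0.0),
            suv_means=(1.0, 1.5, 5.0, 8.5),
            ct_sds=(60.0, 150.0, 100.0, 60.0),
            suv_sds=(0.5, 0.7, 2.2, 1.5),
            noise_scale=noise_scale,
            subtype_mixtures=((0.25, 0.25, 0.25, 0.25),),
            peripheral_habitats=((),),
        )


@dataclass
class PhantomCase:
    """One synthetic patient: images, mask, ground-truth labels, subtype."""

    patient_id: str
    ct: ImageVolume
    pet: ImageVolume  # SUV units
    mask: TumorMask
    truth_labels: ImageVolume  # habitat ground truth, 0 outside tumor
    subtype_truth: int
    clinical: dict = field(default_factory=dict)


def _ellipsoid_mask(shape: tuple[int, int, int], spacing: tuple[float, ...],
                    radii: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipsoid centred in the grid plus the normalized radius map
    rho (0 at centre, 1 at the surface)."""
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho2 = np.zeros(shape, dtype=np.float64)
    for g, c, s, r in zip(grids, center, spacing, radii):
        rho2 += (((g - c) * s) / r) ** 2
    rho = np.sqrt(rho2)
    return rho <= 1.0, rho


_NEIGH6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                    [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_habitats(mask: np.ndarray, rho: np.ndarray, targets: np.ndarray,
                   peripheral: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Partition mask voxels into contiguous compact blobs with given target
    counts.

    Seeded region growth: one random seed per habitat (border-shell seeds
    for ``peripheral`` habitat ids), then voxels are claimed one at a time
    by the habitat with the largest remaining deficit, always taking the
    6-connected frontier voxel nearest its seed (with a small random
    tie-break jitter).  Distance-ordered growth keeps blobs spatially
    coherent rather than dendritic, emulating the compactness of real tumor
    habitats.  A habitat whose frontier is exhausted reseeds from a random
    unassigned voxel.
    """
    import heapq

    shape = mask.shape
    labels = np.zeros(shape, dtype=np.int32)
    coords = np.argwhere(mask)
    n_hab = len(targets)
    if len(coords) < n_hab:
        raise ValueError("tumor too small for the requested number of habitats")
    unassigned = set(map(tuple, coords))
    shell = [c for c in unassigned if rho[c] > 0.72]
    heaps: list[list] = [[] for _ in range(n_hab)]
    seeds: list[tuple[int, int, int] | None] = [None] * n_hab
    deficit = targets.astype(np.int64).copy()

    def _push(h: int, v: tuple[int, int, int]) -> None:
        s = seeds[h]
        d = ((v[0] - s[0]) ** 2 + (v[1] - s[1]) ** 2 + (v[2] - s[2]) ** 2) ** 0.5
        heapq.heappush(heaps[h], (d + rng.uniform(0, 0.5), v))

    def _seed(h: int) -> None:
        pool = [c for c in (shell if (h + 1) in peripheral else unassigned)
                if c in unassigned]
        if not pool:
            pool = list(unassigned)
        else:
            pool = sorted(pool)
        c = pool[rng.integers(len(pool))]
        seeds[h] = c
        _push(h, c)

    for h in range(n_hab):
        if deficit[h] > 0:
            _seed(h)

    while unassigned:
        active = [h for h in range(n_hab) if deficit[h] > 0]
        if not active:  # rounding leftovers: give to the largest habitat
            active = [int(np.argmax(targets))]
            deficit[active[0]] = len(unassigned)
        h = max(active, key=lambda i: deficit[i])
        if not heaps[h]:
            _seed(h)
        _, v = heapq.heappop(heaps[h])
        if v not in unassigned:
            continue
        unassigned.discard(v)
        labels[v] = h + 1
        deficit[h] -= 1
        for d in _NEIGH6:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if u in unassigned:
                _push(h, u)
    return labels


def _texture_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Unit-variance noise field: a mix of white noise and a Gaussian-
    correlated component (correlation length ``noise_corr_sigma`` voxels)
    emulating reconstruction-kernel texture."""
    white = rng.normal(0.0, 1.0, spec.grid_shape)
    mix = spec.noise_corr_mix
    if mix <= 0 or spec.noise_corr_sigma <= 0:
        return white
    smooth = ndimage.gaussian_filter(rng.normal(0.0, 1.0, spec.grid_shape),
                                     spec.noise_corr_sigma)
    smooth /= smooth.std()
    return mix * smooth + np.sqrt(1.0 - mix ** 2) * white


def generate_phantom(spec: PhantomSpec, subtype: int = 0, seed: int = 0,
                     fractions: np.ndarray | None = None,
                     patient_id: str | None = None) -> PhantomCase:
    """Generate one phantom patient of the given subtype.

    ``fractions`` overrides the subtype's habitat volume fractions (e.g. a
    Dirichlet draw from :func:`generate_cohort`); by default the subtype
    mixture is used exactly.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if not 0 <= subtype < spec.n_subtypes:
        raise ValueError(f"subtype {subtype} out of range")
    frac = np.asarray(fractions if fractions is not None
                      else spec.subtype_mixtures[subtype], dtype=np.float64)
    if abs(frac.sum() - 1.0) > 1e-6 or (frac < 0).any():
        raise ValueError("fractions must be nonnegative and sum to 1")
    mask, rho = _ellipsoid_mask(spec.grid_shape, spec.spacing, spec.tumor_radii)
    n_vox = int(mask.sum())
    targets = np.floor(frac * n_vox).astype(np.int64)
    if (frac > 0).sum() > n_vox:
        raise ValueError("fewer tumor voxels than requested habitats")
    targets[frac > 0] = np.maximum(targets[frac > 0], 1)
    # distribute rounding remainder to the largest-fraction habitats
    rem = n_vox - targets.sum()
    order = np.argsort(-frac)
    for i in range(abs(int(rem))):
        targets[order[i % len(order)]] += int(np.sign(rem))
    labels = _grow_habitats(mask, rho, targets,
                            spec.peripheral_habitats[subtype], rng)

    ct = np.full(spec.grid_shape, spec.ct_background, dtype=np.float64)
    suv = np.full(spec.grid_shape, spec.suv_background, dtype=np.float64)
    ct_sd = np.full(spec.grid_shape, 25.0)
    suv_sd = np.full(spec.grid_shape, 0.2)
    for h in range(spec.n_habitats):
        sel = labels == h + 1
        ct[sel] = spec.ct_means[h]
        suv[sel] = spec.suv_means[h]
        ct_sd[sel] = spec.ct_sds[h]
        suv_sd[sel] = spec.suv_sds[h]
    if spec.noise_scale > 0:
        ct += _texture_field(rng, spec) * ct_sd * spec.noise_scale
        suv += _texture_field(rng, spec) * suv_sd * spec.noise_scale
    suv = np.clip(suv, 0.0, None)

    pid = patient_id or f"P{seed:05d}"
    sp = spec.spacing
    return PhantomCase(
        patient_id=pid,
        ct=ImageVolume(ct, sp, modality="CT"),
        pet=ImageVolume(suv, sp, modality="SUV"),
        mask=TumorMask(mask, sp),
        truth_labels=ImageVolume(labels, sp, modality="LABEL"),
        subtype_truth=subtype,
    )


def generate_cohort(n_patients: int, spec: PhantomSpec | None = None,
                    seed: int = 0,
                    subtype_probs: tuple[float, ...] | None = None,
                    radii_jitter: float = 0.15) -> list[PhantomCase]:
    """Generate a cohort with balanced (or ``subtype_probs``-weighted)
    subtypes, per-patient Dirichlet jitter around each subtype mixture and
    uniform +/- ``radii_jitter`` scaling of the tumor radii (so tumor
    volumes vary across patients)."""
    from dataclasses import replace

    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    if subtype_probs is None:
        subtypes = np.arange(n_patients) % spec.n_subtypes
    else:
        subtypes = rng.choice(spec.n_subtypes, size=n_patients, p=subtype_probs)
    cases = []
    for i in range(n_patients):
        mix = np.asarray(spec.subtype_mixtures[subtypes[i]])
        alpha = np.maximum(mix * spec.mixture_concentration, 1e-3)
        frac = rng.dirichlet(alpha)
        scale = rng.uniform(1.0 - radii_jitter, 1.0 + radii_jitter)
        pspec = replace(spec, tumor_radii=tuple(r * scale
                                                for r in spec.tumor_radii))
        case_seed = int(rng.integers(0, 2**31 - 1))
        cases.append(generate_phantom(pspec, int(subtypes[i]), seed=case_seed,
                                      fractions=frac, patient_id=f"P{i:04d}"))
    return cases


def simulate_survival(subtypes: np.ndarray, hr_low_vs_high: float = 0.38,
                      hr_int_vs_high: float = 0.52,
                      baseline_shape: float = 1.2, baseline_scale: float = 60.0,
                      censor_rate: float = 0.5, censor_max: float = 80.0,
                      seed: int = 0,
                      extra_loghazard: np.ndarray | None = None) -> pd.DataFrame:
    """Subtype-linked event times from a proportional-hazards Weibull model.

    Subtype codes: 0 = low risk, 1 = intermediate, 2 = high risk (reference).
    Default hazard ratios vs the high-risk group are 0.38 (low) and 0.52
    (intermediate).  A ``censor_rate`` fraction of patients receives an
    independent U(0, ``censor_max``) censoring time.  ``extra_loghazard``
    adds per-patient log-hazard terms (e.g. ctDNA or treatment effects).
    Returns columns ``time`` (months) and ``event`` (0/1).
    """
    if hr_low_vs_high <= 0 or hr_int_vs_high <= 0:
        raise ValueError("hazard ratios must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if baseline_shape <= 0 or baseline_scale <= 0:
        raise ValueError("Weibull parameters must be > 0")
    subtypes = np.asarray(subtypes)
    rng = np.random.default_rng(seed)
    log_hr = np.where(subtypes == 0, np.log(hr_low_vs_high),
                      np.where(subtypes == 1, np.log(hr_int_vs_high), 0.0))
    if extra_loghazard is not None:
        log_hr = log_hr + np.asarray(extra_loghazard, dtype=np.float64)
    u = rng.uniform(size=len(subtypes))
    t = baseline_scale * (-np.log(u) / np.exp(log_hr)) ** (1.0 / baseline_shape)
    cens = np.full(len(subtypes), np.inf)
    which = rng.uniform(size=len(subtypes)) < censor_rate
    cens[which] = rng.uniform(0.0, censor_max, size=int(which.sum()))
    time = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    return pd.DataFrame({"time": time, "event": event})


# Default per-subtype ctDNA clearance distributions over
# (Persistent, Cleared, Never Detected): 67% of high-risk patients have
# persistent ctDNA, 62% of low-risk patients never have ctDNA detected and
# 45% of intermediate-risk patients clear ctDNA after therapy.
DEFAULT_CTDNA_CLEARANCE_PROBS = {
    0: (0.13, 0.25, 0.62),
    1: (0.25, 0.45, 0.30),
    2: (0.67, 0.18, 0.15),
}


def simulate_ctdna(subtypes: np.ndarray,
                   clearance_probs: dict | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Draw subtype-linked ctDNA categories.

    Clearance is drawn per patient from the subtype's distribution over
    (Persistent, Cleared, Never Detected); baseline detection is the coherent
    indicator: ctDNA was detected before surgery iff the patient's clearance
    category is not "Never Detected".
    """
    probs = clearance_probs or DEFAULT_CTDNA_CLEARANCE_PROBS
    subtypes = np.asarray(subtypes)
    for k, p in probs.items():
        p = np.asarray(p, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"malformed ctDNA distribution for subtype {k}")
    rng = np.random.default_rng(seed)
    clearance = np.empty(len(subtypes), dtype=object)
    for st in np.unique(subtypes):
        sel = subtypes == st
        draws = rng.choice(3, size=int(sel.sum()), p=np.asarray(probs[int(st)]))
        clearance[sel] = np.array(CTDNA_CLEARANCE_LEVELS, dtype=object)[draws]
    baseline = np.where(clearance == "Never Detected", "not_detected", "detected")
    return pd.DataFrame({"ctdna_baseline": baseline, "ctdna_clearance": clearance})


def simulate_clinical_cohort(n: int, seed: int = 0,
                             subtype_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3),
                             hr_low_vs_high: float = 0.38,
                             hr_int_vs_high: float = 0.52,
                             hr_ctdna_persistent: float = 3.0,
                             hr_ctdna_cleared: float = 1.5,
                             hr_chemo: float = 2.0,
                             hr_mtv_per_sd: float = 1.4,
                             censor_rate: float = 0.5) -> pd.DataFrame:
    """A full synthetic clinical table with subtype, ctDNA, PET metrics and
    survival endpoints.

    Recurrence hazard combines the imaging-subtype effect (HRs anchored to
    the multivariate estimates 0.38 / 0.52 vs high risk), an independent
    ctDNA-clearance effect (Persistent vs Never Detected HR 3.0), a
    treatment effect and a metabolic-tumor-volume effect, so that subtype
    and ctDNA each carry signal beyond the clinical covariates.
    """
    rng = np.random.default_rng(seed)
    subtype = rng.choice(3, size=n, p=subtype_probs)
    ctdna = simulate_ctdna(subtype, seed=int(rng.integers(2**31 - 1)))
    age = np.clip(rng.normal(66, 9, n), 40, 90).round(1)
    sex = rng.choice(["M", "F"], size=n, p=[0.55, 0.45])
    histology = rng.choice(["adenocarcinoma", "other"], size=n, p=[0.75, 0.25])
    treatment = rng.choice(["chemotherapy", "other"], size=n, p=[0.35, 0.65])
    stage = rng.choice(["I", "II", "III"], size=n, p=[0.55, 0.25, 0.20])
    # tumor burden: larger and hotter in the high-risk subtype
    log_mtv = rng.normal(1.0 + 0.4 * subtype, 0.8, n)
    mtv = np.exp(log_mtv)
    suv_max = np.exp(rng.normal(1.5 + 0.2 * subtype, 0.5, n))
    tlg = mtv * suv_max * np.exp(rng.normal(-0.7, 0.25, n))
    tumor_volume = mtv * np.exp(rng.normal(0.2, 0.3, n))

    lp = (np.log(hr_ctdna_persistent) * (ctdna["ctdna_clearance"] == "Persistent").to_numpy()
          + np.log(hr_ctdna_cleared) * (ctdna["ctdna_clearance"] == "Cleared").to_numpy()
          + np.log(hr_chemo) * (treatment == "chemotherapy")
          + np.log(hr_mtv_per_sd) * (log_mtv - log_mtv.mean()) / log_mtv.std()
          + np.log(0.75) * (histology == "adenocarcinoma"))
    rfs = simulate_survival(subtype, hr_low_vs_high, hr_int_vs_high,
                            censor_rate=censor_rate,
                            seed=int(rng.integers(2**31 - 1)),
                            extra_loghazard=lp)
    os_ = simulate_survival(subtype, hr_low_vs_high=0.52, hr_int_vs_high=0.68,
                            baseline_scale=75.0, censor_rate=censor_rate,
                            seed=int(rng.integers(2**31 - 1)),
                            extra_loghazard=0.7 * lp)
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age": age, "sex": sex, "stage": stage, "histology": histology,
        "treatment": treatment,
        "rfs_time": rfs["time"].round(2), "rfs_event": rfs["event"],
        "os_time": os_["time"].round(2), "os_event": os_["event"],
        "ctdna_baseline": ctdna["ctdna_baseline"],
        "ctdna_clearance": ctdna["ctdna_clearance"],
        "subtype": np.array(SUBTYPE_NAMES, dtype=object)[subtype],
        "subtype_code": subtype,
        "mtv": mtv.round(3), "tlg": tlg.round(3),
        "suv_max": suv_max.round(3), "tumor_volume": tumor_volume.round(3),
    })
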