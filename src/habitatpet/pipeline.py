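"""End-to-end orchestration: simulate -> preprocess -> habitats -> msi ->
subtype -> survive.

A single YAML config drives every stage; each stage reads and writes files
under one output directory so stages can also run standalone.  Every run
writes the resolved config plus a manifest with SHA-256 hashes of all
artifacts; reruns with the same config and seeds reproduce the hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitats as hb
from . import io_preproc as iop
from . import msi as msi_mod
from . import phantom as ph
from . import subtyping as st
from . import survival as sv

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "STAGES"]

log = logging.getLogger("habitatpet")

STAGES = ("simulate", "preprocess", "habitats", "msi", "subtype", "survive")


@dataclass
class PipelineConfig:
    """Resolved parameters for every pipeline stage."""

    output_dir: str = "habitatpet_run"
    # phantom cohort (set n_patients to 0 to use pre-existing inputs)
    n_patients: int = 24
    cohort_seed: int = 0
    four_habitat_phantom: bool = False
    phantom_noise_scale: float = 1.0
    # preprocessing
    window_center: float = -400.0
    window_width: float = 1500.0
    entropy_radius: int = 1
    entropy_bins: int = 32
    target_spacing: float = 1.0
    # habitats
    superpixel_target_size: int = 100
    compactness: float = 0.2
    min_superpixel_size: int = 10
    knn: int = 20
    resolution: float = 0.6
    habitat_seed: int = 0
    # msi
    mtv_threshold: float = 2.5
    # subtyping
    k_min: int = 2
    k_max: int = 5
    n_resamples: int = 500
    subsample_fraction: float = 0.8
    subtype_seed: int = 0
    # survival
    endpoint: str = "rfs"
    bootstrap_reps: int = 200
    survival_seed: int = 0

    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _phantom_spec(cfg: PipelineConfig) -> ph.PhantomSpec:
    if cfg.four_habitat_phantom:
        return ph.PhantomSpec.four_habitat(noise_scale=cfg.phantom_noise_scale)
    return ph.PhantomSpec(noise_scale=cfg.phantom_noise_scale)


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    """Write a phantom cohort: per-patient CT/PET/mask/truth NIfTI volumes
    plus a clinical table with subtype-linked outcomes and ctDNA."""
    out = cfg.outdir() / "cases"
    out.mkdir(exist_ok=True)
    spec = _phantom_spec(cfg)
    cases = ph.generate_cohort(cfg.n_patients, spec, seed=cfg.cohort_seed)
    rng = np.random.default_rng(cfg.cohort_seed + 1)
    subtype_truth = np.array([c.subtype_truth for c in cases])
    surv_rfs = ph.simulate_survival(subtype_truth, seed=int(rng.integers(2**31 - 1)))
    surv_os = ph.simulate_survival(subtype_truth, hr_low_vs_high=0.52,
                                   hr_int_vs_high=0.68, baseline_scale=75.0,
                                   seed=int(rng.integers(2**31 - 1)))
    ctdna = ph.simulate_ctdna(subtype_truth, seed=int(rng.integers(2**31 - 1)))
    files = []
    for case in cases:
        for tag, vol in (("ct", case.ct), ("pet", case.pet),
                         ("truth", case.truth_labels)):
            files.append(iop.write_volume(vol, out / f"{case.patient_id}_{tag}.nii"))
        mask_vol = iop.ImageVolume(case.mask.data.astype(np.uint8),
                                   case.mask.spacing, case.mask.origin, "LABEL")
        files.append(iop.write_volume(mask_vol, out / f"{case.patient_id}_mask.nii"))
    clin = pd.DataFrame({
        "patient_id": [c.patient_id for c in cases],
        "age": np.clip(rng.normal(66, 9, len(cases)), 40, 90).round(1),
        "sex": rng.choice(["M", "F"], len(cases), p=[0.55, 0.45]),
        "stage": rng.choice(["I", "II", "III"], len(cases), p=[0.55, 0.25, 0.2]),
        "histology": rng.choice(["adenocarcinoma", "other"], len(cases), p=[0.75, 0.25]),
        "treatment": rng.choice(["chemotherapy", "other"], len(cases), p=[0.35, 0.65]),
        "rfs_time": surv_rfs["time"].round(2), "rfs_event": surv_rfs["event"],
        "os_time": surv_os["time"].round(2), "os_event": surv_os["event"],
        "ctdna_baseline": ctdna["ctdna_baseline"],
        "ctdna_clearance": ctdna["ctdna_clearance"],
        "subtype_truth": subtype_truth,
    })
    files.append(iop.write_clinical(clin, cfg.outdir() / "clinical.csv"))
    return files


def _case_ids(cfg: PipelineConfig) -> list[str]:
    clin = iop.read_clinical(cfg.outdir() / "clinical.csv")
    return list(clin["patient_id"])


def stage_preprocess(cfg: PipelineConfig) -> list[Path]:
    """Harmonize each case into the four [0, 1] channels on the target grid."""
    out = cfg.outdir() / "channels"
    out.mkdir(exist_ok=True)
    files = []
    for pid in _case_ids(cfg):
        cdir = cfg.outdir() / "cases"
        ct = iop.load_volume(cdir / f"{pid}_ct.nii", "CT")
        pet = iop.load_volume(cdir / f"{pid}_pet.nii", "SUV")
        mask_v = iop.load_volume(cdir / f"{pid}_mask.nii", "LABEL")
        ct = iop.resample_isotropic(ct, cfg.target_spacing)
        pet = iop.resample_isotropic(pet, cfg.target_spacing)
        mask_v = iop.resample_isotropic(mask_v, cfg.target_spacing, is_label=True)
        mask = iop.TumorMask(mask_v.data > 0, mask_v.spacing, mask_v.origin)
        stack = hb.preprocess_case(ct, pet, mask, cfg.window_center,
                                   cfg.window_width, cfg.entropy_radius,
                                   cfg.entropy_bins)
        for name in hb.CHANNEL_NAMES:
            vol = iop.ImageVolume(stack.channels[name].astype(np.float32),
                                  mask.spacing, mask.origin, "NORMALIZED")
            files.append(iop.write_volume(vol, out / f"{pid}_{name}.nii"))
        files.append(iop.write_volume(
            iop.ImageVolume(mask.data.astype(np.uint8), mask.spacing,
                            mask.origin, "LABEL"),
            out / f"{pid}_mask.nii"))
    return files


def _load_stack(cfg: PipelineConfig, pid: str) -> hb.FusedStack:
    out = cfg.outdir() / "channels"
    mask_v = iop.load_volume(out / f"{pid}_mask.nii", "LABEL")
    mask = iop.TumorMask(mask_v.data > 0, mask_v.spacing, mask_v.origin)
    channels = {name: iop.load_volume(out / f"{pid}_{name}.nii", "NORMALIZED").data
                for name in hb.CHANNEL_NAMES}
    composite = sum(channels[c] for c in hb.CHANNEL_NAMES)
    return hb.FusedStack(channels=channels, composite=composite, mask=mask)


def stage_habitats(cfg: PipelineConfig) -> list[Path]:
    """Over-segment every tumor, pool superpixel features, Louvain-cluster
    them into habitats and render per-patient habitat maps."""
    out = cfg.outdir()
    (out / "superpixels").mkdir(exist_ok=True)
    (out / "habitats").mkdir(exist_ok=True)
    files = []
    tables, spmaps = [], {}
    for i, pid in enumerate(_case_ids(cfg)):
        stack = _load_stack(cfg, pid)
        spmap = hb.oversegment(stack, target_size=cfg.superpixel_target_size,
                               compactness=cfg.compactness,
                               min_size=cfg.min_superpixel_size,
                               seed=cfg.habitat_seed + i, patient_id=pid)
        spmaps[pid] = (spmap, stack.mask)
        tables.append(hb.superpixel_features(stack, spmap))
        files.append(iop.write_volume(
            iop.ImageVolume(spmap.labels, stack.mask.spacing,
                            stack.mask.origin, "LABEL"),
            out / "superpixels" / f"{pid}.nii"))
    pooled = pd.concat(tables, ignore_index=True)
    ids = hb.population_cluster(pooled, knn=cfg.knn, resolution=cfg.resolution,
                                seed=cfg.habitat_seed)
    pooled["habitat"] = ids
    pooled_path = out / "superpixel_features.csv"
    pooled.to_csv(pooled_path, index=False)
    files.append(pooled_path)
    for pid in spmaps:
        sub = pooled[pooled["patient_id"] == pid].sort_values("superpixel_id")
        spmap, mask = spmaps[pid]
        hmap = hb.render_habitat_map(spmap, sub["habitat"].to_numpy())
        hmap = iop.ImageVolume(hmap.data, mask.spacing, mask.origin, "LABEL")
        files.append(iop.write_volume(hmap, out / "habitats" / f"{pid}.nii"))
    return files


def stage_msi(cfg: PipelineConfig) -> list[Path]:
    """Per-patient MSI matrices, MSI feature vectors and conventional PET
    metrics."""
    out = cfg.outdir()
    pooled = pd.read_csv(out / "superpixel_features.csv")
    # canonical 8-habitat (92-feature) vector; absent habitats contribute
    # zero-valued features so vectors stay aligned across patients
    n_habitats = max(8, int(pooled["habitat"].max()))
    rows = []
    for pid in _case_ids(cfg):
        hmap = iop.load_volume(out / "habitats" / f"{pid}.nii", "LABEL")
        mask_v = iop.load_volume(out / "channels" / f"{pid}_mask.nii", "LABEL")
        mask = iop.TumorMask(mask_v.data > 0, mask_v.spacing, mask_v.origin)
        labeled = msi_mod.add_border_label(hmap.data.astype(np.int32), mask)
        matrix = msi_mod.build_msi_matrix(labeled, n_habitats)
        feats = msi_mod.extract_msi_features(matrix, hmap.data, n_habitats)
        pet = iop.load_volume(out / "cases" / f"{pid}_pet.nii", "SUV")
        pet = iop.resample_isotropic(pet, cfg.target_spacing)
        pm = msi_mod.conventional_pet_metrics(pet, mask, cfg.mtv_threshold)
        row = {"patient_id": pid, **feats,
               "suv_max": pm.suv_max, "suv_mean": pm.suv_mean,
               "mtv": pm.mtv_ml, "tlg": pm.tlg,
               "tumor_volume": pm.tumor_volume_ml}
        rows.append(row)
    df = pd.DataFrame(rows)
    path = out / "msi_features.csv"
    df.to_csv(path, index=False)
    return [path]


def stage_subtype(cfg: PipelineConfig) -> list[Path]:
    """Consensus-cluster MSI feature vectors into imaging subtypes."""
    out = cfg.outdir()
    df = pd.read_csv(out / "msi_features.csv")
    feat_cols = [c for c in df.columns if c.startswith("MSI")]
    res = st.consensus_cluster(df[feat_cols],
                               k_range=tuple(range(cfg.k_min, cfg.k_max + 1)),
                               n_resamples=cfg.n_resamples,
                               subsample_fraction=cfg.subsample_fraction,
                               seed=cfg.subtype_seed)
    clin = iop.read_clinical(out / "clinical.csv")
    merged = clin.merge(df, on="patient_id")
    merged["subtype_cluster"] = res.labels
    # post-hoc risk naming: rank clusters by RFS event rate (ascending)
    rates = merged.groupby("subtype_cluster")["rfs_event"].mean().sort_values()
    names = ["low", "intermediate", "high", "cluster4", "cluster5"]
    name_map = {c: names[i] for i, c in enumerate(rates.index)}
    merged["subtype"] = merged["subtype_cluster"].map(name_map)
    files = []
    path = out / "clinical_with_subtypes.csv"
    merged.to_csv(path, index=False)
    files.append(path)
    cons_path = out / "consensus.json"
    with open(cons_path, "w") as fh:
        json.dump({
            "chosen_k": res.chosen_k,
            "cdf_areas": res.cdf_areas,
            "delta_area": res.delta_area,
            "risk_names": {str(k): v for k, v in name_map.items()},
            "n_resamples": res.n_resamples,
            "subsample_fraction": res.subsample_fraction,
            "seed": res.seed,
        }, fh, indent=2)
    files.append(cons_path)
    for k, mat in res.consensus.items():
        p = out / f"consensus_k{k}.csv"
        np.savetxt(p, mat, delimiter=",", fmt="%.6f")
        files.append(p)
    return files


def stage_survive(cfg: PipelineConfig) -> list[Path]:
    """KM/log-rank by subtype, multivariate Cox, ctDNA crosstabs and the
    nested C-index model comparison."""
    out = cfg.outdir()
    df = pd.read_csv(out / "clinical_with_subtypes.csv")
    time_col, event_col = f"{cfg.endpoint}_time", f"{cfg.endpoint}_event"
    results: dict = {"endpoint": cfg.endpoint}
    km = sv.km_logrank(df, "subtype", time_col, event_col)
    results["logrank"] = {"statistic": km.statistic, "p": km.p_value, "df": km.df}
    try:
        cox = sv.cox_fit(df, ["subtype", "age", "mtv"], time_col, event_col,
                         reference={"subtype": "high"})
        results["cox"] = cox.to_dict(orient="records")
    except Exception as exc:  # tiny cohorts may not support a stable fit
        results["cox"] = {"error": str(exc)}
    try:
        comp = sv.compare_models(
            df,
            {"clinical": ["age", "sex", "histology", "treatment"],
             "clinical+volume+subtype": ["age", "sex", "histology", "treatment",
                                         "mtv", "tlg", "suv_max", "tumor_volume",
                                         "subtype"],
             "clinical+volume+subtype+ctdna": ["age", "sex", "histology",
                                               "treatment", "mtv", "tlg",
                                               "suv_max", "tumor_volume",
                                               "subtype", "ctdna_clearance"]},
            time_col, event_col, reference={"subtype": "high"},
            n_bootstrap=cfg.bootstrap_reps, seed=cfg.survival_seed)
        results["c_index"] = comp.c_index
        results["c_index_ci"] = comp.c_ci
        results["c_index_deltas"] = comp.deltas
    except Exception as exc:  # tiny cohorts can lack usable pairs
        results["c_index"] = {"error": str(exc)}
    crosstab = sv.ctdna_crosstab(df)
    results["ctdna_crosstab"] = crosstab.to_dict(orient="records")
    path = out / "survival_results.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    ct_path = out / "ctdna_crosstab.csv"
    crosstab.to_csv(ct_path, index=False)
    return [path, ct_path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "habitats": stage_habitats,
    "msi": stage_msi,
    "subtype": stage_subtype,
    "survive": stage_survive,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order and write the run manifest."""
    out = cfg.outdir()
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": []}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s", stage)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                files = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({
            "name": stage,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
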