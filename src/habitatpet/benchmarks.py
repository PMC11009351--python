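"""Self-contained recovery benchmarks on synthetic phantom cohorts.

Each function generates its own data with the phantom module, runs the
relevant pipeline stage(s) and measures how well planted structure is
recovered: voxel-level habitat agreement (adjusted Rand index), consensus
subtype recovery, Cox confidence-interval coverage, log-rank type-I error
and the concordance gain of nested risk models.  They are used by the test
suite and by the acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import phantom as ph
from .habitats import (oversegment, population_cluster, preprocess_case,
                       render_habitat_map, superpixel_features)
from .msi import add_border_label, build_msi_matrix, extract_msi_features
from .subtyping import consensus_cluster
from .survival import compare_models, cox_fit, km_logrank

__all__ = [
    "habitat_recovery",
    "msi_features_from_truth",
    "subtype_recovery",
    "cox_coverage",
    "logrank_type1_error",
    "cindex_ordering",
]

CLINICAL_COVS = ["age", "sex", "histology", "treatment"]
VOLUME_COVS = ["mtv", "tlg", "suv_max", "tumor_volume"]


def habitat_recovery(n_patients: int = 20, seed: int = 7,
                     noise_scale: float = 1.0) -> dict:
    """End-to-end habitat discovery on a 64^3 four-habitat phantom cohort.

    Runs harmonization, over-segmentation, feature extraction and
    population-level Louvain clustering with default parameters, then scores
    the rendered habitat maps against the planted labels.  Returns the
    pooled voxel-level ARI across all patients, the per-case ARIs and the
    emergent habitat count K.
    """
    spec = ph.PhantomSpec.four_habitat(noise_scale=noise_scale)
    cases = ph.generate_cohort(n_patients, spec, seed=seed)
    tables, maps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, case in enumerate(cases):
            stack = preprocess_case(case.ct, case.pet, case.mask)
            spmap = oversegment(stack, seed=seed + i, patient_id=case.patient_id)
            tables.append(superpixel_features(stack, spmap))
            maps.append((case, spmap))
        pooled = pd.concat(tables, ignore_index=True)
        ids = population_cluster(pooled, seed=seed)
    truth_all, pred_all, per_case = [], [], []
    off = 0
    for case, spmap in maps:
        n = spmap.n_superpixels
        hmap = render_habitat_map(spmap, ids[off:off + n])
        off += n
        m = case.mask.data
        truth_all.append(case.truth_labels.data[m])
        pred_all.append(hmap.data[m])
        per_case.append(adjusted_rand_score(truth_all[-1], pred_all[-1]))
    ari = adjusted_rand_score(np.concatenate(truth_all), np.concatenate(pred_all))
    return {"ari": float(ari), "per_case_ari": per_case,
            "k": int(ids.max()), "n_patients": n_patients}


def msi_features_from_truth(cases: list[ph.PhantomCase],
                            n_habitats: int = 8) -> pd.DataFrame:
    """MSI feature vectors computed from the planted habitat maps."""
    rows = []
    for case in cases:
        labeled = add_border_label(case.truth_labels.data.astype(np.int32),
                                   case.mask)
        matrix = build_msi_matrix(labeled, n_habitats)
        rows.append(extract_msi_features(matrix, case.truth_labels.data,
                                         n_habitats))
    return pd.DataFrame(rows)


def subtype_recovery(seed: int = 0, n_patients: int = 90,
                     n_resamples: int = 200,
                     tumor_radii: tuple[float, float, float] = (14.0, 11.0, 9.0)) -> dict:
    """Consensus-cluster MSI features of a 3-subtype phantom cohort.

    The cohort uses the default subtype mixtures on moderately sized tumors
    (radii in mm chosen to keep the benchmark fast); features come from the
    planted habitat maps so the benchmark isolates the subtyping stage.
    Returns the CDF-selected k and the ARI against the planted subtypes.
    """
    spec = ph.PhantomSpec(tumor_radii=tuple(tumor_radii))
    cases = ph.generate_cohort(n_patients, spec, seed=1000 + seed)
    X = msi_features_from_truth(cases)
    truth = np.array([c.subtype_truth for c in cases])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = consensus_cluster(X, n_resamples=n_resamples, seed=seed)
    return {"chosen_k": res.chosen_k,
            "ari": float(adjusted_rand_score(truth, res.labels)),
            "delta_area": res.delta_area}


def cox_coverage(n_reps: int = 100, hr_low_vs_high: float = 0.38,
                 n: int = 300, seed: int = 0) -> dict:
    """Fraction of replicates whose Cox 95% CI covers the generating hazard
    ratio (low- vs high-risk subtype)."""
    cover = 0
    for rep in range(n_reps):
        subtypes = np.repeat([0, 1, 2], n // 3)
        df = ph.simulate_survival(subtypes, hr_low_vs_high=hr_low_vs_high,
                                  seed=seed * 100003 + rep)
        df["subtype"] = pd.Categorical.from_codes(subtypes,
                                                  ["low", "int", "high"])
        res = cox_fit(df, ["subtype"], reference={"subtype": "high"})
        row = res[res["variable"] == "subtype[low]"].iloc[0]
        cover += row["ci_low"] <= hr_low_vs_high <= row["ci_high"]
    return {"coverage": cover / n_reps, "n_reps": n_reps, "n": n}


def logrank_type1_error(n_reps: int = 500, n: int = 120,
                        seed: int = 0) -> dict:
    """Log-rank rejection rate at alpha = 0.05 when group labels are
    independent of survival, plus the simulated p-values."""
    rng = np.random.default_rng(seed)
    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            df = ph.simulate_survival(np.full(n, 2), seed=seed * 99991 + rep)
            df["group"] = rng.choice(["a", "b"], n)
            pvals.append(km_logrank(df, "group").p_value)
    pvals = np.array(pvals)
    return {"rejection_rate": float((pvals < 0.05).mean()),
            "p_values": pvals, "n_reps": n_reps}


def cindex_ordering(n_seeds: int = 10, n: int = 400, seed: int = 0) -> dict:
    """Harrell's C of nested Cox models on synthetic cohorts where subtype
    and ctDNA each carry hazard signal beyond the clinical covariates.

    Returns the fraction of seeds with the strict ordering
    C(clinical+volume+subtype+ctDNA) > C(clinical+volume+subtype) >
    C(clinical), and the mean C per model.
    """
    specs = {
        "clinical": CLINICAL_COVS,
        "clinical+volume+subtype": CLINICAL_COVS + VOLUME_COVS + ["subtype"],
        "clinical+volume+subtype+ctdna":
            CLINICAL_COVS + VOLUME_COVS + ["subtype", "ctdna_clearance"],
    }
    ordered = 0
    sums = {k: 0.0 for k in specs}
    for s in range(n_seeds):
        df = ph.simulate_clinical_cohort(n, seed=seed * 7919 + s)
        res = compare_models(df, specs, time_col="rfs_time",
                             event_col="rfs_event",
                             reference={"subtype": "high"},
                             n_bootstrap=10, seed=s)
        c = res.c_index
        ordered += (c["clinical+volume+subtype+ctdna"]
                    > c["clinical+volume+subtype"] > c["clinical"])
        for k in specs:
            sums[k] += c[k]
    return {"ordered_fraction": ordered / n_seeds,
            "mean_c": {k: v / n_seeds for k, v in sums.items()},
            "n_seeds": n_seeds}
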