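"""Generate a synthetic PET/CT phantom and harmonize it.

Builds one 8-habitat phantom tumor, converts a PET activity map to SUV,
applies the CT lung window and computes the local-entropy texture maps.
"""

import numpy as np

from habitatpet import (ImageVolume, PhantomSpec, compute_suv, ct_lung_window,
                        generate_phantom, local_entropy)

case = generate_phantom(PhantomSpec(), subtype=2, seed=1)
print(f"phantom {case.patient_id}: tumor of {case.mask.n_voxels} voxels, "
      f"{case.truth_labels.data.max()} habitats, subtype {case.subtype_truth} (high risk)")

# the phantom PET is already in SUV units; here is the SUVbw conversion one
# would apply to a raw activity map (Bq/mL) from a scanner
activity = ImageVolume(case.pet.data * (3.7e8 / 7.0e4), case.pet.spacing,
                       modality="PET_ACT")
suv = compute_suv(activity, injected_dose_bq=3.7e8, body_weight_g=7.0e4)
print(f"SUV range in tumor: {suv.data[case.mask.data].min():.2f}"
      f" .. {suv.data[case.mask.data].max():.2f}"
      " (activity / (dose/weight), density 1 g/mL)")

ctw = ct_lung_window(case.ct)  # -400 HU center, 1500 HU width -> [0, 1]
ent = local_entropy(ctw, radius=1, n_bins=32, value_range=(0.0, 1.0))
m = case.mask.data
print(f"windowed CT in tumor: mean {ctw.data[m].mean():.3f} (0=air, 1=dense)")
print(f"CT entropy in tumor:  mean {ent.data[m].mean():.2f} bits "
      f"(max attainable {np.log2(32):.0f}) - higher = more local texture")
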