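# Full-pipeline configuration (see habitatpet.pipeline.PipelineConfig for
# every key).  Run with: habitatpet run-all --config examples/pipeline_config.yaml
output_dir: scratch/demo_run
n_patients: 12
four_habitat_phantom: true
cohort_seed: 0

window_center: -400.0     # HU
window_width: 1500.0      # HU
entropy_radius: 1         # voxels
entropy_bins: 32
target_spacing: 1.0       # mm

superpixel_target_size: 100
compactness: 0.2
knn: 20
resolution: 0.6
habitat_seed: 0

k_min: 2
k_max: 3
n_resamples: 50
subtype_seed: 0

endpoint: rfs
bootstrap_reps: 50
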