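# Small end-to-end demo: two arms, two fields each, ~10 cells per field.
# Runs in seconds via `ktrquant run-all --config configs/demo.yaml --out scratch/demo`
seed: 7
scene:
  image_height_px: 384
  image_width_px: 384
  n_cells: 10
conditions:
  - name: DMSO
    preset: control
    n_fields: 2
  - name: SCH
    preset: inhibitor
    n_fields: 2
segmentation:
  nucleus_smoothing_sigma: 1.0
  nucleus_min_area: 50
  nucleus_max_area: 5000
  sauvola_window_px: 25
  sauvola_k: 0.1
morphology:
  body_radius_px: 4
  skeleton_length_mode: pixel_count
qc:
  remove_border_cells: true
  area_gate: [100, 20000]
  nucleus_fraction_gate: [0.02, 0.9]
  outlier_rule: iqr
  iqr_multiplier: 1.5
stats:
  comparisons: [[DMSO, SCH]]
output:
  write_images: false
  make_figures: false
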