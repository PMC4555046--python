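# Desk-scale end-to-end run: 20 trials per finger, coarsened SVM grid.
# Remove grid_step / cv_repeats overrides to run the full protocol
# (80 trials per finger, 806-point grid, 30 repeats).
synth:
  trials_per_finger: 20
  seed: 7
seed: 7
cv_repeats: 6
grid_step: 4
finger_inner_folds: 2
detection_sets:
  pc1: [PC1]
  pc123: [PC1, PC2, PC3]
  alpha_beta: [alpha, beta]
finger_sets:
  pc123: [PC1, PC2, PC3]
  alpha_beta: [alpha, beta]
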