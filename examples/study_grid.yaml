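# Full study grid: 36 scenarios x 2 algorithms x 2 caliper widths.
# Run with:  greedymatch run-grid --config examples/study_grid.yaml --out grid.csv
reps: 1000
base_seed: 1
algorithms: [caliper_random, nn_caliper]
caliper_multipliers: [0.2, 0.01]
grid:
  n: [500, 2500, 10000]
  p_treat: [0.2, 0.5]
  p_outcome: [0.1, 0.5]
  true_or: [0.75, 1.0, 1.5]
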