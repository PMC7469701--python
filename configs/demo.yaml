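# Demo run: triplicate injected vs mock at two timepoints, single-cut cleavage
# model, planted off-target complementarity spectrum, decaying crRNA
# contamination. Deterministic under the seed below.
seed: 11
depth: 30000
dispersion: 0.05
fraglen: [180, 320]
transcriptome:
  n_genes: 60
  length_range: [400, 1500]
  gc_target: 0.5
  target_length: 720
  target_weight: 0.12
crrna:
  protospacer_start: 300
cleavage:
  cut_prob: 0.9
  cut_offsets: [0]
  stagger: 6
  five_prime_survival: 0.05
  degradation_to_completion_prob: 0.9
design:
  n_batches: 3
  timepoints: ["128cell", "5hpf"]
  conditions: ["injected", "mock"]
batch_factors: {b1: 1.0, b2: 1.8, b3: 0.6}
contamination: {"128cell": 0.003, "5hpf": 0.0012}
complementarity_spectrum: {22: 2, 18: 5}
analysis:
  epsilon: 1.0e-6
  min_z: 4.0
  n_offsets: 3
  which_ends: both
  ci_method: t
  thresholds: [22, 20, 18, 16, 15, 14, 13]
  min_mean: 5.0
  test_method: lrt
  gating_fold: 50.0
  depth_floor: 1.0e+7
facs:
  n: 50000
  high_frac: 0.002
  high_multiplier: 2000.0
  knockdown_factor: 20.0
plots: false
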