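# Example configuration for `nnindep benchmark` (flat key-value YAML).
# Required keys: kinds, methods, n_points, n_test, n_ref.

# Dependence shapes to benchmark. Functional kinds get Gaussian noise whose
# level is calibrated so the grid MI hits each target; "patchwork" uses a
# random-search copula instead.
kinds: [linear, quadratic, cubic, sine_p05, fourth_root, step, circle, patchwork]

# Dependence measures to compare (larger statistic = more dependence):
# pearson |r|, dcor, hoeffd, kraskov_mi, mic (needs minepy), novel_chisq,
# novel_ext.
methods: [pearson, dcor, hoeffd, novel_chisq, novel_ext]

# Mutual-information targets in nats. Default (when omitted): 20 linearly
# spaced values from 0.01 to 0.5.
mi_values: [0.01, 0.05, 0.1, 0.3, 0.5]

n_points: 320   # points per sample
n_test: 500     # dependent samples per (kind, MI)
n_ref: 500      # independent reference samples (sets the 5% cutoff)
alpha: 0.05     # significance level of the empirical cutoff
seed: 0         # root seed; reference/test streams are spawned disjointly

grid_m: 300     # grid resolution for the MI calibration
patchwork_g: 4  # patchwork copula grid size
geometry: euclidean   # or "torus" (affects only the NN tests' bookkeeping)

# Output (via --out) is a tidy TSV with frozen columns:
# method, kind, target_mi, sigma, n_points, n_test, n_ref, alpha, seed,
# cutoff, power.  Rows already present are skipped, so interrupted runs
# resume where they stopped.
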