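# Minimal end-to-end run: simulate -> preprocess -> evaluate -> stack -> importance
seed: 42
out_dir: runs/demo
task: pd-vs-hc
cohort:
  n_pd: 12
  n_hc: 12
  n_dd: 0
cv:
  outer_k: 3
  inner_k: 2
grid:
  sources: [acceleration, rotation]
  options: [A]
  classifiers: [svm, gbdt]
  svm_C: [1.0]
importance:
  n_repeats: 20
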