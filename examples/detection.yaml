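# Binary detection experiment: 30+30 cohort, both classifiers,
# all-56 and top-3 feature conditions, stratified 10-fold CV.
mode: detection
cohorts:
  - kind: binary
    n_per_class: 30
    pathology: polyp-like
    duration_s: 2.0
cv_k: 10
seed: 7
wavelet: haar
levels: 4
iaif_method: dap
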