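# A small labeled cohort: 10 healthy vs 10 polyp-like sustained vowels.
fs_hz: 22050
classes:
  - name: healthy
    count: 10
    duration_s: 2.0
  - name: polyp-like
    count: 10
    duration_s: 2.0
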