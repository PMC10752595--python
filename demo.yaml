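# Demo pipeline configuration: simulate a small cohort and run every stage.
simulate: true
simulation:
  n_patients: 80
seed: 7
out_dir: demo_run
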