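# End-to-end demo: simulate a temperature-jump dataset from the
# uncatalyzed fixture and fit the Ground<->FS interconversion rates.
schema_version: 1
seed: 11
output_dir: results/demo
stages:
  simulate:
    scenario: tjump_20C
  fit_realtime:
    bootstrap_n: 100
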