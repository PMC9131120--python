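# Demo pipeline run: simulate an ordered day-1 colony, fit every quantity.
seed: 1
output_dir: colonyoptics_out
spectral:
  preset: ASWB_day1
index:
  params:
    n_avg: 1.4
    lambda_p: 578.0
morphometry:
  preset: ASWB
domains:
  params:
    image_size: 256
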