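# 25 mg dapivirine matrix ring in the two-phase vessel: 100 mL acetate
# buffer (pH 4.2) under a 20 mL octanol layer, 1.0 mL daily sampling and
# replacement of each phase, octanol aliquots diluted 1:20 for assay.
drug:
  name: dapivirine
  molecular_weight: 329.4
  pKa: 5.30
  logP: 5.35
  intrinsic_solubility: 0.01765
  ring_loading: 24400.0

medium:
  label: acetate_pH4.2
  solubility: 0.499            # µg/mL, measured in this buffer
  volume: 100.0
  pH: 4.2

protocol:
  kind: biphasic
  days: 28
  volume_ml: 100.0
  octanol_volume_ml: 20.0
  sample_ml: 1.0
  dilution_factor: 20.0

simulation:
  k_r: 2.0                     # 1/day, ring -> buffer approach to saturation
  q_t: 400.0                   # mL/day, buffer <-> octanol transfer
  noise_cv: 0.03
  n_replicates: 4
  anomaly:                     # one ring contacts the octanol from day 10
    replicate: 3
    start_day: 10
    jump_rate: 200.0           # µg/day straight into the octanol layer
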