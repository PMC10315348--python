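# 25 mg dapivirine matrix ring released into 50/50 IPA/water, 28 days,
# daily full medium replacement with weekend bridging (200 mL Friday refill).
drug:
  name: dapivirine
  molecular_weight: 329.4      # g/mol
  pKa: 5.30
  logP: 5.35
  intrinsic_solubility: 0.01765  # µg/mL, unionized aqueous
  ring_loading: 24400.0          # µg per ring
  medium_solubilities:
    "50/50": 645.0

medium:
  label: "50/50"
  solubility: 645.0            # µg/mL
  volume: 100.0                # mL
  cosolvent_percent: 50.0

protocol:
  kind: monophasic
  days: 28
  volume_ml: 100.0
  weekend_volume_ml: 200.0
  initial_volume_ml: 200.0
  skip_weekends: true

simulation:
  release_law:
    higuchi_a: 2022.0          # µg/day^1/2
    burst_b: 0.0               # µg
  saturation_fraction: 0.5
  noise_cv: 0.03
  n_replicates: 4
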