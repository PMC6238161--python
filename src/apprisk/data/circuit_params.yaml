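# Default basal-ganglia rate-model parameters (version 1).
# Rates and time constants are in arbitrary units; only the normalized STN
# readout is interpreted downstream.  Chosen so the drug-free fixed point is
# interior (every population active) with cortex normalized to rate 1.
baseline_rates:
  cortex_SMA: 1.0
  MSN_D1: 0.2
  MSN_D2: 0.2
  GPe: 1.0
  STN: 1.0
  GPi: 1.0
weights:
  cortex_SMA->MSN_D1: 0.5
  cortex_SMA->MSN_D2: 0.5
  MSN_D1->GPi: -0.5
  MSN_D2->GPe: -0.5
  GPe->STN: -0.5
  STN->GPi: 0.5
gain_d2: 2.0
gain_5ht2a: 0.3
baseline_d2_activation: 0.5
tau:
  cortex_SMA: 1.0
  MSN_D1: 1.0
  MSN_D2: 1.0
  GPe: 1.0
  STN: 1.0
  GPi: 1.0
tol: 1.0e-10
max_steps: 100000
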