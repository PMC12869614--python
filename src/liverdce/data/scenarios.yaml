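# Built-in synthetic study scenarios.
#
# Ground-truth rates are given in reporting units (min^-1) and converted to
# s^-1 internally.  frame_interval matches the dog (7.65 s) and pig
# (13.4 s) acquisitions; duration is the 60-minute session.  noise_sigma is
# the additive Gaussian noise SD as a fraction of the baseline signal.

dog_eob:
  species: dog
  agent: Gd-EOB-DTPA
  frame_interval: 7.65
  duration: 3600.0
  n_baseline: 10
  tristan: {k1_per_min: 1.0, k2_per_min: 0.027}
  noise_sigma: 0.005
  seed: 1

dog_gadovist:
  species: dog
  agent: Gd-BT-DO3A
  frame_interval: 7.65
  duration: 3600.0
  n_baseline: 10
  # non-hepatospecific: essentially no hepatocyte uptake, but k1 is kept
  # slightly above zero so the fitted lower-bound behaviour is exercised
  tristan: {k1_per_min: 1.0e-6, k2_per_min: 0.01}
  noise_sigma: 0.005
  seed: 1

dog_berks:
  species: dog
  agent: Gd-EOB-DTPA
  frame_interval: 7.65
  duration: 3600.0
  n_baseline: 10
  berks: {alpha_plus: 0.05, beta_plus: 0.01, alpha_minus: 0.002, beta_minus: 2.0e-4, fa: 0.25}
  noise_sigma: 0.005
  seed: 1

pig_eob:
  species: pig
  agent: Gd-EOB-DTPA
  frame_interval: 13.4
  duration: 3600.0
  n_baseline: 10
  tristan: {k1_per_min: 0.24, k2_per_min: 0.15}
  noise_sigma: 0.005
  seed: 1

pig_eob_2:
  species: pig
  agent: Gd-EOB-DTPA
  frame_interval: 13.5
  duration: 3600.0
  n_baseline: 10
  tristan: {k1_per_min: 0.24, k2_per_min: 0.15}
  spleen_in_fov: false
  noise_sigma: 0.005
  seed: 2

pig_bopta:
  species: pig
  agent: Gd-BOPTA
  frame_interval: 13.4
  duration: 3600.0
  n_baseline: 10
  tristan: {k1_per_min: 0.21, k2_per_min: 0.05}
  noise_sigma: 0.005
  seed: 1

pig_dtpa:
  species: pig
  agent: Gd-DTPA
  frame_interval: 13.4
  duration: 3600.0
  n_baseline: 10
  tristan: {k1_per_min: 1.0e-6, k2_per_min: 0.01}
  noise_sigma: 0.005
  seed: 1
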