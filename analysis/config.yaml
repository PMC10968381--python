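# Scaled synthetic two-group study driven by the numbered analysis scripts.
# The athlete-like group gets a 50% alpha-amplitude boost and a phase-locked
# posterior module; every processing parameter below the synthetic block
# keeps its protocol default (0.1-50 Hz, 48/52 Hz notches, 2-s epochs,
# 75 uV rejection, alpha bands, sparsity grid 0.05-0.50).
out_dir: results/study
seed: 1
synthetic:
  n_per_group: 12
  fs: 250.0
  duration: 90.0
  noise_amplitude: 4.0
  mixing_spread: 0.2
  group_amplitude_scale:
    athlete: 1.5
  group_modules:
    athlete:
      - channels: [C2, C4, C6, T8,
                   TP7, CP5, CP3, CP1, CPz, CP2, CP4, CP6, TP8,
                   P7, P5, P3, P1, Pz, P2, P4, P6, P8,
                   PO7, PO3, POz, PO4, PO8, O1, Oz, O2]
        coupling_strength: 0.4
        lag_spacing: 0.1
band_names: [alpha, alpha1, alpha2]
topology_band: alpha
n_perm: 500
richclub_nulls: 20
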