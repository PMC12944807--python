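# Synthetic odorant class templates: characteristic fingerprint-region bands
# (cm^-1) for five structural families of floral odorants. Band centers follow
# standard functional-group assignments; where an assignment spans a range the
# center is the midpoint and the half-width is folded into the jitter SD.
# Intensity means are order-of-magnitude synthetic estimates (no quantitative
# literature intensities exist for most bands), chosen so the aldehyde carbonyl
# dominates its spectrum as described for linear aldehydes/acids.
classes:
  - class_name: sulfide
    odor_label: garlic
    background_mode_count: 10
    background_intensity_scale: 2.0
    bands:
      # S-S stretch
      - {center: 452, center_jitter_sd: 5, intensity_mean: 30, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # CH3 wagging
      - {center: 963, center_jitter_sd: 5, intensity_mean: 40, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # CH3 symmetric bending
      - {center: 1344, center_jitter_sd: 5, intensity_mean: 25, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # CH3 asymmetric bending
      - {center: 1470, center_jitter_sd: 5, intensity_mean: 20, intensity_rel_sd: 0.3, presence_prob: 1.0}
  - class_name: aromatic_carbonyl
    odor_label: sweet
    background_mode_count: 10
    background_intensity_scale: 2.0
    bands:
      # C=O stretch of aromatic ketones/esters, range 1750-1780 -> 1765 +- (5+15)
      - {center: 1765, center_jitter_sd: 20, intensity_mean: 80, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # aromatic ring C-C stretch
      - {center: 1600, center_jitter_sd: 10, intensity_mean: 60, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # out-of-plane aromatic C-H bend
      - {center: 750, center_jitter_sd: 10, intensity_mean: 70, intensity_rel_sd: 0.3, presence_prob: 1.0}
  - class_name: aliphatic_aldehyde
    odor_label: decayed
    background_mode_count: 10
    background_intensity_scale: 2.0
    bands:
      # dominant C=O stretch of linear aldehydes/acids
      - {center: 1800, center_jitter_sd: 8, intensity_mean: 200, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # CH2 scissoring (weak)
      - {center: 1465, center_jitter_sd: 8, intensity_mean: 15, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # CH3 umbrella bending (weak)
      - {center: 1380, center_jitter_sd: 8, intensity_mean: 10, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # chain rocking (weak, not always resolved)
      - {center: 720, center_jitter_sd: 8, intensity_mean: 8, intensity_rel_sd: 0.3, presence_prob: 0.8}
  - class_name: terpene
    odor_label: mixed
    background_mode_count: 12
    background_intensity_scale: 2.0
    bands:
      # out-of-plane =CH2 bend, range 900-950 -> 925 +- (5+25)
      - {center: 925, center_jitter_sd: 30, intensity_mean: 50, intensity_rel_sd: 0.3, presence_prob: 0.9}
      # CH2 twisting/wagging, broad range 1000-1400 -> 1200 +- (5+200)
      - {center: 1200, center_jitter_sd: 205, intensity_mean: 35, intensity_rel_sd: 0.3, presence_prob: 0.9}
      # in-plane CH2 scissoring, range 1450-1500 -> 1475 +- (5+25)
      - {center: 1475, center_jitter_sd: 30, intensity_mean: 40, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # C=C stretch, range 1650-1700 -> 1675 +- (5+25)
      - {center: 1675, center_jitter_sd: 30, intensity_mean: 45, intensity_rel_sd: 0.3, presence_prob: 0.9}
  - class_name: n_heterocycle
    odor_label: decayed
    background_mode_count: 10
    background_intensity_scale: 2.0
    bands:
      # dominant out-of-plane C-H bend of the fused ring
      - {center: 750, center_jitter_sd: 5, intensity_mean: 100, intensity_rel_sd: 0.3, presence_prob: 1.0}
      # ring C-C / C-N stretches, 1300-1550
      - {center: 1340, center_jitter_sd: 10, intensity_mean: 25, intensity_rel_sd: 0.3, presence_prob: 1.0}
      - {center: 1455, center_jitter_sd: 10, intensity_mean: 20, intensity_rel_sd: 0.3, presence_prob: 1.0}
      - {center: 1550, center_jitter_sd: 10, intensity_mean: 30, intensity_rel_sd: 0.3, presence_prob: 1.0}
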