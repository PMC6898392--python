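name: fafa-vs-control
arms:
- arm_id: fafa
  genotype: fa/fa
  diet: ad-libitum
  weeks:
  - 6
  - 15
  - 30
  - 46
  n_animals: 6
  glom_volume_trajectory:
    '6': 1467000.0
    '15': 2066000.0
    '30': 2834000.0
    '46': 3564000.0
  podocyte_number_start: 220.0
  podocyte_number_ref_week: 6
  podocyte_loss_slope: -1.49
  glepp1_fraction_trajectory:
    '6': 0.28
    '15': 0.25
    '30': 0.21
    '46': 0.17
  albumin_link:
    anchors:
    - - 45.0
      - 300.0
    - - 65.0
      - 100.0
    - - 82.0
      - 20.0
    - - 100.0
      - 10.0
    - - 150.0
      - 2.0
    - - 250.0
      - 0.5
    noise_sd: 0.25
  mrna_truth:
    trajectories:
      podocin:
        '6': 478928.57142857136
      nephrin:
        '6': 39910.71428571428
      aquaporin2:
        '6': 30000.0
    copies_per_podocyte: 50.0
    urine_recovery_fraction: 0.75
    podocin_linked_to_detachment: true
    noise_sd: 0.3
  hormone_truth:
    insulin:
      '6': 6.4
      '46': 6.4
    igf1:
      '6': 32.0
      '46': 32.0
    igf2:
      '6': 42.0
      '46': 42.0
    noise_sd: 0.1
  ps6_positive_fraction:
    '6': 0.4
    '15': 0.78
    '30': 0.78
    '46': 0.78
  sclerosis_density_threshold: 50.0
  sclerosis_span: 13.0
  collection_hours_mean: 17.0
  collection_hours_sd: 1.5
  urine_volume_ml_per_day: 15.0
  urine_glucose_mg_per_day: 5.0
  glomeruli_per_animal: 60000
  glomeruli_sampled_per_week: 60
  between_animal_cv: 0.15
  within_animal_volume_cv: 0.2
  glomerulus_density_cv: 0.15
  glepp1_profile_sd: 0.03
  nucleus_diameter_um: 6.5
  qpcr:
    slope: -3.3219
    intercept: 35.0
    cq_noise_sd: 0.15
    standard_copies:
    - 1000000.0
    - 100000.0
    - 10000.0
    - 1000.0
    - 100.0
    - 10.0
    standard_replicates: 2
    detection_cq_cutoff: 40.0
  seed: 0
- arm_id: control
  genotype: Fa/fa
  diet: ad-libitum
  weeks:
  - 6
  - 15
  - 30
  - 46
  n_animals: 6
  glom_volume_trajectory:
    '6': 917000.0
    '15': 1050000.0
    '30': 1150000.0
    '46': 1250000.0
  podocyte_number_start: 210.0
  podocyte_number_ref_week: 6
  podocyte_loss_slope: 0.0
  glepp1_fraction_trajectory:
    '6': 0.3
    '15': 0.3
    '30': 0.29
    '46': 0.29
  albumin_link:
    anchors:
    - - 65.0
      - 5.0
    - - 100.0
      - 0.8
    - - 150.0
      - 0.4
    - - 250.0
      - 0.2
    noise_sd: 0.25
  mrna_truth:
    trajectories:
      podocin:
        '6': 5442.370129870129
      nephrin:
        '6': 2721.1850649350645
      aquaporin2:
        '6': 30000.0
    copies_per_podocyte: 50.0
    urine_recovery_fraction: 0.75
    podocin_linked_to_detachment: false
    noise_sd: 0.3
  hormone_truth:
    insulin:
      '6': 1.0
      '46': 1.0
    igf1:
      '6': 10.0
      '46': 10.0
    igf2:
      '6': 20.0
      '46': 20.0
    noise_sd: 0.1
  ps6_positive_fraction:
    '6': 0.1
    '46': 0.1
  sclerosis_density_threshold: 50.0
  sclerosis_span: 13.0
  collection_hours_mean: 17.0
  collection_hours_sd: 1.5
  urine_volume_ml_per_day: 15.0
  urine_glucose_mg_per_day: 5.0
  glomeruli_per_animal: 60000
  glomeruli_sampled_per_week: 60
  between_animal_cv: 0.15
  within_animal_volume_cv: 0.2
  glomerulus_density_cv: 0.15
  glepp1_profile_sd: 0.03
  nucleus_diameter_um: 6.5
  qpcr:
    slope: -3.3219
    intercept: 35.0
    cq_noise_sd: 0.15
    standard_copies:
    - 1000000.0
    - 100000.0
    - 10000.0
    - 1000.0
    - 100.0
    - 10.0
    standard_replicates: 2
    detection_cq_cutoff: 40.0
  seed: 1
profiles_per_animal: 40
section_thickness_um: 1.5
pixel_size_um: 0.25
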