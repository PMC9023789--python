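# Four-group PBMC-like cohort preset: 12 / 26 / 14 / 14 samples, k = 12
# subtypes collapsible to 2 lineages via pbmc_hierarchy.csv.
#
# Alpha values are artifact choices (a lymphoid-dominant base composition
# mixed toward uniform by 0 / 5 / 10 / 45 percent with total concentration
# 80); they are NOT estimated from any dataset. The extreme_old group is
# deliberately the most even, so it has the highest expected diversity.
panel:
  [CD4_T, CD8_T, MAIT, gdT, NK, B_naive, B_memory, Plasma,
   CD14_Mono, CD16_Mono, cDC, pDC]
cells_per_sample: [300, 1500]
seed: 0
groups:
  - label: younger
    n_samples: 12
    alpha: [25.6, 13.6, 1.6, 1.6, 5.6, 4.8, 2.4, 0.8, 17.6, 3.2, 2.4, 0.8]
  - label: middle
    n_samples: 26
    alpha: [24.653, 13.253, 1.853, 1.853, 5.653, 4.893, 2.613, 1.093,
            17.053, 3.373, 2.613, 1.093]
  - label: older
    n_samples: 14
    alpha: [23.707, 12.907, 2.107, 2.107, 5.707, 4.987, 2.827, 1.387,
            16.507, 3.547, 2.827, 1.387]
  - label: extreme_old
    n_samples: 14
    alpha: [17.08, 10.48, 3.88, 3.88, 6.08, 5.64, 4.32, 3.44,
            12.68, 4.76, 4.32, 3.44]
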