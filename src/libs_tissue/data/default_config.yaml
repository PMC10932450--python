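version: 1
grid:
  lo_nm: 500.0
  hi_nm: 850.0
  step_nm: 0.1
catalog:
  bins:
  - label: Ca_547.89
    element: Ca
    center_nm: 547.89
    lo_nm: 546.89
    hi_nm: 548.89
  - label: Ca_554.52
    element: Ca
    center_nm: 554.52
    lo_nm: 553.52
    hi_nm: 555.52
  - label: Ca_560.01
    element: Ca
    center_nm: 560.01
    lo_nm: 559.01
    hi_nm: 561.01
  - label: Ca_596.05
    element: Ca
    center_nm: 596.05
    lo_nm: 595.05
    hi_nm: 597.05
  - label: Ca_604.21
    element: Ca
    center_nm: 604.21
    lo_nm: 603.21
    hi_nm: 605.21
  - label: Ca_610.08
    element: Ca
    center_nm: 610.08
    lo_nm: 609.08
    hi_nm: 611.08
  - label: Ca_616.66
    element: Ca
    center_nm: 616.66
    lo_nm: 615.66
    hi_nm: 617.66
  - label: Ca_625.88
    element: Ca
    center_nm: 625.88
    lo_nm: 624.88
    hi_nm: 626.88
  - label: Ca_635.58
    element: Ca
    center_nm: 635.58
    lo_nm: 634.58
    hi_nm: 636.58
  - label: Ca_643.38
    element: Ca
    center_nm: 643.38
    lo_nm: 642.38
    hi_nm: 644.38
  - label: Ca_650.8
    element: Ca
    center_nm: 650.8
    lo_nm: 649.8
    hi_nm: 651.8
  - label: K_765.86
    element: K
    center_nm: 765.86
    lo_nm: 764.86
    hi_nm: 766.86
  - label: K_770.76
    element: K
    center_nm: 770.76
    lo_nm: 769.76
    hi_nm: 771.76
  - label: Na_589.14
    element: Na
    center_nm: 589.14
    lo_nm: 588.14
    hi_nm: 590.14
  - label: Na_819.42
    element: Na
    center_nm: 819.42
    lo_nm: 818.42
    hi_nm: 820.42
preprocess:
  baseline_percentile: 5.0
generator:
  line_fwhm_nm: 3.0
  baseline_au: 0.02
  noise_sd_au: 5.0e-05
  reference_peak_nm: 800.0
  reference_height_au: 1.0
  truncation_quantile: 0.975
  gain_log_sd: 0.3
  classes:
    fibrosis:
      ca:
        median: 4.973
        iqr: 8.369
      k:
        median: 3.339
        iqr: 1.31
      na:
        median: 6.0
        iqr: 1.8
    nerve:
      ca:
        median: 63.64
        iqr: 15.07
      k:
        median: 1.738
        iqr: 1.652
      na:
        median: 1.5
        iqr: 0.45
    tumor_stroma:
      ca:
        median: 30.04
        iqr: 40.46
      k:
        median: 5.669
        iqr: 2.812
      na:
        median: 2.0
        iqr: 0.6
    cell_rich_tumor:
      ca:
        median: 1.974
        iqr: 6.47
      k:
        median: 6.498
        iqr: 1.75
      na:
        median: 6.0
        iqr: 1.8
    healthy_bone_ref:
      ca:
        median: 80.0
        iqr: 24.0
      k:
        median: 1.0
        iqr: 0.3
      na:
        median: 1.5
        iqr: 0.45
    tumor_ref:
      ca:
        median: 2.0
        iqr: 0.6
      k:
        median: 7.0
        iqr: 2.1
      na:
        median: 6.0
        iqr: 1.8
  weights: {}
counts:
  fibrosis: 254
  nerve: 516
  tumor_stroma: 821
  cell_rich_tumor: 1458
pca:
  reference_count: 50
  representative_k: 50
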