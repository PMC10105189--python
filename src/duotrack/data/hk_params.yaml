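# Calibrated Hong Kong parameterization (2009-2019 horizon).
# baseline_hi is deliberately absent: the 2009 household-survey penetration is
# not part of the published point estimates and must be supplied by the user
# (or recovered from a ReferenceSeries with duotrack.calibrate.fit_baseline_hi).
scalar:
  use_hi: 0.57
  selfpay: 0.06
  severity_ftr: 0.39          # calibrated; literature value before calibration was 0.4
  occu_dmd: 0.5               # calibrated; literature value before calibration was 1.3351
  tax_dmd: 0.13846153846153847   # 0.036 / 0.26
  baseline_diff: 0.055
  delay_duration: 365.0
  surge_peak_ratio: 1.196
tax_policy:
  tax_inct: 8000.0
  avg_prm_ratio: 0.85
  tax_rate: 0.06
  avg_tax: 2876.0
  start_date: 2019-04-01
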