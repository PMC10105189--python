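# Monte-Carlo sensitivity design for the Hong Kong run: Beta distributions for
# the [0,1]-bounded behavioural fractions, Normal for the unbounded occupancy
# elasticity.  Ranges are +/-10% around the point estimate (mean +/- 2 sd).
n_runs: 500
seed: 1234
beta:
  use_hi: {alpha: 171.43, beta: 129.324}
  selfpay: {alpha: 375.94, beta: 5889.73}
  tax_dmd: {alpha: 36.547, beta: 228.285}
  severity_ftr: {alpha: 243.61, beta: 381.031}
normal:
  occu_dmd: {mu: 0.5, sigma: 0.025}
ranges:
  use_hi: {mean: 0.57, lo: 0.513, hi: 0.627}
  selfpay: {mean: 0.06, lo: 0.054, hi: 0.066}
  tax_dmd: {mean: 0.13846153846153847, lo: 0.09615384615384616, hi: 0.18076923076923077}
  severity_ftr: {mean: 0.39, lo: 0.351, hi: 0.429}
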