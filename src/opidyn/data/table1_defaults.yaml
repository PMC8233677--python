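# National point estimates for the Iranian opium-dependence treatment
# model, 2019 baseline.  Probabilities are annual and on the percent
# scale.  theta_* are entry shares into each treatment group, b_* one-year
# maintenance retention, psi_* month-12 abstinence (treatment success),
# k_* annual death probability, gamma_w the untreated -> heroin transition.
# Discontinuation probabilities (phi_*) are derived at load time from the
# outflow closure and are therefore not listed.
prevalence: 2.06
pop: 1180553
theta_m: 20.71
theta_b: 5.37
theta_d: 2.42
theta_w: 71.50
b_m: 33.3
b_b: 30.0
psi_m: 27.0
psi_b: 26.0
psi_d: 10.0
psi_w: 1.0
k_m: 0.77
k_b: 0.39
k_d: 0.53
k_w: 2.91
gamma_w: 1.50
# Demographic growth of the dependent population: constant annual rate
# calibrated so that 29 annual increments compound to 28.93% total growth.
beta:
  total_percent: 28.93
  steps: 29
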