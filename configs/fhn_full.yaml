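# Stochastic FitzHugh-Nagumo study, full scale.
# Drift (theta1 (x1 - x1^3 - x2), theta2 x1 - x2 + theta3);
# Y_t | X_t ~ N2(X_t, theta4 I); data simulated at level 10.
model: fhn
theta_true: [0.89, 0.98, 0.5, 0.79]
sigma: [0.2, 0.4]
x0: [0.0, 0.0]
n_observations: 500
sim_level: 10
# The unit-step (level-0) Euler map of the cubic drift is unstable: a
# simulated level-0 prior path explodes with high probability.  All FHN
# chains therefore run with base level 1: increments start at level 2
# (coarse side >= 1) and truncated level pmfs are shifted accordingly.
base_level: 1
experiments:
  bias_sweep:
    truncation_levels: [2, 3, 4, 5, 6, 7]
    replicates: 1000
    reference:   # no closed form; high-level estimate stands in
      truncation_level: 10
      replicates: 10000
  variance_sweep:
    levels: [2, 3, 4, 5, 6]
    replicates: 1000
  sgd:
    theta_init: [0.8, 0.8, 0.8, 0.8]
    learning_rate: 0.001
    replicates: 2000
    truncation_level: 8
  newton:
    theta_init: [0.8, 0.8, 0.8, 0.8]
    variant: modified
    replicates: 2000
    truncation_level: 8
estimator:
  particles: 128
  m_star: 2
  coupling: maximal
seed: 2023
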