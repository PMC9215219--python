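# Bivariate Ornstein-Uhlenbeck study, full scale.
# Drift (theta1 - theta2 x1, -theta3 x2); Y_t | X_t ~ N2(X_t, theta4 I).
model: mvou
theta_true: [0.48, 0.78, 0.37, 0.32]
sigma: [0.8, 0.6]
x0: [1.0, 1.0]
n_observations: 500
sim_level: 10
experiments:
  bias_sweep:
    truncation_levels: [2, 3, 4, 5, 6]
    replicates: 10000
  variance_sweep:
    levels: [1, 2, 3, 4, 5, 6]
    replicates: 1000
  sgd:
    theta_init: [0.1, 0.1, 0.1, 0.1]
    learning_rate: 0.005
    replicates: 2000
    truncation_level: 8
  newton:
    theta_init: [0.1, 0.1, 0.1, 0.1]
    variant: modified
    replicates: 2000
    truncation_level: 8
estimator:
  particles: 128
  m_star: 2
  coupling: maximal
seed: 2023
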