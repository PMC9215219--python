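# Univariate Ornstein-Uhlenbeck study, full scale.
# dX = -theta1 X dt + sigma dW, Y_t | X_t ~ N(X_t, theta2).
model: ou
theta_true: [0.46, 0.38]
sigma: 1.0
x0: 1.0
n_observations: 500
sim_level: 10
experiments:
  bias_sweep:
    truncation_levels: [2, 3, 4, 5, 6, 7]
    replicates: 10000
  variance_sweep:
    levels: [1, 2, 3, 4, 5, 6]
    replicates: 1000
  hessian_surface:
    truncation_level: 8
    replicates: 10000
    theta_grid: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  sgd:
    theta_init: [0.1, 0.1]
    learning_rate: 0.002
  newton:
    theta_init: [0.1, 0.1]
estimator:
  particles: 128
  m_star: 2
  coupling: maximal
seed: 2023
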