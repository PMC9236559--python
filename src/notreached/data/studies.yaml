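# Simulation-study condition presets.
# rho: correlation of (theta_h, theta_d); dropout levels map to
# (eta0, eta1) = low (1, -0.7), medium (1, -0.32), high (1, -0.18).
I:
  - {N: 500, J: 30, K: 5, rho: -0.3, dropout_level: medium}
  - {N: 1000, J: 30, K: 5, rho: -0.3, dropout_level: medium}
  - {N: 500, J: 20, K: 5, rho: -0.3, dropout_level: medium}
II:
  - {N: 500, J: 20, K: 5, rho: -0.3, dropout_level: medium}
  - {N: 500, J: 20, K: 3, rho: -0.3, dropout_level: medium}
III:
  - {N: 500, J: 30, K: 5, rho: 0.0, dropout_level: low}
  - {N: 500, J: 30, K: 5, rho: -0.5, dropout_level: low}
  - {N: 500, J: 30, K: 5, rho: -0.8, dropout_level: low}
  - {N: 500, J: 30, K: 5, rho: 0.0, dropout_level: medium}
  - {N: 500, J: 30, K: 5, rho: -0.5, dropout_level: medium}
  - {N: 500, J: 30, K: 5, rho: -0.8, dropout_level: medium}
  - {N: 500, J: 30, K: 5, rho: 0.0, dropout_level: high}
  - {N: 500, J: 30, K: 5, rho: -0.5, dropout_level: high}
  - {N: 500, J: 30, K: 5, rho: -0.8, dropout_level: high}
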