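# Full factorial design grid at full scale (360 cells).
# Expect a long run: 1000 replicates x 100 imputations per cell.
rho_yz: [0.1, 0.3, 0.5, 0.7]
outcome_mech: [1, 2, 3]
aux_mech: [1, 2, 3]
pi_z: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
n: 1000
n_sim: 1000
m: 100
burnin: 10
seed: 1
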