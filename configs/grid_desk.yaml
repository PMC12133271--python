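# Desk-scale slice of the design grid: all nine mechanism pairs, two
# auxiliary strengths, four missingness proportions, reduced Monte Carlo
# size (minutes, not days). Monte Carlo SEs in the output make the reduced
# precision explicit.
rho_yz: [0.3, 0.7]
outcome_mech: [1, 2, 3]
aux_mech: [1, 2, 3]
pi_z: [0.0, 0.3, 0.6, 0.9]
n: 1000
n_sim: 150
m: 20
burnin: 10
seed: 1
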