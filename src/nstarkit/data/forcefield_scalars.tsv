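# nstarkit force-field scalar parameters v1
# units: k kcal/mol/A^2, lengths A, eps kcal/mol
# sha256: 7332578e4841c1e79eeacb4c8af700f22e280c9272acbf4798d313856d4015b5
fene_k 20.0
fene_R0 2.0
bb_bond 3.8
bb_sigma 3.8
eps_bb 0.12
eps_bs 0.18
eps_exv 1.0
dielectric 78.0
debye_length 10.0
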