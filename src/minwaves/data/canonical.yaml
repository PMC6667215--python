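omega_D: 0.1
omega_dD: 5.0
omega_E: 0.1
omega_ed: 100.0
omega_e: 1.0
D_bulk: 100.0
D_mem: 1.0
ce0: 0.0
lam: 1.0
D0: 0.5
eps0: 0.8
model_variant: II
saturation: false
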