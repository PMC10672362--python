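name: chicken_skin
delta_z_um: 4.78
delta_x_um: 2.5
omega_z_um: 14.34
omega_x_um: 4.14
n_spectral: 844
n_fft: 1024
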