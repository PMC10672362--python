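name: retina
delta_z_um: 3.75
delta_x_um: 9.0
omega_z_um: 11.25
omega_x_um: 18.0
n_spectral: 1024
n_fft: 2048
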