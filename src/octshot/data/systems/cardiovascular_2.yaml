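# Clinical intravascular system; 1024 A-lines per rotation.
name: cardiovascular_2
delta_z_um: 4.43
delta_x_um: 24.4
omega_z_um: 13.29
omega_x_um: 30.0
n_spectral: 800
n_fft: 1024
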