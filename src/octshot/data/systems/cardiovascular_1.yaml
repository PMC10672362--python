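# Catheter-based intravascular system (in-house built).
name: cardiovascular_1
delta_z_um: 4.84
delta_x_um: 12.2
omega_z_um: 14.52
omega_x_um: 30.0
n_spectral: 768
n_fft: 1024
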