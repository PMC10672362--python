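# Swept-source bench system used for chicken muscle and blueberry samples.
name: chicken
delta_z_um: 6.0
delta_x_um: 3.06
omega_z_um: 18.0   # axial effective width; 3 axial pixels per speckle grain
omega_x_um: 8.28
n_spectral: 1600
n_fft: 2048
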