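# Water-box benchmark: 30x15x15 cm^3 phantom, 5-cm spherical target at
# 7.5 cm depth, single field, illustrative neutron model parameters.
[phantom]
kind = "water_box"
spacing = 0.25

[plan]
prescription = 36.0
modulation = "auto"
aperture_pixel = 0.1

[output]
isodose_levels = [0.3, 0.5, 1.0, 50.0, 95.0]
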