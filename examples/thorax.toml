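# Thorax-like heterogeneous phantom: anterior-posterior field on a
# mediastinal target, lungs at density 0.26, out-of-field thyroid.
[phantom]
kind = "thorax"
spacing = 0.4

[plan]
prescription = 36.0

[neutron]
hd_iso = 5.09
total_field_radius = 10.0
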