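# Illustrative, NON-CLINICAL neutron source-model parameters.
#
# These values are a physically plausible stand-in so that the full pipeline
# runs out of the box: high-energy intranuclear-cascade neutrons penetrating
# and forward-peaked, evaporation neutrons intermediate, epithermal and
# thermal neutrons strongly attenuated and laterally broad.  For clinical
# use, replace every value in [model] and [components.*] with a fitted set
# for your treatment head (and optionally supply a [spectrum] table of
# per-energy-bin hd_iso_j values instead of model.hd_iso).

[model]
hd_iso = 3.68            # mSv/Gy at isocenter (plan-level)
p = 1.3                  # power-law divergence exponent
d_iso = 33.0             # cm, virtual source to isocenter (geometric)
# dprime_iso omitted: computed per plan by ray tracing source -> isocenter
field_size_factor = 1.0  # dimensionless, in [0, 1]

[components."intranuclear-cascade"]
C = 0.72
alpha = 0.03             # 1/cm water-equivalent
sigma = 18.0             # cm at the isocenter plane

[components.evaporation]
C = 0.20
alpha = 0.08
sigma = 28.0

[components.epithermal]
C = 0.05
alpha = 0.11
sigma = 40.0

[components.thermal]
C = 0.03
alpha = 0.14
sigma = 55.0
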