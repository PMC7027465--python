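# Example desk-scale run configuration for `fragsim run`.

[rates]
# defaults shown explicitly; any field of RateConstants can be overridden
patch_birth_rate = 4e-4
particle_production_rate = 0.5
immigration_rate = 1e-3

[scenario]
S = 32
delta = 1.0
dispersal_mode = "passive"
T = 200.0

[landscape]
V = 50.0

[census]
tau = 1.0
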