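# Default parameter sets for the four switch architectures.
#
# Copy-number units: molecules (dissociation constants included); time unit
# set by the mRNA decay rate beta = 1.  The sequestration-family constants
# were calibrated once against the effective Hill coefficients reported for
# these switch designs (about 1.3 and 3 for the cooperative model without
# and with cooperativity, about 50 for sequestration and
# sequestration+blocking, about 2 for the weak activator, about 200 for the
# triple switch) and are fixed; see docs/methods.md for the procedure.

[defaults]
alpha = 50.0   # mRNA transcription rate from an active promoter (1/time)
beta = 1.0     # mRNA decay rate; defines the time unit
k_on = 1.0     # shared association rate constant (1/(molecule*time))

[cooperative_binding]
K_r = 2000.0   # first-site repressor-DNA dissociation constant (molecules)
c = 0.01       # cooperativity factor; c = 1 means independent sites
R_T = 20

[cooperative_binding.variants.no_cooperativity]
c = 1.0

[sequestration]
# strong activator: tight DNA binding (K_a/A_T = 5e-3)
A_T = 100
R_T = 100
K_a = 0.5
K_s = 0.0025

[sequestration.variants.weak_activator]
K_a = 10.0

[sequestration_blocking]
A_T = 100
R_T = 100
K_a = 0.5
K_s = 0.0025
K_b = 1.0

[sequestration_blocking_displacement]
A_T = 100
R_T = 100
K_a = 0.1
K_s = 0.00025
K_b = 0.1
K_d = 1000.0

[turnover]
# birth-death of the repressor; r_prod is set at run time to r_deg * R_T so
# the stationary mean matches the fixed-R_T counterpart.  The default decay
# is slow relative to mRNA turnover (stable protein), keeping the total
# repressor pool in the slowly-fluctuating regime.
r_deg = 0.01
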