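# In-vitro-shaped preset: recruitment-index tracking with a current
# actuator (amperes, bounds +/-0.95 mA), exercised against the simulated
# plant as a smoke test.  The chamber constants are synthetic stand-ins
# chosen so the current bound maps to the 4 V/cm field bound.
name = "invitro_nn"

[plant]
s = 3.0
tau = 4.0
nu = 1
ef_max = 4.0
composition = "bias_inv_s"

[reference]
kind = "square"
observable = "recruitment_index"
high = 60.0
low = -60.0

[actuator]
cross_section_cm2 = 0.025
conductivity_S_per_cm = 0.0095

[controller.nn]
gamma = 0.00009
gamma_a = 0.00009
gamma_b = 0.00009
alpha_a = 0.4
alpha_b = 0.4
UL = 0.00095
LL = -0.00095
Ts = 300.0
m = 101
n = 6
center_lo = -5.0
center_hi = 5.0
center_step = 0.1
beta = 1.0
weight_scale = 1e-5
regressor_scheme = "ry_interleaved"
# Percent-scale signals divided by 150 land inside the [-5, 5] center grid.
regressor_scale = 0.006666666666666667

[run]
horizon = 144
n_cells = 100
compare_laws = false
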