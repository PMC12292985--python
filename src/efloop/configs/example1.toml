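# In-silico Example 1: non-saturating square-wave reference (+/-0.65).
name = "example1"

[plant]
s = 3.0
tau = 4.0
nu = 1
ef_max = 4.0
composition = "bias_inv_s"

[reference]
kind = "square"
observable = "directedness"
high = 0.65
low = -0.65

[controller.nn]
gamma = 0.0005
gamma_a = 0.0015
gamma_b = 0.006
alpha_a = 0.1
alpha_b = 0.4
UL = 4.0
LL = -4.0
Ts = 1.0
m = 201
n = 6
center_lo = 0.0
center_hi = 2.0
center_step = 0.01
beta = 1.0
weight_scale = 1e-4
regressor_scheme = "r_y5"
regressor_scale = 1.0
regressor_offset = 1.0

[run]
horizon = 3600
n_cells = 100
compare_laws = true
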