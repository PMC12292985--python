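# PID baseline for the in-vitro-shaped experiment.  Gains are documented
# placeholders (none were published): they track the first setpoint and
# wind up on the reversal.
name = "invitro_pid"

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

[controller.pid]
kp = 8e-6
ki = 1e-9
kd = 0.0
UL = 0.00095
LL = -0.00095
Ts = 300.0

[run]
horizon = 144
n_cells = 100
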