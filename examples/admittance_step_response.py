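"""Step response of the discrete admittance controller.

A constant 50 mN push on the virtual mass-damper (F = m a + c v) should
accelerate the exoskeleton along v(t) = (F/c)(1 - exp(-c t / m)) toward
F/c, and a hard shove must saturate at the 16 cm/s forward safety limit.
"""

import numpy as np

from exotwin import AdmittanceParams, ControllerState, admittance_step

params = AdmittanceParams()
m, c = params.virtual_mass[0], params.virtual_damping[0]
F = 0.05  # N

state = ControllerState()
for k in range(int(5 * m / c / params.cycle_time)):
    state = admittance_step([F, 0, 0], state, params)

v_closed_form = (F / c) * (1 - np.exp(-c * (5 * m / c) / m))
print(f"virtual mass {m} kg, damping {c} N·s/m, push {F*1000:.0f} mN")
print(f"simulated velocity after 5 time constants: {state.velocity[0]*100:.2f} cm/s")
print(f"first-order closed form:                  {v_closed_form*100:.2f} cm/s")

state = ControllerState()
for _ in range(1000):
    state = admittance_step([1.0, 0, 0], state, params)
print(f"sustained 1 N push saturates at {state.velocity[0]*100:.0f} cm/s "
      "(the forward velocity limit)")
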