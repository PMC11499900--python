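"""Bench presets: flow cases, Windkessel loads, illumination settings.

The idealized-phantom experiments run three scaled versions of the same
physiological pulse — high (FH), medium (FM) and low (FL) amplitude — each
with its own 3-element Windkessel outlet load.  Velocities are section-mean
values in the 20 mm parent vessel; resistances in kg m^-4 s^-1, capacitance
in m^4 s^2 kg^-1.
"""

from __future__ import annotations

# Parent vessel / cycle defaults (idealized model)
PARENT_DIAMETER_MM = 20.0
CYCLE_PERIOD_S = 0.8
KINEMATIC_VISCOSITY_MM2S = 3.82
BLOOD_ANALOG_DENSITY = 1060.0  # kg/m^3, blood-matched analog
SYSTOLIC_PEAK_S = 0.12
PIXEL_SCALE_IDEALIZED = 24.6  # px/mm
PIXEL_SCALE_PATIENT = 41.6  # px/mm
PAIRS_PER_CYCLE = 25

#: Flow-case table: Windkessel load + target section-mean velocities (m/s).
FLOW_CASES: dict[str, dict[str, float]] = {
    "FL": dict(Rp=1.5e7, C=4e-9, Rd=9e8, u_max=0.26, u_mean=0.06),
    "FM": dict(Rp=1.5e7, C=6e-9, Rd=4.5e8, u_max=0.44, u_mean=0.09),
    "FH": dict(Rp=1.2e7, C=8e-9, Rd=4e8, u_max=0.54, u_mean=0.11),
}

#: Pulsed-LED double-exposure settings: pulse width tau and separation dt, us.
ILLUMINATION_CONFIGS: dict[str, dict[str, float]] = {
    "C1": dict(tau_us=10.0, dt_us=200.0),
    "C2": dict(tau_us=10.0, dt_us=400.0),
    "C3": dict(tau_us=20.0, dt_us=200.0),
    "C4": dict(tau_us=20.0, dt_us=400.0),
}
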