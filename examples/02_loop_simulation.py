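"""Simulate the hybrid mock circulatory loop for the low-amplitude case.

The pump drives the compliant phantom; the outlet chamber's pressure
setpoint follows a 3-element Windkessel model and is tracked by the PID
pneumatic actuator.  Prints the chamber-pressure range, the flowmeter
delay recovered from the logged channels and the peak inlet/outlet flow
imbalance caused by the phantom's compliance.
"""

import numpy as np

from aaapiv import (
    CompliantSegment,
    WindkesselParams,
    flow_balance,
    physiological_waveform,
    run_loop,
)
from aaapiv.metrics import M3S_TO_LMIN

wave = physiological_waveform("FL")
q_mean = float(np.mean(wave.flows))

# ground pressure tuned so the chamber works in the 0-40 mmHg bench range
case = WindkesselParams.from_case("FL")
p0 = -q_mean * (case.Rp + case.Rd) + 2666.0
wk = WindkesselParams(Rp=case.Rp, Rd=case.Rd, C=case.C, P0=p0)

log = run_loop(
    wave, wk,
    seg=CompliantSegment(C_ph=2e-9),
    n_cycles=8, seed=0,
    pc0=p0 + q_mean * wk.Rd,  # start at the settled Windkessel state
)

print(f"sampling rate        : {log.fs:.0f} Hz")
print(f"chamber pressure     : {log.p_chamber.min():.0f} .. "
      f"{log.p_chamber.max():.0f} Pa "
      f"({log.p_chamber.max() / 133.3:.1f} mmHg peak)")

q_true = log.metadata["q_in_true"]
lags = np.arange(250)
xc = [np.corrcoef(log.q_in, np.roll(q_true, k))[0, 1] for k in lags]
print(f"flowmeter delay      : {lags[int(np.argmax(xc))] / log.fs * 1e3:.1f} ms"
      " (recovered by cross-correlation; 23 ms configured)")

_, dq_mean, _ = flow_balance(log, wave.period, lowpass_hz=None)
print(f"peak |dQ| (in - out) : {np.max(np.abs(dq_mean)) * M3S_TO_LMIN:.2f} L/min")
print(
    "\nThe flow imbalance is the volume the compliant wall stores and"
    " releases each cycle (C_ph dP/dt); a rigid phantom would give zero."
)
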