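"""Render synthetic particle images of pulsatile flow and run the PIV chain.

Generates five double-exposure pairs of the high-amplitude Womersley flow
in the inlet region (C4 illumination: 20 us pulses, 400 us apart), runs
background subtraction, CLAHE, 3-pass FFT correlation with window
deformation and the three-criterion validation, and compares the
reconstructed flow rate with the generator's waveform.
"""

import numpy as np

from aaapiv.metrics import M3S_TO_LMIN
from aaapiv.workflows import run_roi1_case

result = run_roi1_case("FH", "C4", seed=7, phases=[2, 4, 6, 10, 16])

print(f"{'t (s)':>6} {'Q_true':>8} {'Q_piv':>8} {'err':>6}  {'invalid':>7}")
for t, q_t, q_p, rate in zip(result.times_s, result.q_true_m3s,
                             result.q_piv_m3s, result.invalid_rates):
    print(f"{t:6.3f} {q_t * M3S_TO_LMIN:8.2f} {q_p * M3S_TO_LMIN:8.2f} "
          f"{(q_p - q_t) * M3S_TO_LMIN:6.2f}  {100 * rate:6.2f}%")

peak = result.fields[int(np.argmax(result.q_true_m3s))]
print(f"\nflow rates in L/min; grid {peak.u_px.shape[0]}x{peak.u_px.shape[1]}"
      f" vectors, {np.diff(peak.x_px)[0]} px spacing")
print(f"max |Q error| {result.max_q_error_lmin:.2f} L/min; "
      f"mean invalid rate {100 * result.mean_invalid_rate:.2f}%")
print(
    "\nQ_piv is the axisymmetric integral 2*pi*int(u r dr) of the"
    " band-averaged axial profile 8-12 mm into the region of interest;"
    " the error against the imposed waveform is the end-to-end accuracy"
    " of the whole imaging + correlation chain."
)
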