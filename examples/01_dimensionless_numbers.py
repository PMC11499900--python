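"""Flow cases of the idealized aneurysm bench and their dimensionless numbers.

Builds the three scaled aortic pump waveforms (low, medium, high amplitude)
and prints peak/mean Reynolds and Womersley numbers for the 20 mm parent
vessel with the blood-analog fluid (nu = 3.82 mm^2/s, T = 0.8 s).
"""

from aaapiv import FluidProperties, dimensionless_numbers, physiological_waveform

fluid = FluidProperties()
print(f"{'case':>5} {'U_max':>7} {'<U>':>6} {'Re_max':>7} {'<Re>':>6} {'alpha':>6}")
for case in ("FL", "FM", "FH"):
    wave = physiological_waveform(case)
    dn = dimensionless_numbers(wave, d=0.02, fluid=fluid)
    print(f"{case:>5} {dn.u_max:7.2f} {dn.u_mean:6.2f} "
          f"{dn.re_max:7.0f} {dn.re_mean:6.0f} {dn.alpha:6.2f}")

print(
    "\nU in m/s.  Re_max > ~2000 for FM/FH marks transitional pulsatile flow"
    " in the bulge; alpha ~ 14 means inertia dominates viscosity over the"
    " cycle, so the velocity profile is plug-like with thin oscillating wall"
    " layers rather than parabolic."
)
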