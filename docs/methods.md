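# Methods

This note records the models, conventions and numerical choices behind
`aaapiv`, and what the synthetic experiments do and do not establish.

## Geometry

The idealized aneurysm lumen is axisymmetric: a raised-cosine bulge
`Γ(x) = d*·cos(πx/(2x*)) + d/2` for `|x| ≤ x*`, parent radius `d/2`
elsewhere, with `x* = (L/d)·d/2` and `d* = (D/d − 1)·d/2`. Defaults
`d = 20 mm`, `L/d = 2.9`, `D/d = 1.9`, total length 250 mm, wall
thickness 1.8 mm (the wall is used only to render optical artifacts,
never by the flow analysis). Axial coordinate in mm, origin at the bulge
center; image columns map to x, rows to the transverse coordinate, pixel
centers at half-integer positions. The rasterized lumen mask matches the
analytic diameter within 1 px at every column (tested against direct
evaluation of Γ).

## Flow representation and dimensionless numbers

A waveform is uniform samples over one period T plus a truncated Fourier
series (12 harmonics by default; the relative RMS truncation error is
exposed as `FlowWaveform.truncation_error()`, ~0.5 % for the default
pulse). Dimensionless numbers use the section-mean velocity
`U = Q/(πd²/4)`:

    Re_max = U_max d/ν,  ⟨Re⟩ = ⟨U⟩ d/ν,  α = (d/2)·√(2π/(T ν))

with ν = 3.82 mm²/s, T = 0.8 s, d = 20 mm by default (α = 14.34). The
mean uses |Q| because brief valve regurgitation would otherwise cancel
forward flow; a signed mean is available (`signed_mean=True`).

The pump shape is a sin² systolic pulse peaking at 0.12 s, a small
regurgitation dip (8 % of the pulse amplitude over 0.1 s) and a constant
diastolic baseline. Pulse amplitude and baseline are solved numerically
so that U_max and ⟨U⟩ hit each flow case's targets exactly: FL
(0.26/0.06 m/s), FM (0.44/0.09), FH (0.54/0.11). The echo-derived pulse
shape of the original bench is not public; this parameterization
reproduces its amplitude scaling and timing landmarks.

## Womersley reference flow

Per harmonic n of the flow waveform, the rigid-tube solution

    u_n(r) = (c_n/πR²) · (1 − J₀(β_n r/R)/J₀(β_n)) /
             (1 − 2J₁(β_n)/(β_n J₀(β_n))),   β_n = i^{3/2} α_n

integrates over the cross-section to exactly c_n; harmonic 0 contributes
the Poiseuille profile of the mean flow. The cross-sectional integral
reproduces Q(t) to < 0.1 % with ≥ 10 harmonics (tested by quadrature).
The field sampler used for particle advection evaluates the radius as
r = √(y² + z²) including the light-sheet depth z, so tracers off the
mid-plane move slightly slower than the mid-plane ground truth — a real
depth-averaging effect of planar PIV.

## Loop simulator

Explicit trapezoidal (Heun) update of the Windkessel capacitor at the
5 kHz logging rate; a guard rejects dt ≥ RdC/2 (the bench loads have
RdC ≈ 2.7–3.6 s, so 0.2 ms is deep in the accurate regime: < 0.1 % error
vs the closed-form exponential). The pneumatic chamber is a rate-limited
integrator driven by a PID controller (defaults kp = 500 s⁻¹,
ki = 5000 s⁻², kd = 0, slew ±2·10⁵ Pa/s) with conditional-integration
anti-windup. The supply lines set the actuator's slew capability rather
than hard pressure clamps; with the published resistances the steady mean
pressure is ⟨Q⟩(Rp+Rd), so the ground pressure P0 must offset it to keep
the chamber in the 0–40 mmHg bench range — P0 is exposed in the config
and the range is a tuning check, not an assertion (the bench's P0 values
are not public).

The compliant segment stores volume at C_ph·dP/dt (default
C_ph = 2·10⁻⁹ m⁴s²/kg) and strains as δ = (P − P_dia)/Ep (default
Ep = 3·10⁵ N/m², inside the reported aortic-distensibility range). The
pressure derivative driving the compliance is first-order low-pass
filtered (τ = 5 ms): the raw per-sample difference of a PID-actuated
pressure is actuator chatter that a fluid column cannot follow, and
feeding it back unfiltered couples into the setpoint with gain
Rp·C_ph/dt ≈ 150 and destabilizes the loop.

Flow channels are logged with the ultrasonic-flowmeter delay (default
23 ms, calibrated bench range 20–26 ms) applied to inlet and outlets
alike, so the flow balance ΔQ needs no relative shift; `flow_balance`
accepts a delay argument for asymmetric channel pairs. The sensor
low-pass default is 25 Hz (the nominal 25 kHz figure exceeds the 2.5 kHz
Nyquist limit of the 5 kHz logs and is treated as a typo). Windkessel
parameter recovery by least squares (log-parameter Levenberg–Marquardt
on the simulated setpoint law) recovers (Rp, Rd, C) within 5 % at 30 dB
SNR (tested).

## Synthetic imaging

Tracers (10 µm hollow glass spheres) are seeded Poisson-uniformly over
the lumen mask at 7 particles/mm² — ≈ 12 per final 32×32 px window,
standard PIV practice; the bench's density is not public — with uniform
depth across a 1.5 mm light sheet. Advection is RK4. Each pulse renders
Gaussian spots (σ = 0.65 px, e⁻² diameter ≈ 2.6 px) with amplitude
proportional to pulse width (exposure linearity), Gaussian sheet-depth
weighting, and motion blur as three sub-exposures along the path covered
during τ. The background is a static offset + linear gradient (and an
optional wall-reflection band); noise is Poisson shot noise plus Gaussian
read noise (σ = 4 counts); values clip to the 12-bit range. Pairs are
phase-locked at 25 per 0.8 s cycle (32 ms interval; one printed source
says 31 ms, which is not commensurate with T/25 — 32 ms is used and the
interval is configurable). Ground truth is the mid-plane displacement
over the pulse separation, integrated on the PIV grid; it matches dense
re-integration within 10⁻³ px (tested).

What the generator does *not* emulate: refraction through the silicone
wall and index-matching fluid, out-of-plane secondary flow (available as
an optional uniform through-sheet drift, off by default for the
idealized case), cycle-to-cycle turbulence (only a lumped per-cycle gain
jitter), and camera fixed-pattern noise. Passing tests therefore
establish the correctness of the processing chain under controlled
conditions, not the full error budget of a physical experiment.

## PIV chain

Preprocessing order is fixed: mean-background subtraction (clipped at
zero) → 20th/99.5th-percentile rescale to [0,1] → CLAHE (clip 0.01, 8×8
tiles) → Gaussian blur (σ = 1 px). The background defaults to the stack
mean — correct for long acquisitions where tracers wash out — and can be
supplied explicitly for short stacks whose frames share tracer positions
(subtracting such a stack's own mean removes half the particle signal;
the illumination-comparison workflow estimates its background from
independently seeded renders instead).

Correlation: three passes, 128/64/32 px windows at 50 % overlap. Each
pass warps frame B by the previous pass's validated field (bilinear dense
predictor, bicubic image interpolation) and measures the residual on
zero-mean unweighted windows via FFT cross-correlation; sub-pixel peak by
a three-point Gaussian fit per axis; SNR is first-to-second correlation
peak. Windows with more than 50 % masked pixels emit no vector; windows
that merely touch the mask boundary are emitted but flagged `boundary`:
their correlation averages tracer motion across the wall layer and the
masked band, a particle-weighted mixture rather than a point velocity,
with a bias that grows nonlinearly with pulse separation.

Validation (in the bench's three criteria): |component − mean| > 5σ
globally, normalized local-median residual > 3 (3×3 neighborhood,
0.1 px regularization), SNR < 1.25. Flagging and neighbor-mean
replacement iterate to a fixed point (≤ 10 sweeps), which makes the
operation idempotent; the reported invalid rate is the first-sweep
(pre-replacement) fraction. Replaced vectors are interpolated fills and
are excluded from ensemble statistics.

Wall segmentation uses an active contour on the smoothed, normalized
image. Tube-like contours (the idealized phantom crosses the whole
field of view) are split at the contour centroid into upper and lower
wall chains refined as open snakes with fixed endpoints — a periodic
snake cannot anchor where the lumen continues past the image border; a
`closed` mode keeps the single periodic snake. Convergence is judged on
the extracted widths (points may slide tangentially along a settled
edge); steps are capped at 0.2 px/iteration to avoid the ±1 px limit
cycle the default step produces on steep edges. Y(x) is the
max-minus-min row of the contour's crossings with a vertical line, and
δ(x,t) = (Y − Y(t₀))/Y(t₀)·100 % relative to the diastolic frame.

The flow-rate integral averages axial velocity over the 8–12 mm band of
the inlet ROI, folds the transverse profile about the axis (average of
the two half-profiles — the symmetric fold; an antisymmetric residue
signals broken axisymmetry and integrates to zero), closes it with the
no-slip point u(R) = 0 and applies trapezoidal quadrature of
2π∫u·r dr.

## Problem sizes

The synthetic experiments run on a 544×640 px crop of the 1920×1200
sensor covering the inlet region (26×22 mm at 24.6 px/mm) — the full
straight-tube segment the flow-rate band needs, at the bench's true
pixel scale. One cycle of 25 pairs per flow case feeds the
invalid-vector and flow-rate checks; the illumination comparison
phase-averages 12 phase-locked cycles per configuration (the bench
averaged 25). These sizes keep a complete run in the minutes range while
leaving every per-window computation identical to a full-frame run.

## Known limitations

- The loop couples pump, compliance and a single averaged chamber; two
  independent outlets with distinct Windkessel loads split the flow
  equally rather than by impedance.
- Wall-adjacent vectors carry the particle-weighted near-wall bias
  described above; the `boundary` flag marks them but no near-wall
  correction (window weighting, single-pixel ensemble correlation) is
  implemented.
- The active contour assumes a bright lumen on a dark exterior (or the
  reverse via `w_line`); heavy reflections beyond the rendered band are
  untested.
- The patient-specific phantom (tortuous geometry, out-of-plane flow,
  its own pixel scale) is outside the scope of the synthetic generator.
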