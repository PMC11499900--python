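"""Pulsatile flow waveforms, dimensionless numbers and the Womersley solution.

A periodic volumetric waveform Q(t) is represented by uniform samples over
one period together with a truncated Fourier series

    Q(t) = c0 + Re( sum_{n>=1} c_n exp(i n w t) ),   w = 2 pi / T.

Dimensionless numbers follow the usual pipe-flow definitions with the
section-mean velocity U = Q / (pi d^2 / 4):

    Re_max = U_max d / nu,   <Re> = <U> d / nu,
    alpha  = (d/2) sqrt(2 pi / (T nu)).

The rigid-tube Womersley solution gives the axial velocity profile driven
by each flow harmonic; the pressure-gradient amplitude of every harmonic is
chosen so that the cross-sectional integral of the profile reproduces that
harmonic of Q(t).  The zeroth harmonic contributes the Poiseuille profile
of the mean flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve
from scipy.special import jv

from . import presets

__all__ = [
    "FluidProperties",
    "FlowWaveform",
    "DimensionlessSummary",
    "fourier_decompose",
    "fourier_reconstruct",
    "dimensionless_numbers",
    "womersley_profile",
    "physiological_waveform",
]


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid properties (blood-matched water/glycerol/urea analog)."""

    kinematic_viscosity: float = presets.KINEMATIC_VISCOSITY_MM2S  # mm^2/s
    density: float = presets.BLOOD_ANALOG_DENSITY  # kg/m^3

    def __post_init__(self) -> None:
        if self.kinematic_viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def nu_m2s(self) -> float:
        return self.kinematic_viscosity * 1e-6


@dataclass
class FlowWaveform:
    """Periodic volumetric flow rate over one cycle.

    Attributes
    ----------
    period : float
        Cycle period T, s.
    times : ndarray
        Uniform sample times in [0, T), s.
    flows : ndarray
        Volumetric flow at ``times``, m^3/s.
    harmonics : ndarray, complex
        Fourier coefficients c_0..c_N (c_0 real, the mean flow).
    """

    period: float
    times: np.ndarray
    flows: np.ndarray
    harmonics: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_harmonics: int = 12

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.times.size < 3 or self.times.size != self.flows.size:
            raise ValueError("need matching time/flow samples (>= 3)")
        if np.any(self.times < 0) or np.any(self.times >= self.period):
            raise ValueError("sample times must lie in [0, T)")
        if self.harmonics is None:
            self.harmonics = fourier_decompose(
                self.times, self.flows, self.period, self.n_harmonics
            )

    def __call__(self, t) -> np.ndarray:
        """Evaluate the Fourier reconstruction of Q at time(s) ``t`` (s)."""
        return fourier_reconstruct(self.harmonics, self.period, t)

    @property
    def mean_flow(self) -> float:
        """Cycle-mean signed flow, m^3/s (the zeroth Fourier coefficient)."""
        return float(np.real(self.harmonics[0]))

    def truncation_error(self) -> float:
        """RMS error of the harmonic reconstruction at the sample points,
        relative to the RMS of the samples."""
        rec = self(self.times)
        denom = np.sqrt(np.mean(self.flows**2))
        if denom == 0:
            return 0.0
        return float(np.sqrt(np.mean((rec - self.flows) ** 2)) / denom)


@dataclass(frozen=True)
class DimensionlessSummary:
    """Peak/mean Reynolds and Womersley numbers for a flow case."""

    re_max: float
    re_mean: float
    alpha: float
    u_max: float  # m/s
    u_mean: float  # m/s
    d: float  # m

    def __post_init__(self) -> None:
        # the rectified-mean convention guarantees Re_mean >= 0; a signed
        # mean may sit at (numerically just below) zero for pure oscillation
        if self.re_max < self.re_mean:
            raise ValueError("require Re_max >= Re_mean")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def fourier_decompose(times, flows, period: float, n_harmonics: int) -> np.ndarray:
    """Truncated Fourier coefficients c_0..c_N of a periodic signal.

    Non-uniform samples are resampled onto a uniform grid by periodic
    linear interpolation before the FFT.  Requires at least
    ``2 n_harmonics + 1`` samples per period.
    """
    times = np.asarray(times, dtype=float)
    flows = np.asarray(flows, dtype=float)
    if times.size < 2 * n_harmonics + 1:
        raise ValueError(
            f"need >= {2 * n_harmonics + 1} samples for {n_harmonics} harmonics"
        )
    order = np.argsort(times)
    times, flows = times[order], flows[order]
    dt = np.diff(times)
    uniform = np.allclose(dt, dt[0], rtol=1e-6) and np.isclose(
        times[0] + period - times[-1], dt[0], rtol=1e-6
    )
    if not uniform:
        n = max(times.size, 4 * n_harmonics)
        tu = np.arange(n) * period / n
        tp = np.concatenate([times, times[:1] + period])
        fp = np.concatenate([flows, flows[:1]])
        flows = np.interp(tu, tp, fp)
    n = flows.size
    spec = np.fft.rfft(flows) / n
    coeffs = np.zeros(n_harmonics + 1, dtype=complex)
    coeffs[0] = spec[0].real
    upto = min(n_harmonics, spec.size - 1)
    coeffs[1 : upto + 1] = 2.0 * spec[1 : upto + 1]
    return coeffs


def fourier_reconstruct(harmonics, period: float, t) -> np.ndarray:
    """Evaluate Q(t) = c0 + Re(sum c_n e^{i n w t}) at time(s) t."""
    harmonics = np.asarray(harmonics, dtype=complex)
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / period
    n = np.arange(1, harmonics.size)
    phase = np.exp(1j * omega * np.multiply.outer(t, n))
    out = harmonics[0].real + np.real(phase @ harmonics[1:])
    return out if out.ndim else float(out)


def dimensionless_numbers(
    waveform: FlowWaveform,
    d: float,
    fluid: FluidProperties,
    signed_mean: bool = False,
) -> DimensionlessSummary:
    """Peak/mean Reynolds and Womersley numbers from a flow waveform.

    Parameters
    ----------
    waveform : FlowWaveform
    d : float
        Tube inner diameter, m.
    fluid : FluidProperties
    signed_mean : bool
        If False (default) the mean velocity uses |Q| — brief valve
        regurgitation would otherwise cancel forward flow in the average.
    """
    if d <= 0:
        raise ValueError("diameter must be positive (m)")
    area = np.pi * d**2 / 4.0
    u = waveform.flows / area
    if u.size == 0 or area == 0:
        raise ValueError("empty waveform or zero area")
    u_max = float(np.max(u))
    u_mean = float(np.mean(u if signed_mean else np.abs(u)))
    nu = fluid.nu_m2s
    alpha = (d / 2.0) * np.sqrt(2.0 * np.pi / (waveform.period * nu))
    return DimensionlessSummary(
        re_max=u_max * d / nu,
        re_mean=u_mean * d / nu,
        alpha=float(alpha),
        u_max=u_max,
        u_mean=u_mean,
        d=d,
    )


def womersley_profile(
    harmonics,
    d: float,
    fluid: FluidProperties,
    period: float,
    r,
    t,
) -> np.ndarray:
    """Axial velocity u(r, t) of the rigid-tube Womersley solution, m/s.

    Parameters
    ----------
    harmonics : complex array
        Fourier coefficients c_0..c_N of the volumetric flow (m^3/s).
    d : float
        Tube diameter, m.
    fluid : FluidProperties
    period : float
        Cycle period, s.
    r : array-like
        Radial positions, m, |r| <= d/2.
    t : scalar or array-like
        Times, s.

    Returns
    -------
    u : ndarray, shape broadcast of (t, r)
        Real axial velocity; zero at the wall at all times.  Each harmonic n
        contributes

            u_n(r) = (c_n / (pi R^2)) *
                     (1 - J0(beta_n r/R) / J0(beta_n)) /
                     (1 - 2 J1(beta_n) / (beta_n J0(beta_n)))

        with beta_n = i^{3/2} alpha_n and alpha_n = R sqrt(n w / nu), which
        integrates over the section to exactly c_n; the n = 0 term is the
        Poiseuille profile of the mean flow.
    """
    harmonics = np.asarray(harmonics, dtype=complex)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    R = d / 2.0
    if np.any(np.abs(r) > R * (1 + 1e-12)):
        raise ValueError("radial position outside tube")
    if not np.all(np.isfinite(harmonics)):
        raise ValueError("harmonics must be finite")
    nu = fluid.nu_m2s
    omega = 2.0 * np.pi / period
    area = np.pi * R**2
    rho = np.clip(np.abs(r) / R, 0.0, 1.0)

    # steady (Poiseuille) part of the mean flow
    u = np.zeros((t.size, r.size))
    u += 2.0 * (harmonics[0].real / area) * (1.0 - rho**2)[None, :]

    i32 = 1j ** 1.5
    for n in range(1, harmonics.size):
        if harmonics[n] == 0:
            continue
        alpha_n = R * np.sqrt(n * omega / nu)
        beta = i32 * alpha_n
        j0b = jv(0, beta)
        shape = (1.0 - jv(0, beta * rho) / j0b) / (1.0 - 2.0 * jv(1, beta) / (beta * j0b))
        phasor = np.exp(1j * n * omega * t)
        u += np.real(np.outer(phasor, (harmonics[n] / area) * shape))
    return u.squeeze()


def _pulse_shape(t, period: float, systolic_peak: float, regurg_frac: float,
                 regurg_width: float):
    """Unit-peak systolic sin^2 pulse with a post-systolic regurgitation dip."""
    t = np.mod(np.asarray(t, dtype=float), period)
    ts = 2.0 * systolic_peak  # systole duration, peak at its midpoint
    s = np.where(t < ts, np.sin(np.pi * t / ts) ** 2, 0.0)
    in_dip = (t >= ts) & (t < ts + regurg_width)
    s = s - np.where(
        in_dip, regurg_frac * np.sin(np.pi * (t - ts) / regurg_width) ** 2, 0.0
    )
    return s


def physiological_waveform(
    case: str | None = None,
    *,
    u_max: float | None = None,
    u_mean: float | None = None,
    d: float = presets.PARENT_DIAMETER_MM * 1e-3,
    period: float = presets.CYCLE_PERIOD_S,
    systolic_peak: float = presets.SYSTOLIC_PEAK_S,
    regurg_frac: float = 0.08,
    regurg_width: float = 0.1,
    n_samples: int = 400,
    n_harmonics: int = 12,
) -> FlowWaveform:
    """Parameterized aortic-like pump waveform scaled to target velocities.

    The shape is a sin^2 systolic pulse (peaking at ``systolic_peak``),
    a brief valve-regurgitation dip after systole and a constant diastolic
    baseline.  Pulse amplitude and baseline are solved numerically so the
    section-mean velocity hits ``u_max`` (peak) and ``u_mean`` (cycle mean
    of |U|) exactly — either given directly or looked up from a named flow
    case (``"FL"``, ``"FM"``, ``"FH"``).
    """
    if case is not None:
        params = presets.FLOW_CASES[case]
        u_max, u_mean = params["u_max"], params["u_mean"]
    if u_max is None or u_mean is None:
        raise ValueError("provide a flow case or both u_max and u_mean")
    if not 0 < u_mean < u_max:
        raise ValueError("require 0 < u_mean < u_max")
    area = np.pi * d**2 / 4.0
    tt = np.arange(n_samples) * period / n_samples
    s = _pulse_shape(tt, period, systolic_peak, regurg_frac, regurg_width)

    def residual(ab):
        a, b = ab
        vel = a * s + b
        return [np.max(vel) - u_max, np.mean(np.abs(vel)) - u_mean]

    a0 = (u_max - u_mean) / (1.0 - systolic_peak / period)
    sol = fsolve(residual, x0=[a0, max(u_mean - a0 * systolic_peak / period, 1e-4)],
                 full_output=False)
    a, b = sol
    vel = a * s + b
    if not (np.isclose(np.max(vel), u_max, rtol=1e-6)
            and np.isclose(np.mean(np.abs(vel)), u_mean, rtol=1e-4)):
        raise RuntimeError("waveform scaling did not converge to the targets")
    return FlowWaveform(
        period=period, times=tt, flows=vel * area, n_harmonics=n_harmonics
    )
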