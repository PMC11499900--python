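"""Discrete-time hybrid mock circulatory loop simulator.

The loop couples a piston-pump flow waveform to a pneumatically controlled
hybrid chamber whose pressure setpoint follows a 3-element Windkessel
model of the downstream circulation:

    dPc/dt = (Q - (Pc - P0)/Rd) / C,       P_set = Pc + Q Rp.

The chamber pressure tracks P_set through a PID controller whose commanded
pressure rate is clipped to the slew capability of the pressure (3 kPa) and
vacuum (-0.5 kPa) supply lines.  A lumped compliant phantom segment stores
volume at a rate C_ph dP/dt, producing the inlet/outlet flow imbalance seen
on the bench; per-station wall strain follows the pressure-strain law
delta = (P - P_dia) / Ep.  Sensor logs are written at 5 kHz with a
configurable ultrasonic-flowmeter delay (calibrated on the bench between
20 and 26 ms) and optional Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import presets
from .hemodynamics import FlowWaveform

__all__ = [
    "WindkesselParams",
    "HybridUnitConfig",
    "CompliantSegment",
    "SensorLog",
    "wk3_setpoint_step",
    "hybrid_unit_step",
    "compliant_segment_step",
    "run_loop",
    "fit_windkessel",
]

LOG_RATE_HZ = 5000.0
DEFAULT_FLOWMETER_DELAY_S = 0.023  # calibrated range 0.020-0.026 s


@dataclass(frozen=True)
class WindkesselParams:
    """3-element Windkessel outlet load (SI units)."""

    Rp: float  # proximal resistance, kg m^-4 s^-1
    Rd: float  # distal resistance, kg m^-4 s^-1
    C: float  # capacitance, m^4 s^2 kg^-1
    P0: float = 0.0  # ground pressure, Pa

    def __post_init__(self) -> None:
        if min(self.Rp, self.Rd, self.C) <= 0:
            raise ValueError("Rp, Rd, C must be positive")

    @classmethod
    def from_case(cls, case: str, P0: float = 0.0) -> "WindkesselParams":
        p = presets.FLOW_CASES[case]
        return cls(Rp=p["Rp"], Rd=p["Rd"], C=p["C"], P0=P0)

    @property
    def tau(self) -> float:
        """Distal time constant Rd C, s."""
        return self.Rd * self.C


@dataclass(frozen=True)
class HybridUnitConfig:
    """PID-regulated pneumatic chamber.

    The actuator is modeled as a rate-limited integrator: the PID output is
    a commanded pressure rate, clipped to ``slew_pressure`` (> 0, toward the
    3 kPa pressure line) and ``slew_vacuum`` (< 0, toward the -0.5 kPa
    vacuum line).
    """

    kp: float = 500.0  # 1/s
    ki: float = 5000.0  # 1/s^2
    kd: float = 0.0  # dimensionless
    slew_pressure: float = 2.0e5  # Pa/s, toward the pressure line
    slew_vacuum: float = -2.0e5  # Pa/s, toward the vacuum line
    control_step: float = 1.0 / LOG_RATE_HZ  # s

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be non-negative")
        if self.control_step <= 0:
            raise ValueError("control step must be positive")
        if self.slew_pressure <= 0 or self.slew_vacuum >= 0:
            raise ValueError("slew limits must bracket zero")


@dataclass(frozen=True)
class CompliantSegment:
    """Lumped compliant phantom segment."""

    Ep: float = 3.0e5  # pressure-strain elastic modulus, N m^-2
    reference_diameters_mm: tuple[float, ...] = (20.0, 24.0, 36.0)
    C_ph: float = 2.0e-9  # volumetric compliance, m^4 s^2 kg^-1
    p_diastole: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if self.Ep <= 0:
            raise ValueError("Ep must be positive")
        if self.C_ph < 0:
            raise ValueError("C_ph must be non-negative")


@dataclass
class SensorLog:
    """Uniformly sampled bench log (5 kHz by default)."""

    time: np.ndarray  # s
    q_in: np.ndarray  # m^3/s
    q_out: np.ndarray  # (n_samples, n_outlets), m^3/s
    p_chamber: np.ndarray  # Pa
    p_in: np.ndarray  # Pa
    p_out: np.ndarray  # Pa
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q_out = np.atleast_2d(self.q_out.T).T if self.q_out.ndim == 1 else self.q_out
        n = self.time.size
        for name in ("q_in", "p_chamber", "p_in", "p_out"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        if self.q_out.shape[0] != n:
            raise ValueError("q_out length mismatch")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def phase_average(self, period: float, channel: str, last_fraction: float = 0.5):
        """Phase-average a channel over the last ``last_fraction`` of cycles.

        Returns (phase_times, mean, sd) with sd the per-phase sample
        standard deviation (ddof=1; zero when a single cycle contributes).
        """
        sig = getattr(self, channel)
        if sig.ndim > 1:
            sig = sig[:, 0]
        spc = int(round(period * self.fs))
        n_cycles = sig.size // spc
        if n_cycles < 1:
            raise ValueError("log shorter than one period")
        first = int(np.ceil(n_cycles * (1.0 - last_fraction)))
        segs = sig[: n_cycles * spc].reshape(n_cycles, spc)[first:]
        mean = segs.mean(axis=0)
        sd = segs.std(axis=0, ddof=1) if segs.shape[0] > 1 else np.zeros(spc)
        return np.arange(spc) / self.fs, mean, sd


def wk3_setpoint_step(
    pc: float, q: float, params: WindkesselParams, dt: float
) -> tuple[float, float]:
    """One explicit-trapezoidal (Heun) update of the Windkessel setpoint law.

    Returns ``(pc_new, p_set)`` with ``p_set = pc_new + q Rp``.  Steady
    constant Q drives P_set toward P0 + Q (Rp + Rd); at Q = 0 the capacitor
    pressure decays to P0 with time constant Rd C.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= params.tau / 2.0:
        raise ValueError(
            f"dt = {dt:g} s unstable for the explicit update (Rd C = {params.tau:g} s)"
        )

    def f(p):
        return (q - (p - params.P0) / params.Rd) / params.C

    k1 = f(pc)
    k2 = f(pc + dt * k1)
    pc_new = pc + 0.5 * dt * (k1 + k2)
    return pc_new, pc_new + q * params.Rp


def hybrid_unit_step(
    pressure: float,
    setpoint: float,
    config: HybridUnitConfig,
    dt: float,
    state: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """One PID step of the pneumatic chamber; returns (new pressure, state).

    ``state`` carries (integral, previous error).  Anti-windup: the integral
    is frozen while the commanded rate is saturated and the error would push
    it further into saturation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    integ, e_prev = state if state is not None else (0.0, setpoint - pressure)
    e = setpoint - pressure
    de = (e - e_prev) / dt
    u = config.kp * e + config.ki * (integ + e * dt) + config.kd * de
    u_sat = float(np.clip(u, config.slew_vacuum, config.slew_pressure))
    if u == u_sat or (u > u_sat) != (e > 0):  # conditional integration
        integ += e * dt
    return pressure + u_sat * dt, (integ, e)


def compliant_segment_step(
    q_in: float, p: float, dpdt: float, seg: CompliantSegment
) -> tuple[float, np.ndarray]:
    """Outlet flow and per-station wall strain of the compliant segment.

    Q_out = Q_in - C_ph dP/dt; strain delta = (P - P_dia)/Ep (fractional,
    identical at every station under the lumped pressure-strain law).
    """
    q_out = q_in - seg.C_ph * dpdt
    delta = np.full(len(seg.reference_diameters_mm), (p - seg.p_diastole) / seg.Ep)
    return q_out, delta


def run_loop(
    pump: FlowWaveform,
    wk: WindkesselParams | list[WindkesselParams],
    unit: HybridUnitConfig | None = None,
    seg: CompliantSegment | None = None,
    n_cycles: int = 10,
    seed: int | None = None,
    fs: float = LOG_RATE_HZ,
    flowmeter_delay: float = DEFAULT_FLOWMETER_DELAY_S,
    noise_sd: dict[str, float] | None = None,
    pc0: float | None = None,
    dpdt_filter_tau: float = 5e-3,
) -> SensorLog:
    """Simulate the loop and return the 5 kHz sensor log.

    The pump imposes Q_in(t); the compliant segment diverts C_ph dP/dt of
    it; the remaining flow splits equally over the outlets, each driving a
    Windkessel setpoint tracked by its hybrid unit (all outlets share one
    chamber trace here; the idealized phantom has a single outlet).  Flow
    channels are logged with the flowmeter delay applied; optional Gaussian
    noise is added per channel (``noise_sd`` maps channel name to absolute
    sd).  ``pc0`` warm-starts the Windkessel capacitor (default: the ground
    pressure P0; the charging transient has time constant Rd C, several
    cycles long for the bench loads).  The pressure derivative driving the
    compliant segment is low-pass filtered (first order, ``dpdt_filter_tau``)
    — the raw per-sample difference of a PID-actuated pressure is dominated
    by actuator chatter that the fluid column cannot follow.  Raises if the
    state diverges, naming the offending step size.
    """
    wk_list = [wk] if isinstance(wk, WindkesselParams) else list(wk)
    unit = unit or HybridUnitConfig()
    seg = seg or CompliantSegment()
    dt = 1.0 / fs
    n = int(round(n_cycles * pump.period * fs))
    t = np.arange(n) * dt
    q_in = pump(t)

    pc = np.array([w.P0 if pc0 is None else pc0 for w in wk_list], dtype=float)
    p_ch = float(np.mean(pc))
    state = None
    p_chamber = np.empty(n)
    q_out = np.empty((n, len(wk_list)))
    p_in = np.empty(n)
    p_prev = p_ch
    dpdt_f = 0.0
    alpha = dt / (dt + dpdt_filter_tau) if dpdt_filter_tau > 0 else 1.0
    for i in range(n):
        dpdt_raw = (p_ch - p_prev) / dt if i else 0.0
        dpdt_f += alpha * (dpdt_raw - dpdt_f)
        p_prev = p_ch
        qo_total, _ = compliant_segment_step(q_in[i], p_ch, dpdt_f, seg)
        qo = qo_total / len(wk_list)
        p_sets = np.empty(len(wk_list))
        for k, w in enumerate(wk_list):
            pc[k], p_sets[k] = wk3_setpoint_step(pc[k], qo, w, dt)
        p_ch, state = hybrid_unit_step(p_ch, float(np.mean(p_sets)), unit, dt, state)
        if not np.isfinite(p_ch):
            raise FloatingPointError(
                f"loop state diverged at step {i} (dt = {dt:g} s)"
            )
        p_chamber[i] = p_ch
        q_out[i] = qo
        p_in[i] = p_ch + qo_total * wk_list[0].Rp

    lag = int(round(flowmeter_delay * fs))
    q_in_log = _delay(q_in, lag)
    q_out_log = np.column_stack([_delay(q_out[:, k], lag) for k in range(q_out.shape[1])])

    rng = np.random.default_rng(seed)
    log = SensorLog(
        time=t,
        q_in=q_in_log,
        q_out=q_out_log,
        p_chamber=p_chamber,
        p_in=p_in,
        p_out=p_chamber.copy(),
        metadata=dict(
            flowmeter_delay_s=flowmeter_delay,
            seed=seed,
            n_cycles=n_cycles,
            period_s=pump.period,
            q_in_true=q_in,
            q_out_true=q_out,
        ),
    )
    if noise_sd:
        for name, sd in noise_sd.items():
            chan = getattr(log, name)
            chan += rng.normal(0.0, sd, size=chan.shape)
    return log


def _delay(signal: np.ndarray, lag: int) -> np.ndarray:
    """Shift a signal by ``lag`` samples, edge-padding the head."""
    if lag == 0:
        return signal.copy()
    out = np.empty_like(signal)
    out[:lag] = signal[0]
    out[lag:] = signal[:-lag]
    return out


def fit_windkessel(
    p_set: np.ndarray,
    q: np.ndarray,
    dt: float,
    x0: tuple[float, float, float] | None = None,
    P0: float = 0.0,
) -> WindkesselParams:
    """Least-squares recovery of (Rp, Rd, C) from a setpoint/flow record.

    Simulates the discrete Windkessel law for candidate parameters (in log
    space, enforcing positivity) and minimizes the pressure residual.
    """
    p_set = np.asarray(p_set, float)
    q = np.asarray(q, float)
    if x0 is None:
        x0 = (1e7, 1e9, 5e-9)

    def simulate(rp, rd, c):
        params = WindkesselParams(Rp=rp, Rd=rd, C=c, P0=P0)
        pc = P0
        out = np.empty_like(p_set)
        for i in range(p_set.size):
            pc, out[i] = wk3_setpoint_step(pc, q[i], params, dt)
        return out

    scale = np.std(p_set) or 1.0

    def resid(logx):
        rp, rd, c = np.exp(logx)
        return (simulate(rp, rd, c) - p_set) / scale

    sol = least_squares(resid, np.log(np.asarray(x0)), method="lm")
    rp, rd, c = np.exp(sol.x)
    return WindkesselParams(Rp=float(rp), Rd=float(rd), C=float(c), P0=P0)
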