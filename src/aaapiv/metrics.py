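"""Derived hemodynamic quantities from vector fields and sensor logs.

Phase-ensemble statistics (mean, sd, u'_rms), out-of-plane vorticity,
the axisymmetric flow-rate integral Q(t) = 2 pi \\int u(r) r dr from the
band-averaged axial profile, illumination-configuration difference maps,
inlet/outlet flow balance and the pressure-strain elastic modulus
Ep = dP / (dD/D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .loop import SensorLog
from .piv import VectorField

__all__ = [
    "PhaseEnsemble",
    "phase_average",
    "rms_fluctuations",
    "vorticity",
    "flow_rate_from_profile",
    "config_difference",
    "flow_balance",
    "pressure_strain_modulus",
]

M3S_TO_LMIN = 6.0e4


@dataclass
class PhaseEnsemble:
    """Vector fields grouped by cycle phase: fields[phase][cycle]."""

    fields: list[list[VectorField]]
    phase_times: np.ndarray  # s within the cycle

    def __post_init__(self) -> None:
        if len(self.fields) != len(self.phase_times):
            raise ValueError("one field list per phase time required")
        ref = self.fields[0][0]
        for per_phase in self.fields:
            for f in per_phase:
                if f.u_px.shape != ref.u_px.shape:
                    raise ValueError("all ensemble members must share the grid")

    @property
    def n_cycles(self) -> int:
        return len(self.fields[0])


def _component_stack(members: list[VectorField], comp: str) -> np.ndarray:
    """(n_cycles, ny, nx) stack of a velocity component, NaN at invalid.

    Replaced vectors are interpolated fills, not measurements, and do not
    contribute to ensemble statistics.
    """
    out = []
    for f in members:
        arr = getattr(f, comp).copy()
        arr[~(f.in_domain & f.valid) | f.replaced] = np.nan
        out.append(arr)
    return np.stack(out)


def phase_average(ensemble: PhaseEnsemble):
    """Per-phase element-wise mean and sample sd over valid vectors.

    Returns a dict with 'u_mean', 'v_mean', 'u_sd', 'v_sd', 'count'
    (each a list over phases of (ny, nx) arrays).  Statistics use only
    valid contributors (ddof=1); grid points with no contributor are NaN.
    """
    if ensemble.n_cycles < 2:
        raise ValueError("phase statistics need at least 2 cycles")
    out = {k: [] for k in ("u_mean", "v_mean", "u_sd", "v_sd", "count")}
    for members in ensemble.fields:
        us = _component_stack(members, "u_ms")
        vs = _component_stack(members, "v_ms")
        count = np.sum(np.isfinite(us), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["u_mean"].append(np.nanmean(us, axis=0))
            out["v_mean"].append(np.nanmean(vs, axis=0))
            out["u_sd"].append(_nan_sd(us))
            out["v_sd"].append(_nan_sd(vs))
        out["count"].append(count)
    return out


def _nan_sd(stack: np.ndarray) -> np.ndarray:
    """Sample sd (ddof=1) ignoring NaN; NaN where fewer than 2 values."""
    n = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sd[n < 2] = np.nan
    return sd


def rms_fluctuations(ensemble: PhaseEnsemble) -> list[np.ndarray]:
    """u'_rms map per phase: sqrt(sd_x^2 + sd_y^2) of the two components."""
    stats = phase_average(ensemble)
    return [
        np.sqrt(su**2 + sv**2) for su, sv in zip(stats["u_sd"], stats["v_sd"])
    ]


def vorticity(field: VectorField) -> np.ndarray:
    """Out-of-plane vorticity w_z = dv/dx - du/dy, 1/s.

    Central differences in the interior, one-sided at the borders; grid
    spacing converted to meters through the px/mm scale.  Invalid or
    out-of-domain vectors propagate NaN.
    """
    if field.u_px.shape[0] < 3 or field.u_px.shape[1] < 3:
        raise ValueError("vorticity needs at least a 3x3 grid")
    if field.scale is None:
        raise ValueError("field needs a px/mm scale")
    u = field.u_ms.copy()
    v = field.v_ms.copy()
    bad = ~(field.in_domain & field.valid)
    u[bad] = np.nan
    v[bad] = np.nan
    x_m = field.x_px / field.scale * 1e-3
    y_m = field.y_px / field.scale * 1e-3
    dvdx = np.gradient(v, x_m, axis=1)
    dudy = np.gradient(u, y_m, axis=0)
    w = dvdx - dudy
    w[bad] = np.nan  # a masked point is itself missing, not just its stencil
    return w


def flow_rate_from_profile(
    field: VectorField,
    band_mm: tuple[float, float],
    radius_mm: float,
    roi_x0_mm: float = 0.0,
    axis_row_px: float | None = None,
    n_radial: int = 64,
) -> float:
    """Axisymmetric flow rate from the band-averaged axial profile, m^3/s.

    The axial velocity is averaged over the columns whose axial position
    (mm from the ROI edge ``roi_x0_mm``) falls inside ``band_mm``; the
    resulting transverse profile u(r) is folded about the axis (the two
    half-profiles are averaged, equivalent to pi * int u |r| dr over
    [-R, R]), closed with the no-slip point u(R) = 0, and integrated as
    Q = 2 pi int_0^R u(r) r dr with trapezoidal quadrature.
    """
    if field.scale is None:
        raise ValueError("field needs a px/mm scale")
    x_mm = roi_x0_mm + field.x_px / field.scale
    cols = (x_mm >= band_mm[0]) & (x_mm <= band_mm[1])
    if not cols.any():
        raise ValueError("axial band outside the field")
    u = field.u_ms.copy()
    u[~(field.in_domain & field.valid)] = np.nan
    band = u[:, cols]
    counts = np.sum(np.isfinite(band), axis=1)
    profile = np.where(
        counts > 0, np.nansum(np.nan_to_num(band), axis=1), np.nan
    ) / np.maximum(counts, 1)
    profile[counts == 0] = np.nan
    if np.all(np.isnan(profile)):
        raise ValueError("axial band fully masked")
    if axis_row_px is None:
        axis_row_px = float(np.mean(field.y_px))
    r_mm = (field.y_px - axis_row_px) / field.scale

    r_grid = np.linspace(0.0, radius_mm, n_radial)
    halves = []
    for sign in (+1.0, -1.0):
        side = sign * r_mm
        sel = (side >= 0) & np.isfinite(profile) & (side <= radius_mm)
        if np.count_nonzero(sel) < 2:
            continue
        rr = np.concatenate([side[sel], [radius_mm]])
        uu = np.concatenate([profile[sel], [0.0]])  # no-slip closure
        order = np.argsort(rr)
        halves.append(np.interp(r_grid, rr[order], uu[order]))
    if not halves:
        raise ValueError("no usable half-profile in the band")
    u_bar = np.mean(halves, axis=0)  # m/s on r_grid (mm)
    r_m = r_grid * 1e-3
    return float(2.0 * np.pi * np.trapezoid(u_bar * r_m, r_m))


def config_difference(
    field_a: VectorField, field_b: VectorField
) -> tuple[np.ndarray, float]:
    """Signed difference of velocity magnitude |v|_A - |v|_B and max |diff|.

    Both fields must share the grid; points invalid in either propagate
    NaN and are excluded from the scalar maximum.
    """
    if field_a.u_px.shape != field_b.u_px.shape or not (
        np.array_equal(field_a.x_px, field_b.x_px)
        and np.array_equal(field_a.y_px, field_b.y_px)
    ):
        raise ValueError("fields must share the grid")
    mag_a = field_a.magnitude_ms.copy()
    mag_b = field_b.magnitude_ms.copy()
    bad = ~(
        field_a.in_domain & field_a.valid & field_b.in_domain & field_b.valid
    )
    diff = mag_a - mag_b
    diff[bad] = np.nan
    max_abs = float(np.nanmax(np.abs(diff))) if np.isfinite(diff).any() else 0.0
    return diff, max_abs


def flow_balance(
    log: SensorLog,
    period: float,
    delay_s: float | None = None,
    lowpass_hz: float | None = 25.0,
    last_fraction: float = 0.5,
):
    """Phase-averaged inlet/outlet flow imbalance dQ(t) = Q_in - sum Q_out.

    Outlet channels are advanced by the flowmeter delay (from the log
    metadata unless given) before differencing; an optional zero-phase
    low-pass is applied first.  Returns (phase_times, mean, sd), m^3/s.
    """
    if delay_s is None:
        delay_s = float(log.metadata.get("flowmeter_delay_s", 0.0))
    q_in = log.q_in.astype(float)
    q_out = log.q_out.astype(float).sum(axis=1)
    if q_in.size != q_out.size:
        raise ValueError("channel length mismatch")
    if lowpass_hz:
        sos = sp_signal.butter(2, lowpass_hz, fs=log.fs, output="sos")
        q_in = sp_signal.sosfiltfilt(sos, q_in)
        q_out = sp_signal.sosfiltfilt(sos, q_out)
    # both flow channels carry the same flowmeter delay, so dQ needs no
    # relative shift; the delay argument allows correcting a channel pair
    # with asymmetric delays
    dq = q_in - q_out
    spc = int(round(period * log.fs))
    n_cycles = dq.size // spc
    first = int(np.ceil(n_cycles * (1.0 - last_fraction)))
    segs = dq[: n_cycles * spc].reshape(n_cycles, spc)[first:]
    mean = segs.mean(axis=0)
    sd = segs.std(axis=0, ddof=1) if segs.shape[0] > 1 else np.zeros(spc)
    return np.arange(spc) / log.fs, mean, sd


def pressure_strain_modulus(dp_pa: float, d_ref: float, dd: float) -> float:
    """Pressure-strain elastic modulus Ep = dP / (dD/D), N m^-2.

    ``d_ref`` and ``dd`` share any unit; zero or negative strain raises.
    """
    if d_ref <= 0:
        raise ValueError("reference diameter must be positive")
    strain = dd / d_ref
    if strain <= 0:
        raise ValueError("zero or negative strain")
    return dp_pa / strain
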