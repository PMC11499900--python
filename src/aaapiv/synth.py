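"""Synthetic double-exposure particle-image generator with ground truth.

Emulates the bench imaging chain: hollow glass tracer particles (10 um)
seeded in the lumen, a 1-2 mm light sheet, a pulsed high-power LED firing
two pulses (width tau, separation dt; configurations C1-C4), and a 12-bit
camera (values stored in a 16-bit container).  Particles are rendered as
diffraction-limited Gaussian spots with motion blur along the path covered
during the pulse, depth-weighted by the sheet profile, over a static
background (offset + smooth gradient + optional wall-reflection band) with
Poisson-Gaussian sensor noise.  Every pair carries the ground-truth
displacement field on the PIV output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable

import numpy as np

from . import presets
from .piv import window_grid

__all__ = [
    "CameraModel",
    "IlluminationConfig",
    "ParticleField",
    "ImagePair",
    "ImagePairSequence",
    "BackgroundModel",
    "seed_particles",
    "advect",
    "render_pair",
    "generate_dataset",
]

#: velocity-field sampler signature: (x_mm, y_mm, z_mm, t_s) -> (u_mps, v_mps)
FieldSampler = Callable[[np.ndarray, np.ndarray, np.ndarray, float], tuple]


@dataclass(frozen=True)
class CameraModel:
    """Acquisition camera; a ROI crop of the 1920x1200 12-bit sensor."""

    shape: tuple[int, int] = (1200, 1920)  # (rows, cols) px
    bit_depth: int = 12
    scale: float = presets.PIXEL_SCALE_IDEALIZED  # px/mm
    exposure_us: float = 13000.0
    min_interframe_us: float = 80.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class IlluminationConfig:
    """Pulsed-LED double-exposure timing."""

    tau_us: float
    dt_us: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.tau_us < self.dt_us:
            raise ValueError("require 0 < pulse width < pulse separation")

    @property
    def duty_cycle(self) -> float:
        """tau/dt — the streak length as a fraction of the displacement."""
        return self.tau_us / self.dt_us

    @classmethod
    def from_label(cls, label: str) -> "IlluminationConfig":
        p = presets.ILLUMINATION_CONFIGS[label]
        return cls(tau_us=p["tau_us"], dt_us=p["dt_us"], label=label)


@dataclass
class ParticleField:
    """Tracer positions in window coordinates (mm) plus sheet depth."""

    x_mm: np.ndarray
    y_mm: np.ndarray  # transverse, 0 on the lumen axis
    z_mm: np.ndarray  # through-sheet depth, 0 at the sheet center
    diameter_um: float = 10.0
    sheet_thickness_mm: float = 1.5
    density_per_mm2: float = 7.0

    @property
    def n(self) -> int:
        return self.x_mm.size


@dataclass(frozen=True)
class BackgroundModel:
    """Static background: offset + linear gradient + wall-reflection band."""

    offset: float = 100.0  # counts
    gradient: float = 60.0  # counts across the frame
    reflection_amplitude: float = 0.0  # counts, band hugging the wall
    reflection_sigma_px: float = 2.0
    read_noise_sd: float = 4.0  # counts
    poisson: bool = True


@dataclass
class ImagePair:
    frame_a: np.ndarray  # uint16, 12-bit range
    frame_b: np.ndarray
    t_s: float  # first-pulse time within the cycle
    gt_x_px: np.ndarray  # ground-truth grid columns
    gt_y_px: np.ndarray
    gt_u_px: np.ndarray  # (ny, nx) displacement over dt, px
    gt_v_px: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass
class ImagePairSequence:
    pairs: list[ImagePair]
    illumination: IlluminationConfig
    camera: CameraModel
    pair_interval_s: float
    pairs_per_cycle: int
    mask: np.ndarray  # lumen mask (bool) shared by all pairs
    window_mm: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def seed_particles(
    mask: np.ndarray,
    window: tuple[float, float],
    scale: float,
    density_per_mm2: float = 7.0,
    sheet_thickness_mm: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> ParticleField:
    """Poisson-seed tracers uniformly over the lumen mask.

    The particle count is Poisson with mean density x lumen area (mm^2);
    in-plane positions are uniform over mask-true pixels (rejection
    sampling), depths uniform across the sheet.  Reproducible given seed.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty lumen mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    area_mm2 = mask.sum() / scale**2
    n = int(rng.poisson(density_per_mm2 * area_mm2))
    h, w = mask.shape
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = int((n - got) * 1.8) + 16
        cand_c = rng.uniform(0, w, m)
        cand_r = rng.uniform(0, h, m)
        keep = mask[cand_r.astype(int), cand_c.astype(int)]
        take = min(int(keep.sum()), n - got)
        xs[got : got + take] = cand_c[keep][:take]
        ys[got : got + take] = cand_r[keep][:take]
        got += take
    x_min = window[0]
    return ParticleField(
        x_mm=x_min + xs / scale,
        y_mm=(ys - h / 2.0) / scale,
        z_mm=rng.uniform(-sheet_thickness_mm / 2, sheet_thickness_mm / 2, n),
        sheet_thickness_mm=sheet_thickness_mm,
        density_per_mm2=density_per_mm2,
    )


def advect(
    particles: ParticleField,
    sampler: FieldSampler,
    dt_s: float,
    t0: float = 0.0,
    window: tuple[float, float] | None = None,
    substeps: int = 1,
) -> ParticleField:
    """Advect tracers through the velocity field with RK4 integration.

    Particles leaving the axial window are respawned at the inlet edge with
    their transverse position kept.  Raises on non-finite velocities.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    x = particles.x_mm.astype(float).copy()
    y = particles.y_mm.astype(float).copy()
    z = particles.z_mm
    h = dt_s / substeps
    t = t0
    for _ in range(substeps):
        k1u, k1v = sampler(x, y, z, t)
        k2u, k2v = sampler(x + 0.5 * h * _mm(k1u), y + 0.5 * h * _mm(k1v), z, t + h / 2)
        k3u, k3v = sampler(x + 0.5 * h * _mm(k2u), y + 0.5 * h * _mm(k2v), z, t + h / 2)
        k4u, k4v = sampler(x + h * _mm(k3u), y + h * _mm(k3v), z, t + h)
        du = h * _mm(k1u + 2 * np.asarray(k2u) + 2 * np.asarray(k3u) + np.asarray(k4u)) / 6.0
        dv = h * _mm(k1v + 2 * np.asarray(k2v) + 2 * np.asarray(k3v) + np.asarray(k4v)) / 6.0
        if not (np.all(np.isfinite(du)) and np.all(np.isfinite(dv))):
            raise FloatingPointError("non-finite velocity during advection")
        x += du
        y += dv
        t += h
    if window is not None:
        exited = x > window[1]
        x[exited] = window[0] + (x[exited] - window[1])
        exited_l = x < window[0]
        x[exited_l] = window[0]
    return dc_replace(particles, x_mm=x, y_mm=y)


def _mm(v_mps) -> np.ndarray:
    """m/s -> mm/s."""
    return np.asarray(v_mps, dtype=float) * 1e3


def _stamp(
    img: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> None:
    """Accumulate Gaussian spots at sub-pixel positions (in place)."""
    reach = max(int(np.ceil(3 * sigma_px)), 2)
    ir = np.floor(rows).astype(int)
    ic = np.floor(cols).astype(int)
    h, w = img.shape
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            r = ir + dr
            c = ic + dc
            ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
            if not ok.any():
                continue
            g = amplitudes[ok] * np.exp(
                -((r[ok] - rows[ok]) ** 2 + (c[ok] - cols[ok]) ** 2)
                / (2 * sigma_px**2)
            )
            np.add.at(img, (r[ok], c[ok]), g)


def _background_image(
    shape: tuple[int, int], model: BackgroundModel, mask: np.ndarray | None
) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    bg = model.offset + model.gradient * (0.5 * rr / h + 0.5 * cc / w)
    if model.reflection_amplitude > 0 and mask is not None:
        inside = mask.astype(float)
        # distance-like band at the mask boundary
        from scipy import ndimage

        edge = inside - ndimage.binary_erosion(mask).astype(float)
        band = ndimage.gaussian_filter(edge, model.reflection_sigma_px)
        if band.max() > 0:
            bg = bg + model.reflection_amplitude * band / band.max()
    return bg


def render_pair(
    particles: ParticleField,
    camera: CameraModel,
    illum: IlluminationConfig,
    sampler: FieldSampler,
    t0: float,
    window: tuple[float, float],
    shape: tuple[int, int],
    background: BackgroundModel | None = None,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    brightness: float = 1300.0,
    spot_sigma_px: float = 0.65,
    gt_window_px: int = 32,
    gt_overlap: float = 0.5,
    blur_substeps: int = 3,
) -> ImagePair:
    """Render one double-exposure pair plus its ground-truth displacement.

    Pulse A exposes the tracers over [t0, t0 + tau]; pulse B over the same
    width starting at t0 + dt after RK4 advection of every tracer.  Motion
    blur is modeled by splitting each pulse into ``blur_substeps``
    sub-exposures along the particle path; spot peak intensity scales with
    the pulse width (exposure linearity) and with a Gaussian sheet-depth
    profile.  Ground truth is the mid-plane displacement over dt on the PIV
    grid (``gt_window_px`` windows, ``gt_overlap``), in px.
    """
    if illum.dt_us > camera.exposure_us:
        raise ValueError("pulse separation exceeds the camera exposure")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    background = background or BackgroundModel()
    tau_s = illum.tau_us * 1e-6
    dt_s = illum.dt_us * 1e-6
    scale = camera.scale
    h = shape[0]
    x_min = window[0]

    amp = brightness * (illum.tau_us / 20.0) * np.exp(
        -particles.z_mm**2 / (2 * (particles.sheet_thickness_mm / 4.0) ** 2)
    )

    def expose(p0: ParticleField, t_pulse: float) -> np.ndarray:
        img = np.zeros(shape)
        p = p0
        for j in range(blur_substeps):
            rows = p.y_mm * scale + h / 2.0
            cols = (p.x_mm - x_min) * scale
            _stamp(img, rows, cols, amp / blur_substeps, spot_sigma_px)
            if j < blur_substeps - 1:
                p = advect(p, sampler, tau_s / (blur_substeps - 1),
                           t_pulse + j * tau_s / (blur_substeps - 1), window)
        return img

    img_a = expose(particles, t0)
    moved = advect(particles, sampler, dt_s, t0, window)
    img_b = expose(moved, t0 + dt_s)

    bg = _background_image(shape, background, mask)
    out = []
    for img in (img_a, img_b):
        signal = img + bg
        if background.poisson:
            signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
        signal = signal + rng.normal(0.0, background.read_noise_sd, shape)
        out.append(np.clip(signal, 0, camera.max_count).astype(np.uint16))
    frame_a, frame_b = out

    meta: dict = dict(config=illum.label, t0_s=t0)
    sat = float((frame_a >= camera.max_count).mean())
    if sat > 0.5:
        meta["saturation_warning"] = sat

    gx = window_grid(shape[1], gt_window_px, gt_overlap).astype(float)
    gy = window_grid(shape[0], gt_window_px, gt_overlap).astype(float)
    cc, rr = np.meshgrid(gx, gy)
    x_mm = x_min + cc / scale
    y_mm = (rr - h / 2.0) / scale
    gp = ParticleField(x_mm=x_mm.ravel(), y_mm=y_mm.ravel(),
                       z_mm=np.zeros(x_mm.size))
    gmoved = advect(gp, sampler, dt_s, t0, window=None)
    gt_u = (gmoved.x_mm - gp.x_mm).reshape(rr.shape) * scale
    gt_v = (gmoved.y_mm - gp.y_mm).reshape(rr.shape) * scale

    return ImagePair(
        frame_a=frame_a, frame_b=frame_b, t_s=t0,
        gt_x_px=gx, gt_y_px=gy, gt_u_px=gt_u, gt_v_px=gt_v, metadata=meta,
    )


def generate_dataset(
    sampler: FieldSampler,
    mask: np.ndarray,
    window: tuple[float, float],
    camera: CameraModel,
    illum: IlluminationConfig,
    period_s: float = presets.CYCLE_PERIOD_S,
    n_cycles: int = 1,
    pairs_per_cycle: int = presets.PAIRS_PER_CYCLE,
    seed: int = 0,
    density_per_mm2: float = 7.0,
    sheet_thickness_mm: float = 1.5,
    cycle_jitter: float = 0.0,
    background: BackgroundModel | None = None,
    phase_indices: list[int] | None = None,
    **render_kwargs,
) -> ImagePairSequence:
    """Generate phase-locked image pairs over one or more cardiac cycles.

    Pairs are acquired at ``pairs_per_cycle`` phases per cycle (default 25,
    i.e. one pair every T/25 = 32 ms).  ``cycle_jitter`` scales the whole
    velocity field by a factor ~ N(1, jitter) drawn per cycle, emulating
    cycle-to-cycle fluctuation; with jitter 0 the ground truth is identical
    across cycles at fixed phase.  Particle seeding is re-drawn per pair
    from a (seed, cycle, phase)-derived stream, so the first-pulse particle
    positions depend only on the seed — not on the illumination config.
    """
    pair_interval = period_s / pairs_per_cycle
    if pair_interval * 1e6 < camera.min_interframe_us:
        raise ValueError("pair cadence faster than the camera inter-frame time")
    shape = mask.shape
    jit_rng = np.random.default_rng((seed, 0xC1C1E))
    pairs = []
    for cyc in range(n_cycles):
        gain = 1.0 + (cycle_jitter * jit_rng.standard_normal() if cycle_jitter else 0.0)
        samp = (lambda g: lambda x, y, z, t: tuple(
            g * np.asarray(c) for c in sampler(x, y, z, t)
        ))(gain)
        for ph in (range(pairs_per_cycle) if phase_indices is None
                   else phase_indices):
            t0 = ph * pair_interval
            p_rng = np.random.default_rng((seed, cyc, ph))
            particles = seed_particles(
                mask, window, camera.scale, density_per_mm2,
                sheet_thickness_mm, p_rng,
            )
            pair = render_pair(
                particles, camera, illum, samp, t0, window, shape,
                background=background, mask=mask, seed=p_rng, **render_kwargs,
            )
            pair.metadata.update(cycle=cyc, phase=ph, gain=gain)
            pairs.append(pair)
    return ImagePairSequence(
        pairs=pairs, illumination=illum, camera=camera,
        pair_interval_s=pair_interval, pairs_per_cycle=pairs_per_cycle,
        mask=np.asarray(mask, bool), window_mm=window,
        metadata=dict(seed=seed, n_cycles=n_cycles, cycle_jitter=cycle_jitter),
    )
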