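"""Particle-image processing chain.

Preprocessing (background subtraction, percentile rescale, CLAHE, Gaussian
smoothing), wall segmentation by active contour, multi-pass FFT
cross-correlation PIV with window deformation, and the three-criterion
vector validation (global 5-sigma threshold, 3x normalized local-median
test, correlation SNR >= 1.25).

Conventions: image rows are the transverse coordinate y, columns the axial
coordinate x; displacements (u, v) are in px along (columns, rows).  The
correlation is computed on zero-mean uniform (unweighted) windows; the
sub-pixel peak uses a three-point Gaussian fit per axis; SNR is the ratio
of the primary correlation peak to the highest peak outside its 3x3
neighborhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage import exposure, segmentation

__all__ = [
    "PreprocessConfig",
    "ValidationConfig",
    "VectorField",
    "WallContour",
    "SegmentationError",
    "preprocess",
    "segment_wall",
    "delta_deformation",
    "piv_multipass",
    "validate_vectors",
    "window_grid",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Image-enhancement settings applied before correlation."""

    p_low: float = 20.0  # rescale percentile, low
    p_high: float = 99.5  # rescale percentile, high
    clahe_clip: float = 0.01
    clahe_tiles: int = 8  # tiles per image side
    gaussian_sigma: float = 1.0  # px

    def __post_init__(self) -> None:
        if not 0 <= self.p_low < self.p_high <= 100:
            raise ValueError("require 0 <= p_low < p_high <= 100")


@dataclass(frozen=True)
class ValidationConfig:
    """Three-criterion vector validation thresholds."""

    global_k: float = 5.0  # sd multiples for the global threshold
    median_k: float = 3.0  # multiples of the local median residual
    snr_min: float = 1.25
    neighborhood: int = 3
    eps_px: float = 0.1  # regularization of the normalized residual

    def __post_init__(self) -> None:
        if self.neighborhood < 3:
            raise ValueError("neighborhood must be at least 3x3")


@dataclass
class VectorField:
    """Gridded 2-D velocity estimate from one image pair.

    ``u_px``/``v_px`` are displacements in px along columns/rows on the
    (y, x) grid of window centers; ``in_domain`` marks windows with enough
    unmasked coverage to emit a vector; ``valid``/``replaced`` are set by
    :func:`validate_vectors`.
    """

    x_px: np.ndarray  # (nx,) window-center columns
    y_px: np.ndarray  # (ny,) window-center rows
    u_px: np.ndarray  # (ny, nx)
    v_px: np.ndarray  # (ny, nx)
    snr: np.ndarray  # (ny, nx)
    in_domain: np.ndarray  # (ny, nx) bool
    valid: np.ndarray = None  # type: ignore[assignment]
    replaced: np.ndarray = None  # type: ignore[assignment]
    boundary: np.ndarray = None  # type: ignore[assignment]
    scale: float | None = None  # px/mm
    dt_s: float | None = None  # inter-pulse separation, s
    window_px: int | None = None
    overlap: float | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = self.in_domain.copy()
        if self.replaced is None:
            self.replaced = np.zeros_like(self.in_domain)
        if self.boundary is None:
            self.boundary = np.zeros_like(self.in_domain)

    def _to_ms(self, comp: np.ndarray) -> np.ndarray:
        if self.scale is None or self.dt_s is None:
            raise ValueError("scale and dt_s must be set for velocity conversion")
        return comp / self.scale * 1e-3 / self.dt_s

    @property
    def u_ms(self) -> np.ndarray:
        """Axial velocity, m/s (px displacement / scale / dt)."""
        return self._to_ms(self.u_px)

    @property
    def v_ms(self) -> np.ndarray:
        return self._to_ms(self.v_px)

    @property
    def magnitude_ms(self) -> np.ndarray:
        return np.hypot(self.u_ms, self.v_ms)

    @classmethod
    def from_velocity(
        cls,
        x_px: np.ndarray,
        y_px: np.ndarray,
        u_ms: np.ndarray,
        v_ms: np.ndarray,
        in_domain: np.ndarray | None = None,
        snr: np.ndarray | None = None,
        **kwargs,
    ) -> "VectorField":
        """Build a field directly from velocities in m/s (e.g. an ensemble
        mean); scale/dt are set so the px <-> m/s conversion is identity."""
        if in_domain is None:
            in_domain = np.isfinite(u_ms)
        if snr is None:
            snr = np.full_like(np.asarray(u_ms, float), np.inf)
        return cls(
            x_px=x_px, y_px=y_px, u_px=np.asarray(u_ms, float),
            v_px=np.asarray(v_ms, float), snr=snr, in_domain=in_domain,
            scale=1.0, dt_s=1e-3, **kwargs,
        )

    def masked(self, component: str = "u_px") -> np.ndarray:
        """Component with NaN outside the domain / at invalid vectors."""
        arr = getattr(self, component).astype(float).copy()
        arr[~(self.in_domain & self.valid)] = np.nan
        return arr


def window_grid(n: int, window: int, overlap: float) -> np.ndarray:
    """Window-center positions along one axis (px, pixel-index units)."""
    step = int(round(window * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large for this window size")
    return np.arange(window // 2, n - window // 2 + 1, step)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    frames: np.ndarray,
    config: PreprocessConfig | None = None,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Enhance a stack of frames for cross-correlation.

    Fixed pipeline: mean-background subtraction (clipped at 0), percentile
    rescale to [0, 1], CLAHE, Gaussian smoothing.  The background defaults
    to the stack mean (particle images wash out over a long acquisition);
    pass ``background`` explicitly for short stacks whose frames share
    tracer positions.  Returns the filtered stack (float in [0, 1]) and
    the background image.
    """
    config = config or PreprocessConfig()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames")
    if background is None:
        background = frames.mean(axis=0)
    residual = np.clip(frames - background[None], 0.0, None)

    lo, hi = np.percentile(residual, [config.p_low, config.p_high])
    if hi <= lo:
        raise ValueError(
            "intensity rescale failed: percentile range is empty "
            "(constant or zero-variance stack)"
        )
    rescaled = np.clip((residual - lo) / (hi - lo), 0.0, 1.0)

    h, w = frames.shape[1:]
    kernel = (max(h // config.clahe_tiles, 1), max(w // config.clahe_tiles, 1))
    out = np.empty_like(rescaled)
    for i, frame in enumerate(rescaled):
        eq = exposure.equalize_adapthist(
            frame, kernel_size=kernel, clip_limit=config.clahe_clip
        )
        out[i] = ndimage.gaussian_filter(eq, config.gaussian_sigma)
    return out, background


# ---------------------------------------------------------------------------
# wall segmentation and deformation


class SegmentationError(RuntimeError):
    """Active contour failed to converge; carries the last contour."""

    def __init__(self, message: str, contour: "WallContour"):
        super().__init__(message)
        self.contour = contour


@dataclass
class WallContour:
    """Closed wall contour in pixel coordinates (row, col vertices)."""

    vertices: np.ndarray  # (n, 2) as (row, col), implicitly closed

    def __post_init__(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2) (row, col)")

    def width_at(self, cols) -> np.ndarray:
        """Transverse extent Y(x): contour height at the given column(s).

        Intersects each vertical line with the closed polyline and returns
        max(row) - min(row) of the crossings; NaN where the line misses the
        contour.
        """
        cols = np.atleast_1d(np.asarray(cols, dtype=float))
        v = self.vertices
        r0, c0 = v[:, 0], v[:, 1]
        r1 = np.roll(r0, -1)
        c1 = np.roll(c0, -1)
        widths = np.full(cols.size, np.nan)
        for i, x in enumerate(cols):
            dc = c1 - c0
            with np.errstate(divide="ignore", invalid="ignore"):
                s = (x - c0) / dc
            hit = (np.abs(dc) > 1e-12) & (s >= 0.0) & (s < 1.0)
            if np.count_nonzero(hit) >= 2:
                rows = r0[hit] + s[hit] * (r1[hit] - r0[hit])
                widths[i] = rows.max() - rows.min()
        return widths if widths.size > 1 else float(widths[0])


def segment_wall(
    frame: np.ndarray,
    init: np.ndarray,
    mode: str = "tube",
    alpha: float = 0.01,
    beta: float = 2.0,
    w_line: float = 0.0,
    w_edge: float = 1.0,
    gamma: float = 0.001,
    smooth_sigma: float = 2.0,
    max_num_iter: int = 2500,
    max_px_move: float = 0.2,
    convergence_tol: float = 0.5,
) -> WallContour:
    """Segment the phantom wall with an active contour.

    ``init`` is a closed (n, 2) (row, col) polyline overlapping the wall
    within the snake's capture range (the bench workflow initializes it
    manually).  In ``"tube"`` mode — the idealized phantom crossing the
    whole field of view — the contour is split at its leftmost and
    rightmost vertices into upper and lower wall chains, each refined as
    an open snake with fixed endpoints (a periodic snake cannot anchor
    where the lumen continues past the image border).  ``"closed"`` mode
    refines the polyline as one periodic snake.  Convergence is checked
    by a short re-run; failure raises :class:`SegmentationError` carrying
    the last contour.
    """
    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma)
    peak = np.abs(img).max()
    if peak > 0:
        img = img / peak
    kwargs = dict(alpha=alpha, beta=beta, w_line=w_line, w_edge=w_edge,
                  gamma=gamma, max_px_move=max_px_move)
    init = np.asarray(init, dtype=float)

    def refine(chain, bc, n_iter):
        return segmentation.active_contour(
            img, chain, max_num_iter=n_iter, boundary_condition=bc, **kwargs
        )

    if mode == "closed":
        snake = refine(init, "periodic", max_num_iter)
        check = refine(snake, "periodic", 100)
        pieces = [(snake, check)]
        rebuild = lambda chains: chains[0]
    elif mode == "tube":
        # split into upper / lower wall chains about the contour centroid
        # row (a tube contour has every upper-wall vertex above it)
        mid = init[:, 0].mean()
        upper = init[init[:, 0] < mid]
        lower = init[init[:, 0] >= mid]
        if len(upper) < 4 or len(lower) < 4:
            raise ValueError("tube-mode contour must trace both walls")
        chain_a = upper[np.argsort(upper[:, 1])]
        chain_b = lower[np.argsort(lower[:, 1])]
        pieces = []
        for chain in (chain_a, chain_b):
            snake = refine(chain, "fixed", max_num_iter)
            pieces.append((snake, refine(snake, "fixed", 100)))
        rebuild = lambda chains: np.concatenate([chains[0], chains[1][::-1]])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # convergence is judged on the wall-normal position (via the extracted
    # widths): snake points may still slide tangentially along a settled edge
    before = WallContour(vertices=rebuild([snk for snk, _ in pieces]))
    contour = WallContour(vertices=rebuild([chk for _, chk in pieces]))
    cols = np.linspace(init[:, 1].min() + 2, init[:, 1].max() - 2, 40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        movement = float(np.nanmedian(np.abs(
            contour.width_at(cols) - before.width_at(cols)
        )))
    if np.isnan(movement):
        movement = np.inf
    if movement > convergence_tol:
        raise SegmentationError(
            f"active contour not converged (residual movement {movement:.2f} px)",
            contour,
        )
    return contour


def delta_deformation(
    y_series: np.ndarray,
    t0_index: int = 0,
    normalize: bool = True,
) -> np.ndarray:
    """Wall-dimension change relative to diastole, delta(x, t).

    ``y_series`` is (n_stations, n_times) of transverse extents Y(x, t) in
    px (or mm).  Returns Y - Y(t0) per station; with ``normalize`` the
    result is divided by Y(t0) and reported in percent (the idealized
    phantom's cross-section is circular, so the relative circumferential
    and diameter changes coincide).  delta(x, t0) is exactly zero.
    """
    y = np.asarray(y_series, dtype=float)
    if y.ndim != 2:
        raise ValueError("y_series must be (n_stations, n_times)")
    if not 0 <= t0_index < y.shape[1]:
        raise ValueError("t0_index outside the series")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing station measurement in the series")
    ref = y[:, [t0_index]]
    delta = y - ref
    if normalize:
        delta = delta / ref * 100.0
    return delta


# ---------------------------------------------------------------------------
# multi-pass PIV


def _batched_correlate(wins_a: np.ndarray, wins_b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation planes (B relative to A), fftshifted."""
    a = wins_a - wins_a.mean(axis=(1, 2), keepdims=True)
    b = wins_b - wins_b.mean(axis=(1, 2), keepdims=True)
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    c = np.fft.irfft2(fb * np.conj(fa), s=a.shape[1:])
    return np.fft.fftshift(c, axes=(1, 2))


def _gauss_interp(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian sub-pixel offset from samples at -1, 0, +1."""
    floor = 1e-12
    lm, l0, lp = (np.log(max(v, floor)) for v in (cm, c0, cp))
    denom = 2.0 * (lm + lp - 2.0 * l0)
    if denom >= 0:  # not a local max in log space
        return 0.0
    off = (lm - lp) / denom
    return float(np.clip(off, -1.0, 1.0))


def _peak_and_snr(plane: np.ndarray) -> tuple[float, float, float]:
    """Sub-pixel peak location (dy, dx from center) and peak-to-second SNR."""
    w = plane.shape[0]
    center = w // 2
    pos = plane - plane.min()
    iy, ix = np.unravel_index(np.argmax(pos), pos.shape)
    if not (0 < iy < w - 1 and 0 < ix < w - 1):
        return float(iy - center), float(ix - center), 0.0
    dy = iy - center + _gauss_interp(pos[iy - 1, ix], pos[iy, ix], pos[iy + 1, ix])
    dx = ix - center + _gauss_interp(pos[iy, ix - 1], pos[iy, ix], pos[iy, ix + 1])
    peak1 = pos[iy, ix]
    excl = pos.copy()
    excl[max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2] = 0.0
    peak2 = excl.max()
    snr = peak1 / peak2 if peak2 > 0 else np.inf
    return float(dy), float(dx), float(snr)


def _extract_windows(img: np.ndarray, ys: np.ndarray, xs: np.ndarray, w: int):
    half = w // 2
    wins = np.empty((ys.size * xs.size, w, w), dtype=float)
    k = 0
    for y in ys:
        for x in xs:
            wins[k] = img[y - half : y + half, x - half : x + half]
            k += 1
    return wins


def _dense_predictor(
    field: "VectorField", shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear dense displacement maps from a gridded field (extrapolated
    with edge values outside the grid)."""
    u = field.masked("u_px")
    v = field.masked("v_px")
    u = _fill_nan(u)
    v = _fill_nan(v)
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    out = []
    for comp in (u, v):
        it = RegularGridInterpolator(
            (field.y_px.astype(float), field.x_px.astype(float)),
            comp,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        out.append(it(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(shape))
    return out[0], out[1]  # u (cols), v (rows)


def _fill_nan(arr: np.ndarray) -> np.ndarray:
    """Replace NaNs by the mean of finite neighbors, iteratively."""
    out = arr.copy()
    if not np.any(np.isnan(out)):
        return out
    kernel = np.ones((3, 3))
    for _ in range(max(out.shape) * 2):
        bad = np.isnan(out)
        if not bad.any():
            break
        filled = np.where(bad, 0.0, out)
        counts = ndimage.convolve(
            (~bad).astype(float), kernel, mode="constant", cval=0.0
        )
        sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = sums / counts
        out[bad & (counts > 0)] = est[bad & (counts > 0)]
    out[np.isnan(out)] = 0.0
    return out


def piv_multipass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    mask: np.ndarray | None = None,
    passes: tuple[int, ...] = (128, 64, 32),
    overlap: float = 0.5,
    scale: float | None = None,
    dt_s: float | None = None,
    validation: ValidationConfig | None = None,
    min_coverage: float = 0.5,
) -> VectorField:
    """Multi-pass FFT cross-correlation with window deformation.

    Each pass correlates zero-mean interrogation windows of frame A against
    frame B warped by the previous pass's validated field (bilinear dense
    predictor, bicubic image interpolation), so the pass measures only the
    residual displacement.  Windows whose lumen-mask coverage is below
    ``min_coverage`` emit no vector.  The final pass's raw field (with
    per-vector SNR) is returned; run :func:`validate_vectors` on it for the
    three-criterion validation.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if mask is not None and mask.shape != a.shape:
        raise ValueError("mask must be aligned with the frames")
    if max(passes) > min(a.shape):
        raise ValueError(
            f"window {max(passes)} px larger than image {a.shape}"
        )
    validation = validation or ValidationConfig()
    mask_f = np.ones_like(a) if mask is None else mask.astype(float)

    prev: VectorField | None = None
    for p_idx, w in enumerate(passes):
        ys = window_grid(a.shape[0], w, overlap)
        xs = window_grid(a.shape[1], w, overlap)
        if ys.size == 0 or xs.size == 0:
            raise ValueError(f"window {w} px larger than image {a.shape}")

        if prev is None:
            u_dense = np.zeros(a.shape)
            v_dense = np.zeros(a.shape)
        else:
            u_dense, v_dense = _dense_predictor(prev, a.shape)
        if prev is None:
            b_warp = b
        else:
            rr, cc = np.meshgrid(
                np.arange(a.shape[0], dtype=float),
                np.arange(a.shape[1], dtype=float),
                indexing="ij",
            )
            b_warp = ndimage.map_coordinates(
                b, [rr + v_dense, cc + u_dense], order=3, mode="nearest"
            )

        wins_a = _extract_windows(a * mask_f, ys, xs, w)
        wins_b = _extract_windows(b_warp * mask_f, ys, xs, w)
        cover = _extract_windows(mask_f, ys, xs, w).mean(axis=(1, 2))
        in_domain = (cover >= min_coverage).reshape(ys.size, xs.size)
        # windows crossing the mask boundary hold a mixture of lumen and
        # masked pixels; their correlation is particle-weighted, not a
        # point measurement — flagged for downstream consumers
        boundary = in_domain & (cover < 1.0).reshape(ys.size, xs.size)

        planes = _batched_correlate(wins_a, wins_b)
        u_p = np.zeros((ys.size, xs.size))
        v_p = np.zeros((ys.size, xs.size))
        snr = np.zeros((ys.size, xs.size))
        k = 0
        for i in range(ys.size):
            for j in range(xs.size):
                if in_domain[i, j]:
                    dy, dx, s = _peak_and_snr(planes[k])
                    limit = w / 3.0
                    u_p[i, j] = np.clip(dx, -limit, limit)
                    v_p[i, j] = np.clip(dy, -limit, limit)
                    snr[i, j] = s
                k += 1
        # add the predictor evaluated at the window centers
        u_tot = u_p + u_dense[np.ix_(ys, xs)]
        v_tot = v_p + v_dense[np.ix_(ys, xs)]

        fld = VectorField(
            x_px=xs, y_px=ys, u_px=u_tot, v_px=v_tot, snr=snr,
            in_domain=in_domain, boundary=boundary, scale=scale, dt_s=dt_s,
            window_px=w, overlap=overlap,
        )
        if p_idx < len(passes) - 1:
            fld, _ = validate_vectors(fld, validation)
        prev = fld
    return prev


# ---------------------------------------------------------------------------
# vector validation


def _neighbor_stack(arr: np.ndarray, size: int) -> np.ndarray:
    """Stack of neighbor values within a size x size window (center
    excluded), NaN-padded at the borders."""
    half = size // 2
    padded = np.pad(arr, half, constant_values=np.nan)
    stacks = []
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            if dy == 0 and dx == 0:
                continue
            stacks.append(
                padded[
                    half + dy : half + dy + arr.shape[0],
                    half + dx : half + dx + arr.shape[1],
                ]
            )
    return np.stack(stacks)


def validate_vectors(
    field: VectorField, config: ValidationConfig | None = None
) -> tuple[VectorField, float]:
    """Three-criterion validation with neighbor-mean replacement.

    A vector is invalid when any of: a component deviates from the global
    mean by more than ``global_k`` standard deviations; its residual to the
    neighborhood median exceeds ``median_k`` times the neighborhood median
    residual (normalized, with an ``eps_px`` floor); or its correlation SNR
    is below ``snr_min``.  Invalid vectors are replaced by the mean of the
    valid neighbors (their SNR inherits the donors' mean, making a repeat
    run a no-op).  Returns the validated field and the pre-replacement
    invalid fraction.
    """
    config = config or ValidationConfig()
    if not field.in_domain.any():
        return field, 0.0
    dom = field.in_domain

    u_new = field.u_px.astype(float).copy()
    v_new = field.v_px.astype(float).copy()
    snr_new = field.snr.astype(float).copy()
    flagged = field.replaced.copy()  # consensus values are never re-flagged
    rate = None
    warn_ctx = warnings.catch_warnings()
    warn_ctx.__enter__()
    warnings.simplefilter("ignore", RuntimeWarning)
    for _ in range(10):
        invalid = np.zeros_like(dom)
        for comp_raw in (u_new, v_new):
            comp = comp_raw.copy()
            comp[~dom] = np.nan
            mean = np.nanmean(comp)
            sd = np.nanstd(comp)
            if sd > 0:
                invalid |= np.abs(comp - mean) > config.global_k * sd

            nb = _neighbor_stack(comp, config.neighborhood)
            with np.errstate(all="ignore"):
                med = np.nanmedian(nb, axis=0)
                resid = np.abs(comp - med)
                r_med = np.nanmedian(np.abs(nb - med[None]), axis=0)
                norm = resid / (r_med + config.eps_px)
            invalid |= np.nan_to_num(norm) > config.median_k

        invalid |= snr_new < config.snr_min
        invalid &= dom & ~flagged
        if rate is None:  # pre-replacement invalid fraction, first sweep
            rate = float(np.count_nonzero(invalid) / np.count_nonzero(dom))
        if not invalid.any():
            break
        flagged |= invalid

        good = dom & ~flagged
        nb_mask = _neighbor_stack(np.where(good, 1.0, np.nan), config.neighborhood)
        has_donor = np.nansum(nb_mask, axis=0) > 0
        for arr in (u_new, v_new, snr_new):
            nb = _neighbor_stack(np.where(good, arr, np.nan), config.neighborhood)
            with np.errstate(all="ignore"):
                donor = np.nanmean(nb, axis=0)
            sel = invalid & has_donor
            arr[sel] = donor[sel]

    good = dom & ~flagged
    nb_mask = _neighbor_stack(np.where(good, 1.0, np.nan), config.neighborhood)
    has_donor = np.nansum(nb_mask, axis=0) > 0
    warn_ctx.__exit__(None, None, None)
    out = dc_replace(
        field,
        u_px=u_new,
        v_px=v_new,
        snr=snr_new,
        valid=dom & (~flagged | (flagged & has_donor)),
        replaced=flagged,
    )
    return out, rate
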