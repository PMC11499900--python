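"""Pipeline orchestration: stage execution, artifact I/O, run report.

Stages: ``simulate`` (loop sensor log), ``generate`` (synthetic image
pairs), ``piv`` (vector fields), ``metrics`` (derived quantities).  Each
stage reads its predecessor's artifacts from the output directory, so
stages can be re-run independently; everything is deterministic given the
configured seed.

Artifact formats: sensor logs and vector fields as CSV, images as 16-bit
TIFF, masks as 8-bit PNG, the run report as JSON.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig, config_hash
from .geometry import IdealizedAAAGeometry, lumen_mask
from .hemodynamics import FluidProperties, physiological_waveform
from .loop import (
    CompliantSegment,
    HybridUnitConfig,
    SensorLog,
    WindkesselParams,
    run_loop,
)
from .metrics import M3S_TO_LMIN, flow_balance, flow_rate_from_profile
from .piv import ValidationConfig, VectorField, piv_multipass, preprocess, validate_vectors
from .synth import CameraModel, IlluminationConfig, generate_dataset
from .workflows import ROI1_BAND_MM, womersley_sampler

__all__ = ["run_pipeline", "write_sensor_log", "read_sensor_log",
           "write_vector_field", "read_vector_field"]

STAGES = ("simulate", "generate", "piv", "metrics")

SENSOR_COLUMNS = ["time_s", "q_in_m3s", "q_out1_m3s", "p_chamber_pa",
                  "p_in_pa", "p_out_pa"]


def write_sensor_log(log: SensorLog, path: Path) -> None:
    df = pd.DataFrame({
        "time_s": log.time,
        "q_in_m3s": log.q_in,
        "q_out1_m3s": log.q_out[:, 0],
        "p_chamber_pa": log.p_chamber,
        "p_in_pa": log.p_in,
        "p_out_pa": log.p_out,
    })
    df.to_csv(path, index=False, float_format="%.10e")


def read_sensor_log(path: Path, metadata: dict | None = None) -> SensorLog:
    df = pd.read_csv(path)
    return SensorLog(
        time=df["time_s"].to_numpy(),
        q_in=df["q_in_m3s"].to_numpy(),
        q_out=df["q_out1_m3s"].to_numpy()[:, None],
        p_chamber=df["p_chamber_pa"].to_numpy(),
        p_in=df["p_in_pa"].to_numpy(),
        p_out=df["p_out_pa"].to_numpy(),
        metadata=metadata or {},
    )


def write_vector_field(field: VectorField, path: Path) -> None:
    yy, xx = np.meshgrid(field.y_px, field.x_px, indexing="ij")
    df = pd.DataFrame({
        "x_px": xx.ravel(),
        "y_px": yy.ravel(),
        "x_mm": xx.ravel() / field.scale,
        "y_mm": yy.ravel() / field.scale,
        "u_ms": field.u_ms.ravel(),
        "v_ms": field.v_ms.ravel(),
        "snr": field.snr.ravel(),
        "in_domain": field.in_domain.ravel().astype(int),
        "valid": field.valid.ravel().astype(int),
        "replaced": field.replaced.ravel().astype(int),
    })
    df.to_csv(path, index=False, float_format="%.8e")


def read_vector_field(
    path: Path, scale: float, dt_s: float
) -> VectorField:
    df = pd.read_csv(path)
    x = np.unique(df["x_px"].to_numpy())
    y = np.unique(df["y_px"].to_numpy())
    shape = (y.size, x.size)
    to_px = lambda col: (
        df[col].to_numpy().reshape(shape) * scale * 1e3 * dt_s
    )
    return VectorField(
        x_px=x, y_px=y,
        u_px=to_px("u_ms"), v_px=to_px("v_ms"),
        snr=df["snr"].to_numpy().reshape(shape),
        in_domain=df["in_domain"].to_numpy().reshape(shape).astype(bool),
        valid=df["valid"].to_numpy().reshape(shape).astype(bool),
        replaced=df["replaced"].to_numpy().reshape(shape).astype(bool),
        scale=scale, dt_s=dt_s,
    )


def _geometry(config: RunConfig) -> IdealizedAAAGeometry:
    g = config.geometry
    return IdealizedAAAGeometry(
        d=g.d_mm, aspect_ratio=g.aspect_ratio, dilation_ratio=g.dilation_ratio,
        total_length=g.total_length_mm, wall_thickness=g.wall_thickness_mm,
    )


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages and return the run report.

    Raises a ``FileNotFoundError`` naming the stage to run first when an
    upstream artifact is missing.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config_hash(config),
        "flow_case": config.flow_case,
        "illumination": config.illumination,
        "seed": config.seed,
        "stages": {},
    }
    report_path = out / "report.json"
    if report_path.exists():
        report["stages"] = json.loads(report_path.read_text()).get("stages", {})

    geom = _geometry(config)
    fluid = FluidProperties(
        kinematic_viscosity=config.fluid.kinematic_viscosity_mm2s,
        density=config.fluid.density_kgm3,
    )
    wave = physiological_waveform(config.flow_case)
    shape = (config.camera.rows_px, config.camera.cols_px)
    scale = config.camera.scale_px_mm
    x0 = -geom.total_length / 2.0 + 4.0  # ROI1 left edge, just past inlet
    window = (x0, x0 + shape[1] / scale)
    camera = CameraModel(
        shape=shape, scale=scale, exposure_us=config.camera.exposure_us,
        min_interframe_us=config.camera.min_interframe_us,
    )
    illum = IlluminationConfig.from_label(config.illumination)

    if "simulate" in stages:
        t0 = time.perf_counter()
        log = run_loop(
            wave,
            WindkesselParams.from_case(config.flow_case),
            HybridUnitConfig(),
            CompliantSegment(),
            n_cycles=config.simulate.n_cycles,
            seed=config.seed,
            flowmeter_delay=config.simulate.flowmeter_delay_ms * 1e-3,
        )
        write_sensor_log(log, out / "sensor_log.csv")
        report["stages"]["simulate"] = {
            "n_cycles": config.simulate.n_cycles,
            "p_chamber_range_pa": [float(log.p_chamber.min()),
                                   float(log.p_chamber.max())],
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }

    if "generate" in stages:
        t0 = time.perf_counter()
        mask = lumen_mask(geom, window, scale, shape)
        iio.imwrite(out / "mask.png", (mask * 255).astype(np.uint8))
        sampler = womersley_sampler(wave, geom.d * 1e-3, fluid)
        seq = generate_dataset(
            sampler, mask, window, camera, illum,
            period_s=wave.period,
            n_cycles=config.generate.n_cycles,
            pairs_per_cycle=config.generate.pairs_per_cycle,
            seed=config.seed,
            density_per_mm2=config.generate.density_per_mm2,
            sheet_thickness_mm=config.generate.sheet_thickness_mm,
            cycle_jitter=config.generate.cycle_jitter,
        )
        times = []
        for pair in seq.pairs:
            c, p = pair.metadata["cycle"], pair.metadata["phase"]
            tifffile.imwrite(out / f"c{c:03d}_p{p:02d}_a.tif", pair.frame_a)
            tifffile.imwrite(out / f"c{c:03d}_p{p:02d}_b.tif", pair.frame_b)
            gt = pd.DataFrame({
                "x_px": np.repeat(pair.gt_x_px, pair.gt_y_px.size),
                "y_px": np.tile(pair.gt_y_px, pair.gt_x_px.size),
                "u_px": pair.gt_u_px.T.ravel(),
                "v_px": pair.gt_v_px.T.ravel(),
            })
            gt.to_csv(out / f"c{c:03d}_p{p:02d}_gt.csv", index=False,
                      float_format="%.6e")
            times.append(dict(cycle=c, phase=p, t_s=pair.t_s))
        (out / "sequence.json").write_text(json.dumps({
            "pair_interval_s": seq.pair_interval_s,
            "pairs_per_cycle": seq.pairs_per_cycle,
            "illumination": illum.label,
            "tau_us": illum.tau_us,
            "dt_us": illum.dt_us,
            "window_mm": list(window),
            "scale_px_mm": scale,
            "pairs": times,
        }, indent=1))
        report["stages"]["generate"] = {
            "n_pairs": len(seq.pairs),
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }

    if "piv" in stages:
        t0 = time.perf_counter()
        seq_meta_path = out / "sequence.json"
        if not seq_meta_path.exists():
            raise FileNotFoundError(
                "no generated sequence found: run the 'generate' stage first"
            )
        meta = json.loads(seq_meta_path.read_text())
        mask = iio.imread(out / "mask.png") > 127
        frames = []
        for rec in meta["pairs"]:
            c, p = rec["cycle"], rec["phase"]
            frames.append(tifffile.imread(out / f"c{c:03d}_p{p:02d}_a.tif"))
            frames.append(tifffile.imread(out / f"c{c:03d}_p{p:02d}_b.tif"))
        filtered, _ = preprocess(np.stack(frames).astype(float))
        validation = ValidationConfig(
            snr_min=config.piv.snr_min, global_k=config.piv.global_k,
            median_k=config.piv.median_k,
        )
        rates = []
        for i, rec in enumerate(meta["pairs"]):
            raw = piv_multipass(
                filtered[2 * i], filtered[2 * i + 1], mask=mask,
                passes=tuple(config.piv.passes_px), overlap=config.piv.overlap,
                scale=meta["scale_px_mm"], dt_s=meta["dt_us"] * 1e-6,
                validation=validation,
            )
            fld, rate = validate_vectors(raw, validation)
            rates.append(rate)
            c, p = rec["cycle"], rec["phase"]
            write_vector_field(fld, out / f"c{c:03d}_p{p:02d}_vec.csv")
        report["stages"]["piv"] = {
            "n_pairs": len(meta["pairs"]),
            "mean_invalid_rate": float(np.mean(rates)),
            "max_invalid_rate": float(np.max(rates)),
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }

    if "metrics" in stages:
        t0 = time.perf_counter()
        seq_meta_path = out / "sequence.json"
        if not seq_meta_path.exists():
            raise FileNotFoundError(
                "no generated sequence found: run the 'generate' stage first"
            )
        meta = json.loads(seq_meta_path.read_text())
        vec_paths = sorted(out.glob("c*_p*_vec.csv"))
        if not vec_paths:
            raise FileNotFoundError(
                "no vector fields found: run the 'piv' stage first"
            )
        rows = []
        for rec in meta["pairs"]:
            c, p = rec["cycle"], rec["phase"]
            path = out / f"c{c:03d}_p{p:02d}_vec.csv"
            if not path.exists():
                continue
            fld = read_vector_field(path, meta["scale_px_mm"],
                                    meta["dt_us"] * 1e-6)
            q = flow_rate_from_profile(
                fld, ROI1_BAND_MM, geom.d / 2.0,
                axis_row_px=config.camera.rows_px / 2.0,
            )
            q_true = float(wave(rec["t_s"]))
            rows.append({
                "cycle": c, "phase": p, "t_s": rec["t_s"],
                "q_piv_m3s": q, "q_true_m3s": q_true,
                "q_piv_lmin": q * M3S_TO_LMIN,
                "q_true_lmin": q_true * M3S_TO_LMIN,
            })
        qdf = pd.DataFrame(rows)
        qdf.to_csv(out / "flow_rate.csv", index=False, float_format="%.8e")
        summary = {
            "max_q_error_lmin": float(
                np.max(np.abs(qdf["q_piv_lmin"] - qdf["q_true_lmin"]))
            ),
        }
        log_path = out / "sensor_log.csv"
        if log_path.exists():
            log = read_sensor_log(
                log_path,
                {"flowmeter_delay_s": config.simulate.flowmeter_delay_ms * 1e-3},
            )
            _, dq_mean, _ = flow_balance(
                log, wave.period, lowpass_hz=config.simulate.lowpass_hz
            )
            summary["max_abs_dq_lmin"] = float(
                np.max(np.abs(dq_mean)) * M3S_TO_LMIN
            )
        report["stages"]["metrics"] = {
            **summary, "elapsed_s": round(time.perf_counter() - t0, 2),
        }

    report_path.write_text(json.dumps(report, indent=1))
    return report
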