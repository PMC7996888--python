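"""End-to-end orchestration: equalize -> binarize -> fronts -> trajectories ->
statistics -> fits, with artifacts written to an output directory.

The stages can also be driven individually through the CLI; every number in
the rendered fit/comparison tables comes from a CSV written by the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import yaml

from woundtrack import edge_extraction, frame_io, model_fitting, spt_statistics
from woundtrack import synthetic as synth
from woundtrack import texture_segmentation as texseg
from woundtrack.errors import SegmentationError, ValidationError, WoundTrackError
from woundtrack.pseudo_particles import (
    build_trajectories,
    wound_area_series,
)

logger = logging.getLogger(__name__)

SIDES = ("L", "R")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    input: str | None = None
    synthetic: dict | None = None
    imagej_dir: str | None = None
    out_dir: str = "results"
    method: str = "texture"           # texture | otsu | imagej
    side: str = "both"                # L | R | both
    frame_interval_h: float = 0.25
    pixel_size: float = 1.0
    frame_range: list | None = None   # [start, stop, stride]
    clahe: dict = field(default_factory=lambda: {"tile_size": [50, 50], "clip_limit": 40})
    lbp: dict = field(default_factory=lambda: {"tile_height": 12, "tile_width": 16})
    pca: dict = field(default_factory=lambda: {"n_components": 5})
    gmm: dict = field(default_factory=lambda: {"seed": 0, "covariance": "full"})
    labeling: dict = field(default_factory=lambda: {"mode": "auto"})
    classifier_scope: str = "per_frame"  # per_frame | first_frame
    otsu: dict = field(default_factory=lambda: {"blur_sigma": 2.0, "morph_radius": 5})
    tracking: dict = field(default_factory=lambda: {"n_particles": 103})
    fit: dict = field(default_factory=lambda: {"window": None})
    save_masks: bool = True
    save_equalized: bool = False

    @classmethod
    def from_dict(cls, data):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.method not in ("texture", "otsu", "imagej"):
            raise ValidationError(f"unknown method {cfg.method!r}")
        if cfg.side not in ("L", "R", "both"):
            raise ValidationError(f"side must be L, R, or both, got {cfg.side!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sides(self):
        return SIDES if self.side == "both" else (self.side,)


# ---------------------------------------------------------------- stages


def stage_load(cfg):
    """Load the input stack or generate the synthetic one."""
    if cfg.synthetic is not None:
        spec = synth.SyntheticWoundSpec(**cfg.synthetic)
        spec.frame_interval = cfg.frame_interval_h
        stack, truth = synth.generate_dataset(spec)
        stack.pixel_size = cfg.pixel_size
        return stack, truth
    if cfg.input is None:
        raise ValidationError("config needs either 'input' or 'synthetic'")
    stack = frame_io.load_time_lapse(
        cfg.input, frame_interval=cfg.frame_interval_h, pixel_size=cfg.pixel_size
    )
    if cfg.frame_range:
        start, stop, stride = (list(cfg.frame_range) + [None, 1])[:3]
        stack = stack.subset(start or 0, stop, stride or 1)
    return stack, None


def stage_equalize(stack, cfg):
    tile = tuple(cfg.clahe.get("tile_size", [50, 50]))
    clip = cfg.clahe.get("clip_limit", 40)
    return frame_io.equalize_stack(stack, tile_size=tile, clip_limit=clip)


def stage_binarize(stack, cfg):
    """Texture or Otsu binarization of every (equalized) frame."""
    masks = []
    if cfg.method == "otsu":
        for k, frame in enumerate(stack):
            masks.append(edge_extraction.otsu_segment(
                frame,
                blur_sigma=cfg.otsu.get("blur_sigma", 2.0),
                morph_radius=cfg.otsu.get("morph_radius", 5),
                frame_index=k,
            ))
        return masks
    grid = texseg.tessellate(
        stack[0], cfg.lbp.get("tile_height", 12), cfg.lbp.get("tile_width", 16)
    )
    classifier = None
    for k, frame in enumerate(stack):
        if classifier is None or cfg.classifier_scope == "per_frame":
            feats = texseg.extract_features(texseg.lbp_image(frame), grid)
            classifier = texseg.fit_texture_classifier(
                feats,
                n_pca=cfg.pca.get("n_components", 5),
                seed=cfg.gmm.get("seed", 0),
                covariance_type=cfg.gmm.get("covariance", "full"),
                labeling=cfg.labeling.get("mode", "auto"),
            )
        masks.append(texseg.binarize_frame(frame, classifier, grid, frame_index=k))
    return masks


def stage_fronts(masks, frame_shape, warnings_out=None):
    """Extract L/R fronts per frame; truncate at the first merged-front frame."""
    fronts = {"L": [], "R": []}
    h, w = frame_shape
    for k, mask in enumerate(masks):
        try:
            contours = edge_extraction.extract_wound_contour(mask, frame_index=k)
            fl, fr = edge_extraction.split_fronts(contours, w, h, frame_index=k)
        except SegmentationError as exc:
            msg = f"front extraction stopped at frame {k}: {exc}"
            logger.warning(msg)
            if warnings_out is not None:
                warnings_out.append(msg)
            break
        fronts["L"].append(fl)
        fronts["R"].append(fr)
    if not fronts["L"]:
        raise SegmentationError("no frame yielded a wound front")
    return fronts


def fronts_from_imagej(directory, n_frames=None):
    """Read hand-traced fronts named front_{L|R}_{k:03d}.txt from a directory."""
    directory = Path(directory)
    fronts = {"L": [], "R": []}
    k = 0
    while n_frames is None or k < n_frames:
        paths = {s: directory / f"front_{s}_{k:03d}.txt" for s in SIDES}
        if not all(p.exists() for p in paths.values()):
            break
        for s in SIDES:
            fronts[s].append(edge_extraction.read_imagej_front(paths[s], s, k))
        k += 1
    if not fronts["L"]:
        raise ValidationError(f"no front files found in {directory}")
    return fronts


def stage_statistics(traj, frame_width):
    """Centered/mirrored SPT statistics for one side as a tidy DataFrame."""
    if traj.side == "R" and not traj.mirrored:
        traj = spt_statistics.mirror_right_front(traj, frame_width)
    traj = spt_statistics.center_initial_position(traj)
    dt = traj.frame_interval
    x = traj.x
    v = spt_statistics.velocity(x)
    a = spt_statistics.acceleration(v)
    series = {
        "mean_X": spt_statistics.ensemble_mean(x),
        "mean_V": spt_statistics.ensemble_mean(v),
        "mean_A": spt_statistics.ensemble_mean(a),
        "acf_X": spt_statistics.ensemble_acf(x),
        "acf_V": spt_statistics.ensemble_acf(v),
        "msd_X": spt_statistics.mean_squared_displacement(x),
        "msd_V": spt_statistics.mean_squared_displacement(v),
        "std_A": spt_statistics.ensemble_std_series(a),
    }
    rows = []
    for name, vals in series.items():
        for k, val in enumerate(np.asarray(vals)):
            rows.append({
                "quantity": name, "side": traj.side, "lag_or_frame": k,
                "time_h": k * dt, "value": float(val),
            })
    return traj, series, pd.DataFrame(rows)


def stage_fits(traj, series, cfg, warnings_out=None):
    """Drift fit on the mean position and tail fits on |dV| for one side."""
    dt = traj.frame_interval
    times = np.arange(traj.n_frames) * dt
    mean_x = series["mean_X"]
    window = cfg.fit.get("window")
    if window is None:
        window = model_fitting.detect_drift_window(mean_x, times)
    drift = model_fitting.fit_drift(mean_x, times, tuple(window))
    a = spt_statistics.acceleration(spt_statistics.velocity(traj.x))
    a_times = (np.arange(a.shape[1]) + 1) * dt  # A(tau) uses frames tau..tau+2
    in_win = (a_times > window[0]) & (a_times < window[1])
    abs_dv = np.abs(a[:, in_win]).ravel() if in_win.any() else np.abs(a).ravel()
    tails = None
    try:
        tails = model_fitting.fit_increment_tails(abs_dv)
    except WoundTrackError as exc:
        msg = f"tail fit skipped for side {traj.side}: {exc}"
        logger.warning(msg)
        if warnings_out is not None:
            warnings_out.append(msg)
    return drift, tails


# ---------------------------------------------------------------- outputs


def _write_masks(masks, out):
    out.mkdir(parents=True, exist_ok=True)
    for mask in masks:
        iio.imwrite(out / f"mask_{mask.frame_index:03d}.png",
                    (mask.mask.astype(np.uint8) * 255))


def _write_fronts(fronts, out):
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for side, flist in fronts.items():
        for front in flist:
            edge_extraction.write_front(
                front, out / f"front_{side}_{front.frame_index:03d}.txt")
            for i, (x, y) in enumerate(front.points):
                rows.append({"frame": front.frame_index, "side": side,
                             "point_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(out.parent / "fronts.csv", index=False)


def _write_trajectories(traj, out_dir):
    n, m = traj.x.shape
    particles, frames = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    df = pd.DataFrame({
        "side": traj.side,
        "particle": particles.ravel(),
        "frame": frames.ravel(),
        "x": traj.x.ravel(),
        "y": traj.y.ravel(),
    })
    df.to_csv(out_dir / f"trajectories_{traj.side}.csv", index=False)


def _fit_rows(side, drift, tails):
    rows = [{
        "side": side, "model": drift.model,
        "param": "vd", "estimate": drift.params["vd"], "se": drift.std_errors["vd"],
        "adj_r_squared": drift.adj_r_squared, "window_low": drift.window[0],
        "window_high": drift.window[1], "n_points": drift.n_points,
    }, {
        "side": side, "model": drift.model,
        "param": "tau1", "estimate": drift.params["tau1"],
        "se": drift.std_errors["tau1"],
        "adj_r_squared": drift.adj_r_squared, "window_low": drift.window[0],
        "window_high": drift.window[1], "n_points": drift.n_points,
    }]
    if tails is not None:
        for res in tails:
            (pname, pval), = res.params.items()
            rows.append({
                "side": side, "model": res.model, "param": pname,
                "estimate": pval, "se": res.std_errors[pname],
                "adj_r_squared": res.adj_r_squared,
                "window_low": res.window[0], "window_high": res.window[1],
                "n_points": res.n_points,
            })
    return rows


def run_pipeline(cfg):
    """Execute all stages and write artifacts under ``cfg.out_dir``.

    Returns the run report (also written as ``run_report.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config": dataclasses.asdict(cfg), "stages": [], "warnings": []}
    warns = report["warnings"]

    def record(stage, **info):
        report["stages"].append({"stage": stage, "status": "ok", **info})

    try:
        stack, _truth = stage_load(cfg)
        record("load", n_frames=len(stack), shape=[stack.height, stack.width])

        if cfg.pixel_size == 1.0:
            warns.append("pixel_size defaulted to 1.0: positions are in px, "
                         "velocities in px/h")

        if cfg.method == "imagej":
            if cfg.imagej_dir is None:
                raise ValidationError("method=imagej requires imagej_dir")
            fronts = fronts_from_imagej(cfg.imagej_dir, n_frames=len(stack))
            record("fronts", n_frames=len(fronts["L"]), source="imagej")
        else:
            equalized = stage_equalize(stack, cfg)
            record("equalize", n_frames=len(equalized))
            if cfg.save_equalized:
                frame_io.write_stack(equalized, out / "equalized.tif")
            masks = stage_binarize(equalized, cfg)
            record("binarize", n_frames=len(masks), method=cfg.method)
            if cfg.save_masks:
                _write_masks(masks, out / "masks")
            fronts = stage_fronts(masks, (stack.height, stack.width), warns)
            record("fronts", n_frames=len(fronts["L"]), source=cfg.method)

        _write_fronts(fronts, out / "fronts")

        m = len(fronts["L"])
        area = wound_area_series(fronts["L"], fronts["R"],
                                 frame_interval=cfg.frame_interval_h)
        pd.DataFrame({
            "frame": np.arange(m),
            "time_h": np.arange(m) * cfg.frame_interval_h,
            "normalized_area": area,
        }).to_csv(out / "area.csv", index=False)

        n_particles = cfg.tracking.get("n_particles", 103)
        stats_frames, fit_rows = [], []
        for side in cfg.sides():
            traj = build_trajectories(
                fronts[side], n=n_particles,
                frame_interval=cfg.frame_interval_h, pixel_size=cfg.pixel_size,
            )
            _write_trajectories(traj, out)
            traj_c, series, stats_df = stage_statistics(traj, stack.width)
            stats_frames.append(stats_df)
            try:
                drift, tails = stage_fits(traj_c, series, cfg, warns)
                fit_rows.extend(_fit_rows(side, drift, tails))
            except WoundTrackError as exc:
                warns.append(f"drift fit failed for side {side}: {exc}")
            record("track_stats", side=side, n_particles=n_particles, n_frames=m)

        pd.concat(stats_frames).to_csv(out / "statistics.csv", index=False)
        if fit_rows:
            pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        report["status"] = "ok"
    except WoundTrackError as exc:
        report["status"] = "failed"
        report["error"] = str(exc)
        _dump_report(report, out)
        raise
    _dump_report(report, out)
    return report


def _dump_report(report, out):
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


COMPARE_VARIABLES = ("x_coords", "y_coords", "mean_X", "mean_V", "mean_A")


def _traj_arrays(run_dir, side):
    path = Path(run_dir) / f"trajectories_{side}.csv"
    if not path.exists():
        raise ValidationError(f"missing {path}")
    df = pd.read_csv(path)
    n = df["particle"].nunique()
    m = df["frame"].nunique()
    df = df.sort_values(["particle", "frame"])
    return (df["x"].to_numpy().reshape(n, m), df["y"].to_numpy().reshape(n, m))


def compare_runs(run_a, run_b, sides=SIDES, frame_interval=0.25):
    """Table-3-style Pearson comparison of two runs' trajectory sets."""
    rows = []
    for side in sides:
        xa, ya = _traj_arrays(run_a, side)
        xb, yb = _traj_arrays(run_b, side)
        if xa.shape != xb.shape:
            raise ValidationError(
                f"run shapes differ for side {side}: {xa.shape} vs {xb.shape}"
            )
        pairs = {
            "x_coords": (xa, xb),
            "y_coords": (ya, yb),
            "mean_X": (spt_statistics.ensemble_mean(xa),
                       spt_statistics.ensemble_mean(xb)),
            "mean_V": (spt_statistics.ensemble_mean(spt_statistics.velocity(xa)),
                       spt_statistics.ensemble_mean(spt_statistics.velocity(xb))),
            "mean_A": (
                spt_statistics.ensemble_mean(
                    spt_statistics.acceleration(spt_statistics.velocity(xa))),
                spt_statistics.ensemble_mean(
                    spt_statistics.acceleration(spt_statistics.velocity(xb))),
            ),
        }
        for name, (a, b) in pairs.items():
            res = model_fitting.compare_methods(a, b, variable=name)
            rows.append({"side": side, "variable": name,
                         "pearson_r": res.pearson_r, "p_value": res.p_value,
                         "n": res.n})
    return pd.DataFrame(rows)
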