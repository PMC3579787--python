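"""End-to-end orchestration: image directory → measurements, overlays, QC.

Each image runs through the same deterministic chain: illumination
correction, Minimum-threshold segmentation, area filtering, thinning,
pruning to a single path (objects with cyclic skeletons auto-fail),
prune-ratio filtering, tangent extension and radius-profile measurement.
Review is non-interactive: a ``review.csv`` sidecar (image, worm id,
pass/fail) can be edited by hand and applied to filter the measurement
table, replacing an interactive pass/fail screen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import image_io, measure, preprocess, segment, skeletonize
from .image_io import IntensityImage, MeasurementRecord, RunConfig

__all__ = ["WormObject", "process_image", "run_pipeline", "apply_review"]

log = logging.getLogger("nemameter")


@dataclass
class WormObject:
    """One segmented candidate and everything derived from it."""

    worm_id: str
    mask: np.ndarray = field(repr=False)
    contour: np.ndarray = field(repr=False)
    area_px2: int = 0
    skeleton_path: skeletonize.SkeletonPath | None = None
    radius_profile: measure.RadiusProfile | None = None
    measurement: measure.WormMeasurement | None = None
    passed: bool = False
    fail_reason: str | None = None


def process_image(image: IntensityImage, config: RunConfig,
                  image_name: str = "image") -> list[WormObject]:
    """Run the full measurement chain on one image.

    Raises :class:`segment.NoThresholdError` if the corrected image has no
    bimodal histogram (callers log and skip such images).
    """
    corrected = preprocess.subtract_background(
        image, ball_radius_px=config.ball_radius_px,
        light_background=config.light_background)
    thr = segment.minimum_threshold(segment.intensity_histogram(corrected))
    mask = segment.apply_threshold(corrected, thr.t)
    candidates = segment.area_filter(
        segment.connected_components(mask),
        config.area_min_px2, config.area_max_px2)
    log.info("%s: threshold t=%d (%d smoothing passes), %d candidate(s)",
             image_name, thr.t, thr.smoothing_iterations, len(candidates))

    worms = []
    for i, cand in enumerate(candidates):
        worm = WormObject(worm_id=f"{image_name}:w{i}", mask=cand.mask,
                          contour=cand.contour, area_px2=cand.area_px2)
        worms.append(worm)
        try:
            skel = skeletonize.thin_mask(cand.mask)
            path = skeletonize.prune_to_path(skel)
        except skeletonize.SkeletonCycleError:
            worm.fail_reason = "skeleton-cycle"
            continue
        if not skeletonize.ratio_filter(path, config.prune_ratio_min):
            worm.skeleton_path = path
            worm.fail_reason = (f"prune-ratio {path.prune_ratio:.3f} < "
                                f"{config.prune_ratio_min}")
            continue
        try:
            path = skeletonize.smooth_path(path)
            path = skeletonize.extend_to_edges(
                path, cand.mask, extension_window_px=config.extension_window_px)
            worm.skeleton_path = path
            worm.radius_profile = measure.sample_radii(
                cand.mask, path, config.interval_px,
                tangent_window_px=config.extension_window_px)
            scale = image.scale if image.scale else 1.0
            worm.measurement = _measurement_from_profile(
                worm.radius_profile, scale)
            worm.passed = True
        except (ValueError, measure.MeasurementError) as exc:
            worm.fail_reason = f"measurement: {exc}"
    return worms


def _measurement_from_profile(profile, scale):
    length = float(profile.s[-1])
    interior = profile.r[1:-1]
    avg_width = float(2.0 * interior.mean()) if len(interior) else 0.0
    mid_idx = int(np.argmin(np.abs(profile.s - length / 2.0)))
    mid_width = float(2.0 * profile.r[mid_idx])
    return measure.WormMeasurement(
        length_px=length, avg_width_px=avg_width, mid_width_px=mid_width,
        volume_px3=measure.frustum_volume(profile),
        cylinder_volume_px3=measure.cylinder_volume(length, mid_width),
        scale_um_per_px=scale)


def _resolve_scale(image_path: Path, scale_source) -> float:
    if isinstance(scale_source, (int, float)):
        return float(scale_source)
    if isinstance(scale_source, dict):  # per-image map
        key = image_path.name
        if key not in scale_source:
            raise ValueError(f"no scale recorded for image {key}")
        return float(scale_source[key])
    raise TypeError("scale_source must be a number or an image→scale map")


def run_pipeline(image_dir, config: RunConfig, scale_source,
                 out_dir) -> dict:
    """Process every supported image in a directory.

    Writes ``measurements.csv``, a ``review.csv`` template, per-worm
    overlay PNGs and ``manifest.json`` into ``out_dir``; returns the
    manifest dict.  Unreadable or non-bimodal images are logged and
    skipped.
    """
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "overlays").mkdir(exist_ok=True)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in image_io._SUPPORTED_SUFFIXES)
    if not paths:
        raise IOError(f"no supported images in {image_dir}")

    from . import __version__

    settings = json.dumps(config.to_dict(), sort_keys=True)
    records, manifest_images = [], {}
    for path in paths:
        try:
            img = image_io.load_image(path)
            img.scale = _resolve_scale(path, scale_source)
        except (IOError, ValueError) as exc:
            log.warning("skipping %s: %s", path.name, exc)
            manifest_images[path.name] = {"status": f"skipped: {exc}"}
            continue
        try:
            worms = process_image(img, config, image_name=path.stem)
        except segment.NoThresholdError as exc:
            log.warning("skipping %s: %s", path.name, exc)
            manifest_images[path.name] = {"status": f"no-threshold: {exc}"}
            continue
        outcomes = {}
        for worm in worms:
            if worm.passed:
                outcomes[worm.worm_id] = "measured"
                m = worm.measurement
                records.append(MeasurementRecord(
                    image_file=path.name, worm_id=worm.worm_id, pass_flag=True,
                    length_um=m.length_um, avg_width_um=m.avg_width_um,
                    mid_width_um=m.mid_width_um, volume_pl=m.volume_pl,
                    cylinder_volume_pl=m.cylinder_volume_pl,
                    scale_um_per_px=m.scale_um_per_px,
                    settings_echo=settings))
                overlay = image_io.render_overlay(img, worm)
                image_io.save_image(
                    overlay,
                    out_dir / "overlays" / f"{worm.worm_id.replace(':', '_')}.png")
            else:
                outcomes[worm.worm_id] = f"auto-failed:{worm.fail_reason}"
        manifest_images[path.name] = {"status": "processed",
                                      "candidates": len(worms),
                                      "worms": outcomes}

    image_io.write_measurements(records, out_dir / "measurements.csv")
    pd.DataFrame(
        {"image_file": [r.image_file for r in records],
         "worm_id": [r.worm_id for r in records],
         "pass": ["pass"] * len(records)},
    ).to_csv(out_dir / "review.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "images": manifest_images,
        "n_measured": len(records),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def apply_review(measurements_csv, review_csv, out_csv) -> int:
    """Drop measurement rows a reviewer marked as ``fail``.

    Returns the number of surviving rows.  Review rows referencing unknown
    worm ids raise, listing the offending ids.
    """
    meas = pd.read_csv(measurements_csv)
    review = pd.read_csv(review_csv)
    known = set(meas["worm_id"])
    unknown = sorted(set(review["worm_id"]) - known)
    if unknown:
        raise ValueError(f"review references unknown worm ids: {unknown}")
    verdict = {w: str(v).strip().lower()
               for w, v in zip(review["worm_id"], review["pass"])}
    keep = meas["worm_id"].map(lambda w: verdict.get(w, "pass") != "fail")
    kept = meas[keep].copy()
    kept["pass_flag"] = True
    kept.to_csv(out_csv, index=False)
    return len(kept)
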