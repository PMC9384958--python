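"""End-to-end orchestration: simulate -> analyze -> calibrate -> quantify.

Runs the whole workflow a strip reader performs over a dilution series:
render (or accept) one strip image per concentration and replicate, analyse
each image to its three ratios, summarise replicates, fit the quadratic
calibration curve, estimate the detection limit from noise-free strips, and
quantify every strip back through the fitted curve with a risk label. The
summary is plain JSON-serialisable data and is byte-stable for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

from .calibrate import (
    classify_risk,
    estimate_concentration,
    fit_calibration,
    lod_estimate,
    replicate_stats,
)
from .config import RunConfig
from .detect import analyze_strip
from .errors import CalibrationError, LfaQuantError, PipelineStageError
from .phantom import dilution_series, render_strip

__all__ = ["run_end_to_end", "noise_free_ratio_fn", "measurement_record"]

log = logging.getLogger("lfaquant")


def noise_free_ratio_fn(cfg: RunConfig):
    """Concentration -> pipeline ratio on a noise-free, jitter-free phantom.

    This is the idealised response of the full analysis chain (render,
    average, smooth, detect, ratio), used for the detection-limit rule.
    """
    phantom_cfg = cfg.phantom.noise_free()

    def fn(concentration: float) -> float:
        img, _ = render_strip(concentration, phantom_cfg, seed=0)
        m = analyze_strip(img, phantom_cfg.roi, cfg.detection, keep_audit=False)
        return m.ratio(cfg.ratio_kind)

    return fn


def measurement_record(m, truth=None) -> dict:
    """Flatten a StripMeasurement (and optional phantom truth) to JSON data."""
    rec = {
        "control_pos": m.control_pos,
        "control_value": m.control_value,
        "test_pos": m.test_pos,
        "test_value": m.test_value,
        "background_mean": m.background_mean,
        "background_sd": m.background_sd,
        "ratio_tb": m.ratio_tb,
        "ratio_cb": m.ratio_cb,
        "ratio_tc": m.ratio_tc,
        "flags": sorted(m.flags),
    }
    if truth is not None:
        rec.update(
            {
                "concentration_ng_ml": truth.concentration,
                "seed": truth.seed,
                "true_test_center": truth.true_test_center,
                "true_control_center": truth.true_control_center,
                "true_test_depth": truth.true_test_depth,
                "true_control_depth": truth.true_control_depth,
            }
        )
    return rec


def run_end_to_end(cfg: RunConfig, out_dir: str | os.PathLike | None = None) -> dict:
    """Simulate a dilution ladder and push it through the full pipeline.

    Returns a summary dict with one record per strip (measured ratios,
    estimated concentration, censoring and risk label), the replicate table,
    the fitted calibration curve, and the detection limit. With fewer than 3
    distinct concentrations the calibration step is refused and the summary
    carries the per-strip measurements only. If ``out_dir`` is given the
    summary and the resolved config are written there.
    """
    cfg_hash = cfg.content_hash()
    t0 = time.monotonic()
    log.info("run start: %d concentrations x %d replicates, config %s",
             len(cfg.concentrations), cfg.replicates, cfg_hash)

    strips = dilution_series(
        cfg.concentrations, cfg.replicates, cfg.phantom, cfg.seed
    )

    measurements, records = [], []
    for idx, (img, truth) in enumerate(strips):
        try:
            m = analyze_strip(img, cfg.phantom.roi, cfg.detection, keep_audit=False)
        except PipelineStageError as exc:
            raise LfaQuantError(
                f"strip {idx} (c={truth.concentration} ng/ml, seed={truth.seed}) "
                f"failed at {exc.stage}: {exc.original}"
            ) from exc
        measurements.append(m)
        rec = measurement_record(m, truth)
        rec["strip_id"] = idx
        rec["config_hash"] = cfg_hash
        records.append(rec)
    log.info("analysed %d strips in %.2fs", len(records), time.monotonic() - t0)

    labels = [r["concentration_ng_ml"] for r in records]
    points = replicate_stats(measurements, labels, cfg.ratio_kind)
    summary: dict = {
        "config_hash": cfg_hash,
        "n_strips": len(records),
        "strips": records,
        "replicate_table": [dataclasses.asdict(p) for p in points],
        "calibration": None,
        "lod_ng_ml": None,
    }

    try:
        curve = fit_calibration(points, cfg.ratio_kind, cfg.working_range)
    except CalibrationError as exc:
        log.warning("calibration refused: %s", exc)
        summary["calibration_refused"] = str(exc)
        curve = None

    if curve is not None:
        summary["calibration"] = {
            "coeffs": list(curve.coeffs),
            "working_lo": curve.working_lo,
            "working_hi": curve.working_hi,
            "residual_rmse": curve.residual_rmse,
            "ratio_kind": curve.ratio_kind,
        }
        lod = lod_estimate(
            noise_free_ratio_fn(cfg), cfg.lod_sigma_r, cfg.lod_k, cfg.lod_grid
        )
        summary["lod_ng_ml"] = lod
        for rec, m in zip(records, measurements):
            q = estimate_concentration(curve, m.ratio(cfg.ratio_kind))
            risk, band = classify_risk(
                q.estimated_concentration, cfg.high_threshold, cfg.band_bounds
            )
            rec.update(
                {
                    "estimated_concentration_ng_ml": q.estimated_concentration,
                    "censoring": q.censoring,
                    "risk_label": risk,
                    "band_label": band,
                }
            )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        cfg.to_yaml(os.path.join(out_dir, "run_config.yaml"))
    log.info("run complete in %.2fs", time.monotonic() - t0)
    return summary
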