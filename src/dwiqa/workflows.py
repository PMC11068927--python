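"""End-to-end QA workflows tying the pipeline stages together.

Three study designs are covered:

* ``run_phantom1_workflow`` — calibrated ADC measurement: noise-floor-
  corrected voxelwise ADC fits on a vial phantom, per-vial VOI statistics,
  temperature-corrected reference values and relative differences.
* ``run_phantom2_workflow`` — geometric distortion: marker detection on a
  grid phantom for each b-value volume of a reversed-PE pair, before and
  after integral-matching distortion correction, summarized per scenario.
* ``run_brain_workflow`` — brain-like ADC and distortion estimation:
  per-tissue VOI statistics for two b-value subsets plus off-resonance
  p95 metrics (Hz, ppm, mm) within the brain mask.

Each workflow takes a JSON-able config dict, writes TSV/JSON reports plus
a run manifest into ``out_dir``, and returns its results in memory.
Workflows are deterministic: rerunning a config reproduces the outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import adc as adc_mod
from . import distortion as dist_mod
from . import fieldmetrics, stats, unwarp
from .io import read_dwi, read_nifti
from .markers import MarkerSet


def _write_manifest(out_dir: Path, name: str, config: dict, extras: dict) -> None:
    manifest = {"workflow": name, "config": config, **extras}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )


def _load_pair(config):
    up = read_dwi(config["dwi_up"], config["bval"], config["protocol"])
    down = read_dwi(config["dwi_down"], config["bval"], config["protocol"])
    if up.data.shape != down.data.shape:
        raise ValueError("reversed-PE series must share a shape")
    return up, down


def _noise_estimate(data_4d, config):
    box = config.get("noise_box")
    if box is None:
        return None
    i0, j0, k0, si, sj, sk = [int(x) for x in box]
    return adc_mod.estimate_background_noise(data_4d, ((i0, j0, k0), (si, sj, sk)))


def run_phantom1_workflow(config: dict, out_dir) -> dict:
    """Calibrated ADC workflow on a vial-phantom reversed-PE pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    up, down = _load_pair(config)
    data = np.concatenate([up.data, down.data], axis=-1)
    b_rep = np.concatenate([up.b_values, down.b_values])
    noise = _noise_estimate(data, config)

    b_all = sorted(set(up.b_values))
    methods = {
        "adc_all": b_all,
        "adc_0_800": [0.0, 800.0] if 800.0 in b_all else b_all,
    }
    labels, _ = read_nifti(config["vois"])
    labels = labels.astype(int)
    temp_c = float(config.get("temperature_c", 20.0))
    calib = {int(k): v for k, v in config.get("calibration", {}).items()}

    rows = []
    for method, subset in methods.items():
        amap = adc_mod.fit_adc(data, b_rep, b_subset=subset, noise=noise)
        for lab in sorted(set(np.unique(labels)) - {0}):
            summ = stats.voi_summary(amap, labels == lab)
            ref = None
            if lab in calib:
                ref = adc_mod.temperature_correct_reference(
                    lab, temp_c, {lab: {float(t): a for t, a in calib[lab].items()}}
                )
            row = {"vial": lab, "method": method, **summ.to_dict()}
            if ref is not None:
                row["reference_adc"] = ref
                row["rel_diff_mean"] = stats.relative_difference(summ.mean, ref, ref)
                row["rel_diff_median"] = stats.relative_difference(summ.median, ref, ref)
            rows.append(row)
    report = pd.DataFrame(rows)
    report.to_csv(out / "vial_adc_report.tsv", sep="\t", index=False)
    extras = {"eta_sq": None if noise is None else noise.eta_sq}
    _write_manifest(out, "phantom1", config, extras)
    return {"report": report, "noise": noise}


def run_phantom2_workflow(config: dict, out_dir) -> dict:
    """Grid-phantom distortion workflow on a reversed-PE pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    up, down = _load_pair(config)
    reference = MarkerSet.load_tsv(config["markers"])
    beam = float(config.get("beam_thickness_mm", 6.0))
    spacing = float(config.get("spacing_mm", 25.0))
    min_score = float(config.get("min_score", 0.5))
    voxel = np.abs(np.diag(up.affine)[:3])
    template = dist_mod.make_cross_template(beam, voxel)

    per_volume = {"image": [], "reverse": [], "corrected": []}
    for i in range(up.data.shape[-1]):
        vol_up = up.data[..., i]
        vol_down = down.data[..., i]
        field = unwarp.estimate_field_reversed_pe(
            vol_up, vol_down, up.protocol,
            smooth_mm=float(config.get("smooth_mm", 4.0)),
        )
        corrected = unwarp.unwarp_pair(vol_up, vol_down, field)
        for key, vol in (("image", vol_up), ("reverse", vol_down),
                         ("corrected", corrected)):
            detected = dist_mod.detect_markers(
                vol, up.affine, template, approx=reference,
                search_radius_mm=spacing / 2.0, min_score=min_score,
            )
            per_volume[key].append(dist_mod.marker_distortion(detected, reference))

    rows = []
    for key, reports in per_volume.items():
        mean_mm, max_mm = dist_mod.scenario_summary(reports)
        rows.append({"image": key, "statistic": "mean_mm", "value": mean_mm})
        rows.append({"image": key, "statistic": "max_mm", "value": max_mm})
    table = pd.DataFrame(rows)
    table.to_csv(out / "distortion_summary.tsv", sep="\t", index=False)
    _write_manifest(out, "phantom2", config, {"n_volumes": up.data.shape[-1]})
    return {"summary": table, "reports": per_volume}


def run_brain_workflow(config: dict, out_dir) -> dict:
    """Brain-like ADC + off-resonance workflow for one subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    up, down = _load_pair(config)
    data = np.concatenate([up.data, down.data], axis=-1)
    b_rep = np.concatenate([up.b_values, down.b_values])
    noise = _noise_estimate(data, config)
    labels, _ = read_nifti(config["labels"])
    labels = labels.astype(int)
    label_names = {int(k): v for k, v in config.get(
        "label_names", {1: "csf", 2: "gm", 3: "wm"}).items()}

    b_all = sorted(set(up.b_values))
    methods = {
        "adc_all": b_all,
        "adc_0_800": [0.0, 800.0] if 800.0 in b_all else b_all,
    }
    rows = []
    for method, subset in methods.items():
        amap = adc_mod.fit_adc(data, b_rep, b_subset=subset, noise=noise)
        for lab, name in label_names.items():
            summ = stats.voi_summary(amap, labels == lab)
            rows.append({"voi": name, "method": method, **summ.to_dict()})
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "tissue_adc_report.tsv", sep="\t", index=False)

    field_metrics = None
    if "field_hz" in config:
        field, _ = read_nifti(config["field_hz"])
        brain_mask = labels > 0
        field_metrics = fieldmetrics.field_summary(field, brain_mask, up.protocol)
        (out / "field_metrics.json").write_text(
            json.dumps(field_metrics, indent=2) + "\n"
        )
    _write_manifest(out, "brain", config, {"field_metrics": field_metrics})
    return {"summaries": summaries, "field_metrics": field_metrics, "noise": noise}
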