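"""End-to-end pipeline: validate -> preprocess -> detect -> evaluate.

Driven by a YAML/JSON configuration; writes the detected events, the
per-target quality metrics and a JSON run manifest (package version,
parameters, seed, input hashes) so every output is reproducible from
the manifest alone.  Outputs contain no wall-clock information:
identical configuration and inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixation, io, preprocessing, quality
from .fixation import events_to_frame
from .model import GazeRecording


class PipelineConfigError(ValueError):
    """A required configuration field is missing or inconsistent."""


def load_pipeline_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PipelineConfigError("pipeline config must be a mapping")
    return doc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _detect(recording: GazeRecording, cfg: dict):
    algorithm = cfg.get("algorithm", "ivt")
    if algorithm == "ivt":
        params = fixation.IVTParams(
            velocity_threshold=float(cfg.get("velocity_threshold", 30.0)),
            velocity_window=float(cfg.get("velocity_window", 20.0)),
        )
        _, events = fixation.ivt(recording, params)
    elif algorithm == "idt":
        params = fixation.IDTParams(
            dispersion_threshold=float(cfg.get("dispersion_threshold", 1.0)),
            window_duration=float(cfg.get("window_duration", 250.0)),
        )
        events = fixation.idt(recording, params)
    elif algorithm == "iaoi":
        params = fixation.IAOIParams(min_duration=float(cfg.get("min_duration", 100.0)))
        events = fixation.iaoi(recording, params)
    else:
        raise PipelineConfigError(f"unknown detect.algorithm {algorithm!r}")

    if "merge" in cfg:
        merge_cfg = cfg["merge"] or {}
        events = fixation.merge_adjacent_fixations(
            events,
            fixation.MergeParams(
                max_gap_duration=float(merge_cfg.get("max_gap_duration", 75.0)),
                max_angle=float(merge_cfg.get("max_angle", 0.5)),
                max_dispersion=float(merge_cfg.get("max_dispersion", 1.0)),
            ),
            mode=algorithm,
            recording=recording,
        )
    if "discard" in cfg:
        discard_cfg = cfg["discard"] or {}
        events = fixation.discard_short_fixations(
            events,
            fixation.DiscardParams(min_duration=float(discard_cfg.get("min_duration", 60.0))),
        )
    return events


def _load_targets(spec) -> list[quality.TargetSpec]:
    if isinstance(spec, (str, Path)):
        with open(spec, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        entries = doc["targets"] if isinstance(doc, dict) else doc
    else:
        entries = spec
    return [
        quality.TargetSpec(id=str(e["id"]), position=e["position"]) for e in entries
    ]


def assign_samples_to_targets(
    recording: GazeRecording, targets: list[quality.TargetSpec]
) -> np.ndarray:
    """Nearest-target (by visual angle) assignment of each usable sample.

    A coarse stand-in for manual annotation / ground-truth labels:
    every valid sample with a gaze point is attributed to the target at
    the smallest angle from its gaze origin.  Returns an index array
    (-1 for unusable samples).
    """
    from .geometry import angular_distance

    n = len(recording)
    assign = np.full(n, -1, dtype=int)
    usable = recording.valid & recording.point_hit & ~np.isnan(recording.points).any(axis=1)
    if not usable.any():
        return assign
    points = recording.points[usable]
    origins = recording.origins[usable]
    angles = np.stack(
        [
            angular_distance(points - origins, t.position - origins)
            for t in targets
        ],
        axis=1,
    )
    assign[usable] = np.argmin(angles, axis=1)
    return assign


def evaluate_recording(
    recording: GazeRecording,
    targets: list[quality.TargetSpec],
    angle_mode: str = "per_sample",
    precision_mode: str = "sd",
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-target accuracy/precision table via nearest-target assignment.

    ``sample_mask`` restricts the computation to a subset of samples,
    typically the samples inside detected fixation events so that
    saccades do not contaminate the error statistics.
    """
    assign = assign_samples_to_targets(recording, targets)
    if sample_mask is not None:
        assign = np.where(np.asarray(sample_mask, dtype=bool), assign, -1)
    rows = []
    for i, target in enumerate(targets):
        idx = np.flatnonzero(assign == i)
        if len(idx) < 2:
            continue
        res = quality.accuracy_precision(
            recording.points[idx],
            recording.origins[idx],
            target,
            angle_mode=angle_mode,
            precision_mode=precision_mode,
        )
        rows.append(dataclasses.asdict(res))
    frame = pd.DataFrame(rows)
    if len(frame):
        summary = frame.drop(columns=["target_id"]).mean(numeric_only=True)
        summary["target_id"] = "mean"
        summary["n_samples"] = int(frame["n_samples"].sum())
        frame = pd.concat([frame, summary.to_frame().T[frame.columns]], ignore_index=True)
    return frame


def run_pipeline(config: dict, base_dir=".") -> dict:
    """Execute the configured stages and write the output files.

    Config keys: ``input`` (csv [, json]), optional ``validate``,
    ``preprocess`` (``gap_fill_ms``, ``noise`` {method, window}),
    ``detect`` (algorithm + thresholds, optional merge/discard blocks),
    ``evaluate`` (targets path or inline list), ``output_dir`` and
    ``seed``.  Returns {name: written path}.
    """
    base = Path(base_dir)
    if "input" not in config or "csv" not in (config["input"] or {}):
        raise PipelineConfigError("config field 'input.csv' is required")
    csv_path = base / config["input"]["csv"]
    if not csv_path.exists():
        raise PipelineConfigError(f"input.csv does not exist: {csv_path}")
    json_rel = config["input"].get("json")
    json_path = base / json_rel if json_rel else None

    out_dir = base / config.get("output_dir", "gaze3d_out")
    out_dir.mkdir(parents=True, exist_ok=True)

    recording = io.load_recording(csv_path, json_path)
    outputs: dict[str, str] = {}
    report = None

    if config.get("validate", True):
        vcfg = config.get("validate")
        vcfg = vcfg if isinstance(vcfg, dict) else {}
        recording, report = io.validate_timestamps(
            recording, drop_gap_samples=bool(vcfg.get("drop_gap_samples", False))
        )

    if "preprocess" in config and config["preprocess"]:
        pcfg = config["preprocess"]
        if "gap_fill_ms" in pcfg:
            recording = preprocessing.gap_fill(
                recording, preprocessing.GapFillParams(float(pcfg["gap_fill_ms"]))
            )
        if "noise" in pcfg and pcfg["noise"]:
            ncfg = pcfg["noise"]
            recording = preprocessing.noise_reduction(
                recording,
                preprocessing.NoiseReductionParams(
                    method=ncfg.get("method", "median"),
                    window=int(ncfg.get("window", 3)),
                ),
            )

    fixation_mask = None
    if "detect" in config and config["detect"]:
        events = _detect(recording, config["detect"])
        events_path = out_dir / "events.csv"
        events_to_frame(events).to_csv(events_path, index=False, lineterminator="\n")
        outputs["events"] = str(events_path)
        # evaluate on fixation samples only (saccade removal)
        fixation_mask = np.zeros(len(recording), dtype=bool)
        for ev in events:
            fixation_mask[ev.sample_indices] = True

    if "evaluate" in config and config["evaluate"]:
        ecfg = config["evaluate"]
        if "targets" not in ecfg:
            raise PipelineConfigError("config field 'evaluate.targets' is required")
        targets_spec = ecfg["targets"]
        if isinstance(targets_spec, str):
            targets_path = base / targets_spec
            if not targets_path.exists():
                raise PipelineConfigError(
                    f"evaluate.targets does not exist: {targets_path}"
                )
            targets_spec = targets_path
        targets = _load_targets(targets_spec)
        metrics = evaluate_recording(
            recording,
            targets,
            angle_mode=ecfg.get("angle_mode", "per_sample"),
            precision_mode=ecfg.get("precision_mode", "sd"),
            sample_mask=fixation_mask,
        )
        metrics_path = out_dir / "metrics.csv"
        metrics.to_csv(metrics_path, index=False, lineterminator="\n")
        outputs["metrics"] = str(metrics_path)

    from . import __version__

    manifest = {
        "package": "gaze3d",
        "version": __version__,
        "seed": config.get("seed", 0),
        "parameters": config,
        "inputs": {
            str(csv_path): _sha256(csv_path),
            **({str(json_path): _sha256(json_path)} if json_path else {}),
        },
        "timestamp_report": report.to_dict() if report else None,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    outputs["manifest"] = str(manifest_path)
    return outputs
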