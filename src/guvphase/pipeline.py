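"""End-to-end orchestration: detect -> profile -> segment -> quantify ->
aggregate, over single scenes or manifest-driven batches."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .config import RunConfig
from .detection import detect_vesicles, filter_rings
from .metrics import (
    ConditionSummary,
    PartitionRecord,
    aggregate_condition,
    compute_partition_record,
    select_heatmap_sample,
)
from .profiles import extract_profile
from .segmentation import segment_phases

__all__ = [
    "BatchManifest",
    "SceneResult",
    "process_scene",
    "run_quantify",
    "summarize_records",
]


@dataclass
class BatchManifest:
    """Rows of (image path, scene/condition/replicate ids) plus the run
    configuration; conditions and replicates come only from here, never
    from filenames."""

    rows: list[dict]
    config: RunConfig

    def __post_init__(self) -> None:
        ids = [r["scene_id"] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("scene_ids in a manifest must be unique")

    @classmethod
    def from_csv(cls, path: str | Path, config: RunConfig) -> "BatchManifest":
        frame = pd.read_csv(path, dtype=str, comment="#").fillna("")
        required = {"path", "scene_id", "condition_id", "replicate_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        rows = frame.to_dict("records")
        base = Path(path).parent
        for row in rows:
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            row["path"] = str(p)
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        return cls(rows=rows, config=config)


@dataclass
class SceneResult:
    """Per-scene outcome with an auditable accept/reject trail."""

    scene_id: str
    records: list[PartitionRecord]
    n_detected: int
    n_accepted: int
    rejections: dict[str, int] = field(default_factory=dict)

    def log_line(self) -> str:
        rej = ", ".join(f"{k}={v}" for k, v in sorted(self.rejections.items())) or "none"
        return (
            f"scene {self.scene_id}: detected={self.n_detected} "
            f"accepted={self.n_accepted} qc_pass={sum(r.qc_pass for r in self.records)} "
            f"rejected[{rej}]"
        )


def process_scene(scene: gio.ConfocalScene, config: RunConfig) -> SceneResult:
    """Run the full per-scene stage sequence and return per-GUV records.

    Every filtered-in ring yields a record; vesicles without coexisting
    phases (or with non-positive background-subtracted phase means) carry
    ``qc_pass=False`` so the filter trail stays auditable.
    """
    detected = detect_vesicles(scene, config)
    accepted = filter_rings(detected, config)
    rejections: dict[str, int] = {}
    for ring in detected:
        if ring in accepted:
            continue
        reason = "+".join(sorted(ring.flags)) or "below_threshold"
        rejections[reason] = rejections.get(reason, 0) + 1

    records: list[PartitionRecord] = []
    for ring in accepted:
        others = [r for r in accepted if r is not ring]
        profile = extract_profile(scene, ring, config, other_rings=others)
        if not profile.valid_bin.any():
            rejections["no_valid_bins"] = rejections.get("no_valid_bins", 0) + 1
            continue
        labeling = segment_phases(profile, config)
        records.append(
            compute_partition_record(
                profile,
                labeling,
                condition_id=scene.condition_id,
                replicate_id=scene.replicate_id,
            )
        )
    return SceneResult(
        scene_id=scene.scene_id,
        records=records,
        n_detected=len(detected),
        n_accepted=len(accepted),
        rejections=rejections,
    )


def summarize_records(
    records: Sequence[PartitionRecord], config: RunConfig
) -> pd.DataFrame:
    """Per-condition two-stage summary table (one row per condition)."""
    by_condition: dict[str, list[PartitionRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition_id, []).append(r)
    rows = []
    for cond in sorted(by_condition):
        try:
            s = aggregate_condition(by_condition[cond], config)
        except ValueError:
            rows.append(
                {
                    "condition_id": cond, "n_replicates": 0, "n_guvs_total": 0,
                    "mean_log_fc": math.nan, "sd_log_fc": math.nan,
                    "mean_spi": math.nan, "sd_spi": math.nan,
                    "replicate_ok": False,
                }
            )
            continue
        rows.append(
            {
                "condition_id": s.condition_id,
                "n_replicates": s.n_replicates,
                "n_guvs_total": s.n_guvs_total,
                "mean_log_fc": s.mean_log_fc,
                "sd_log_fc": s.sd_log_fc,
                "mean_spi": s.mean_spi,
                "sd_spi": s.sd_spi,
                "replicate_ok": s.replicate_ok,
            }
        )
    columns = ["condition_id", "n_replicates", "n_guvs_total", "mean_log_fc",
               "sd_log_fc", "mean_spi", "sd_spi", "replicate_ok"]
    return pd.DataFrame(rows, columns=columns)


def run_quantify(manifest: BatchManifest, out_dir: str | Path) -> dict:
    """Quantify every scene in a manifest.

    Writes ``records.csv`` (per GUV), ``summary.csv`` (per condition),
    ``heatmap_sample.csv`` and ``run.log`` under ``out_dir``.  The resolved
    configuration is embedded as a comment header in each CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = manifest.config
    header = [f"config {k} = {v}" for k, v in sorted(config.to_dict().items())]

    all_records: list[PartitionRecord] = []
    log_lines: list[str] = list(header)
    for row in manifest.rows:
        scene = gio.read_scene(
            row["path"],
            config,
            scene_id=row["scene_id"],
            condition_id=row["condition_id"],
            replicate_id=row["replicate_id"],
        )
        result = process_scene(scene, config)
        all_records.extend(result.records)
        log_lines.append(result.log_line())

    gio.write_records(all_records, out / "records.csv", header_lines=header)

    summary = summarize_records(all_records, config)
    with open(out / "summary.csv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        summary.to_csv(fh, index=False, float_format="%.17g")

    sample = select_heatmap_sample(
        all_records, config.heatmap_sample_size, config.seed
    )
    gio.write_records(
        sample, out / "heatmap_sample.csv",
        header_lines=header + [f"heatmap seed = {config.seed}"],
    )

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "records": all_records,
        "summary": summary,
        "heatmap_sample": sample,
        "log": log_lines,
    }
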