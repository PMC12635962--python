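"""Reading confocal scenes and writing tabular results.

Intensities are never rescaled, clipped or brightness-adjusted on load: all
downstream metrics are computed from raw pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .metrics import PartitionRecord

__all__ = [
    "ConfocalScene",
    "read_scene",
    "write_scene",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]


@dataclass
class ConfocalScene:
    """One two-channel equatorial confocal section.

    ``marker_channel`` carries the Ld-phase lipid label, ``dna_channel`` the
    DNA label.  Both are 2-D non-negative rasters in arbitrary units of the
    same shape.
    """

    marker_channel: np.ndarray
    dna_channel: np.ndarray
    pixel_size_um: float
    scene_id: str = ""
    condition_id: str = ""
    replicate_id: str = ""
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.marker_channel = np.asarray(self.marker_channel)
        self.dna_channel = np.asarray(self.dna_channel)
        if self.marker_channel.ndim != 2 or self.dna_channel.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.marker_channel.shape != self.dna_channel.shape:
            raise ValueError(
                "marker and dna channels must have identical shape, got "
                f"{self.marker_channel.shape} vs {self.dna_channel.shape}"
            )
        for name, ch in (("marker", self.marker_channel), ("dna", self.dna_channel)):
            if not np.issubdtype(ch.dtype, np.number):
                raise ValueError(f"{name} channel has non-numeric dtype {ch.dtype}")
            if np.any(ch < 0):
                raise ValueError(f"{name} channel contains negative intensities")
        if self.bit_depth is not None:
            ceiling = 2 ** self.bit_depth - 1
            if self.marker_channel.max(initial=0) > ceiling or self.dna_channel.max(
                initial=0
            ) > ceiling:
                raise ValueError(f"intensities exceed 2^{self.bit_depth} - 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.marker_channel.shape


def read_scene(
    path: str | Path,
    config: RunConfig,
    scene_id: str = "",
    condition_id: str = "",
    replicate_id: str = "",
    bit_depth: int | None = None,
) -> ConfocalScene:
    """Read a multichannel TIFF into a :class:`ConfocalScene`.

    The channel axis is resolved from the array shape (leading axis for
    ``(C, H, W)``, trailing for ``(H, W, C)`` with small C) and roles come
    exclusively from ``config.channel_map``.  Pixel values pass through
    unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scene file not found: {path}")
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric pixel data in {path} (dtype {arr.dtype})")
    if arr.ndim == 2:
        arr = arr[None, :, :]
    elif arr.ndim == 3:
        # channel axis: prefer the small leading axis (multi-page TIFF);
        # fall back to a small trailing axis (interleaved).
        if arr.shape[0] > 8 and arr.shape[2] <= 8:
            arr = np.moveaxis(arr, 2, 0)
    else:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    max_index = max(config.channel_map)
    if max_index >= arr.shape[0]:
        raise ValueError(
            f"channel index {max_index} out of range: file has "
            f"{arr.shape[0]} channel(s)"
        )
    role_to_index = {role: idx for idx, role in config.channel_map.items()}
    return ConfocalScene(
        marker_channel=arr[role_to_index["marker"]],
        dna_channel=arr[role_to_index["dna"]],
        pixel_size_um=config.pixel_size_um,
        scene_id=scene_id or path.stem,
        condition_id=condition_id,
        replicate_id=replicate_id,
        bit_depth=bit_depth,
    )


def write_scene(scene: ConfocalScene, path: str | Path, config: RunConfig) -> None:
    """Write a scene as an uncompressed multichannel TIFF (inverse of
    :func:`read_scene` under the same channel map)."""
    n_channels = max(config.channel_map) + 1
    role_to_index = {role: idx for idx, role in config.channel_map.items()}
    stack = np.zeros((n_channels,) + scene.shape, dtype=scene.marker_channel.dtype)
    stack[role_to_index["marker"]] = scene.marker_channel
    stack[role_to_index["dna"]] = scene.dna_channel
    tifffile.imwrite(path, stack)


#: Column order of the per-GUV record table.
RECORD_COLUMNS = [
    "guv_id",
    "condition_id",
    "replicate_id",
    "i_lo",
    "i_ld",
    "log_fc",
    "spi",
    "whole_vesicle_intensity",
    "n_lo_bins",
    "n_ld_bins",
    "qc_pass",
]


def records_to_frame(records: Sequence[PartitionRecord]) -> pd.DataFrame:
    rows = [
        {
            "guv_id": r.guv_id,
            "condition_id": r.condition_id,
            "replicate_id": r.replicate_id,
            "i_lo": r.i_lo,
            "i_ld": r.i_ld,
            "log_fc": r.log_fc,
            "spi": r.spi,
            "whole_vesicle_intensity": r.whole_vesicle_intensity,
            "n_lo_bins": r.n_lo_bins,
            "n_ld_bins": r.n_ld_bins,
            "qc_pass": r.qc_pass,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(
    records: Sequence[PartitionRecord],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write one CSV row per GUV in :data:`RECORD_COLUMNS` order.

    Floats are written with 17 significant digits so that re-reading
    reproduces every value exactly.  ``header_lines`` are embedded as
    ``#``-prefixed comment lines before the header (used by the CLI to
    record the resolved configuration).
    """
    frame = records_to_frame(records)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_records(path: str | Path) -> list[PartitionRecord]:
    """Inverse of :func:`write_records`."""
    frame = pd.read_csv(
        path,
        comment="#",
        dtype={"guv_id": str, "condition_id": str, "replicate_id": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PartitionRecord(
                guv_id=_as_str(row.guv_id),
                condition_id=_as_str(row.condition_id),
                replicate_id=_as_str(row.replicate_id),
                i_lo=float(row.i_lo),
                i_ld=float(row.i_ld),
                log_fc=float(row.log_fc),
                spi=float(row.spi),
                whole_vesicle_intensity=float(row.whole_vesicle_intensity),
                n_lo_bins=int(row.n_lo_bins),
                n_ld_bins=int(row.n_ld_bins),
                qc_pass=_as_bool(row.qc_pass),
            )
        )
    return records


def _as_str(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1"}
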