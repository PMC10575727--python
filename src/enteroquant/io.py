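"""File formats: multi-page TIFF images, tab-delimited tables, truth sidecars.

Conventions: images travel as multi-page TIFF with a ``*.channels.tsv``
sidecar naming one channel per page; traces and DE tables are UTF-8
tab-delimited text with a header row; events accompany traces in a
``*.events.tsv`` sidecar; planted ground truth is YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AssayTrace, MultichannelImage, TraceEvent
from .rescue import DE_COLUMNS, DeContrastTable
from .simulate import SyntheticTruth

__all__ = [
    "write_multichannel_tiff",
    "read_multichannel_tiff",
    "write_trace",
    "read_trace",
    "write_de_table",
    "read_de_table",
    "write_truth",
    "read_truth",
    "write_label_stack",
    "read_label_stack",
]


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def write_multichannel_tiff(image: MultichannelImage, path: str | Path) -> Path:
    """Write channels as TIFF pages plus a channel-name sidecar table."""
    path = Path(path)
    names = image.channel_names
    stack = np.stack([image[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack)
    sidecar = pd.DataFrame({"page": range(len(names)), "channel": names})
    if image.pixel_size is not None:
        sidecar["pixel_size_um"] = image.pixel_size
    sidecar.to_csv(_sidecar(path, ".channels.tsv"), sep="\t", index=False)
    if image.mask is not None:
        tifffile.imwrite(_sidecar(path, ".mask.tif"), image.mask.astype(np.uint8))
    return path


def read_multichannel_tiff(path: str | Path) -> MultichannelImage:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = pd.read_csv(_sidecar(path, ".channels.tsv"), sep="\t")
    names = list(sidecar.sort_values("page")["channel"])
    if len(names) != len(stack):
        raise ValueError(
            f"channel sidecar lists {len(names)} channels, TIFF has {len(stack)} pages"
        )
    pixel_size = None
    if "pixel_size_um" in sidecar.columns:
        pixel_size = float(sidecar["pixel_size_um"].iloc[0])
    mask_path = _sidecar(path, ".mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return MultichannelImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        mask=mask,
        pixel_size=pixel_size,
    )


def write_trace(trace: AssayTrace, path: str | Path) -> Path:
    """Write (time, value) as TSV with an events sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "value": trace.value}).to_csv(
        path, sep="\t", index=False
    )
    ev = pd.DataFrame(
        [(e.time, e.agent, e.concentration) for e in trace.events],
        columns=["time_s", "agent", "concentration_uM"],
    )
    ev.to_csv(_sidecar(path, ".events.tsv"), sep="\t", index=False)
    return path


def read_trace(path: str | Path, units: str = "a.u.") -> AssayTrace:
    path = Path(path)
    t = pd.read_csv(path, sep="\t")
    events: list[TraceEvent] = []
    ev_path = _sidecar(path, ".events.tsv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path, sep="\t")
        for _, row in ev.iterrows():
            conc = row.get("concentration_uM")
            events.append(TraceEvent(
                time=float(row["time_s"]),
                agent=str(row["agent"]),
                concentration=None if pd.isna(conc) else float(conc),
            ))
    return AssayTrace(
        time=t["time_s"].to_numpy(), value=t["value"].to_numpy(),
        events=events, units=units,
    )


def write_de_table(table: DeContrastTable, path: str | Path) -> Path:
    path = Path(path)
    table.table[DE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_de_table(path: str | Path, name: str | None = None) -> DeContrastTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return DeContrastTable(name=name or path.stem, table=df)


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(truth.to_yaml())
    return path


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_yaml(Path(path).read_text())


def write_label_stack(frames: list[np.ndarray], path: str | Path) -> Path:
    """Write per-timepoint label masks as a multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([f.astype(np.int32) for f in frames]))
    return path


def read_label_stack(path: str | Path) -> list[np.ndarray]:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None]
    return [frame.astype(np.int32) for frame in stack]
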