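"""Readers and writers: TIFF/OME-TIFF stacks, CSV tables, YAML configs.

CSV schemas are versioned with a leading comment line
(``# t6sspipe csv v1 <table>``); every writer here has a matching reader
that round-trips without loss.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import Focus, ImageStack, LabelMask, Track
from .simulate import FieldGroundTruth

CSV_VERSION = "v1"


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: ImageStack, ome: bool = True,
                dtype=np.uint16) -> None:
    """Write an (m, n, z) stack as a multi-page (OME-)TIFF in ZYX page order."""
    data = np.clip(np.round(stack.voxels), 0, np.iinfo(dtype).max).astype(dtype)
    pages = data.transpose(2, 0, 1)  # (z, y, x)
    path = Path(path)
    if ome:
        tifffile.imwrite(
            path, pages, ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": stack.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": stack.z_spacing_um,
                "PhysicalSizeZUnit": "µm",
            },
        )
    else:
        tifffile.imwrite(path, pages, photometric="minisblack")


def _ome_pixel_sizes(tf: tifffile.TiffFile) -> tuple[float | None, float | None]:
    xml = tf.ome_metadata
    if not xml:
        return None, None
    mx = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', xml)
    mz = re.search(r'PhysicalSizeZ="([0-9.eE+-]+)"', xml)
    return (float(mx.group(1)) if mx else None,
            float(mz.group(1)) if mz else None)


def read_stack(path: str | Path, channel: int | None = None,
               z_range: tuple[int, int] | None = None,
               axes: str | None = None,
               pixel_size_um: float | None = None,
               z_spacing_um: float | None = None,
               channel_label: str = "") -> ImageStack:
    """Read a TIFF/OME-TIFF stack into an ImageStack.

    Axis order is resolved from the file's series metadata, or from the
    ``axes`` argument when the file carries none. A configured
    ``pixel_size_um`` wins over file metadata; if neither is available an
    error is raised. Supported axis orders are any arrangement of C, Z, Y, X.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
        meta_px, meta_z = _ome_pixel_sizes(tf)
    ax = (axes or file_axes or "").upper()
    if len(ax) != data.ndim or set(ax) - set("CZYX"):
        # no usable axis metadata (plain TIFFs report unknown axes as Q):
        # fall back to the conventional order for the dimensionality
        if axes is not None:
            raise ValueError(f"unsupported axes {axes!r}; expected CZYX order")
        if data.ndim == 2:
            ax = "YX"
        elif data.ndim == 3:
            ax = "ZYX"
        else:
            raise ValueError(
                f"ambiguous axis order for {path.name} (shape {data.shape}); "
                "pass axes explicitly")
    if "C" in ax:
        if channel is None:
            raise ValueError("multi-channel file: a channel index is required")
        data = np.take(data, channel, axis=ax.index("C"))
        ax = ax.replace("C", "")
    if "Z" not in ax:
        data = data[None, ...] if ax == "YX" else data
        ax = "Z" + ax if ax == "YX" else ax
    # reorder to (Y, X, Z)
    order = [ax.index("Y"), ax.index("X"), ax.index("Z")]
    data = np.transpose(data, order)
    if z_range is not None:
        data = data[:, :, z_range[0]:z_range[1]]
    px = pixel_size_um if pixel_size_um is not None else meta_px
    dz = z_spacing_um if z_spacing_um is not None else meta_z
    if px is None:
        raise ValueError(
            f"pixel size for {path.name} not in metadata and not configured")
    if dz is None:
        dz = px  # single-plane or unspecified spacing
    return ImageStack(data.astype(np.float32), float(px), float(dz),
                      channel=channel_label)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    """Write a label mask as 16-bit TIFF (2D plane or ZYX pages)."""
    labels = mask.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    out = labels.astype(np.uint16)
    if out.ndim == 3:
        out = out.transpose(2, 0, 1)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def read_mask(path: str | Path) -> LabelMask:
    data = tifffile.imread(Path(path))
    if data.ndim == 3:
        data = data.transpose(1, 2, 0)
    return LabelMask(data.astype(np.int32))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def _write_csv(path: str | Path, df: pd.DataFrame, table: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# t6sspipe csv {CSV_VERSION} {table}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_cells_csv(path: str | Path, truth: FieldGroundTruth) -> None:
    rows = [{"id": c.id, "x": c.center[0], "y": c.center[1],
             "length": c.length, "width": c.width, "theta": c.orientation}
            for c in truth.cells]
    _write_csv(path, pd.DataFrame(rows, columns=["id", "x", "y", "length",
                                                 "width", "theta"]), "cells")


def read_cells_csv(path: str | Path) -> list:
    from .simulate import CellGeometry

    df = _read_csv(path)
    return [CellGeometry(int(r.id), (float(r.x), float(r.y)), float(r.length),
                         float(r.width), float(r.theta))
            for r in df.itertuples()]


def write_true_foci_csv(path: str | Path, truth: FieldGroundTruth) -> None:
    rows = [{"channel": f.channel, "cell_id": f.cell_id, "x": f.x, "y": f.y,
             "z": f.z}
            for foci in truth.foci.values() for f in foci]
    _write_csv(path, pd.DataFrame(rows, columns=["channel", "cell_id",
                                                 "x", "y", "z"]), "foci_true")


def write_events_csv(path: str | Path, truth: FieldGroundTruth) -> None:
    rows = [{"focus_id": e.focus_id, "cell_id": e.cell_id,
             "t_appear": e.t_appear, "t_disappear": e.t_disappear}
            for e in truth.events]
    _write_csv(path, pd.DataFrame(rows, columns=["focus_id", "cell_id",
                                                 "t_appear", "t_disappear"]),
               "events")


def read_events_csv(path: str | Path) -> list:
    from .simulate import FocusEvent

    df = _read_csv(path)
    return [FocusEvent(int(r.focus_id),
                       None if pd.isna(r.cell_id) else int(r.cell_id),
                       float(r.t_appear), float(r.t_disappear))
            for r in df.itertuples()]


def write_foci_csv(path: str | Path, foci: list[Focus],
                   pixel_size_um: float) -> None:
    rows = [{"frame": f.frame, "channel": f.channel, "x_px": f.x, "y_px": f.y,
             "x_um": f.x * pixel_size_um, "y_um": f.y * pixel_size_um,
             "intensity": f.integrated_intensity, "snr": f.peak_snr}
            for f in foci]
    _write_csv(path, pd.DataFrame(rows, columns=["frame", "channel", "x_px",
                                                 "y_px", "x_um", "y_um",
                                                 "intensity", "snr"]),
               "foci_detected")


def read_foci_csv(path: str | Path) -> list[Focus]:
    df = _read_csv(path)
    return [Focus(x=row.x_px, y=row.y_px, channel=str(row.channel),
                  frame=int(row.frame), integrated_intensity=row.intensity,
                  peak_snr=row.snr)
            for row in df.itertuples()]


def write_per_cell_counts_csv(path: str | Path, counts_by_field: dict) -> None:
    """``counts_by_field`` maps field index -> PerCellCounts."""
    rows = []
    for field_idx, pcc in counts_by_field.items():
        for lab, n in sorted(pcc.counts.items()):
            rows.append({"field": field_idx, "cell_label": lab, "n_foci": n,
                         "is_single": pcc.is_single.get(lab, False),
                         "touches_border": pcc.touches_border.get(lab, False)})
    _write_csv(path, pd.DataFrame(rows, columns=["field", "cell_label",
                                                 "n_foci", "is_single",
                                                 "touches_border"]),
               "per_cell_counts")


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    rows = [{"track_id": t.track_id, "frame": p[0], "x": p[1], "y": p[2],
             "intensity": p[3]} for t in tracks for p in t.points]
    _write_csv(path, pd.DataFrame(rows, columns=["track_id", "frame", "x",
                                                 "y", "intensity"]), "tracks")


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = _read_csv(path)
    tracks: dict[int, Track] = {}
    for row in df.itertuples():
        t = tracks.setdefault(int(row.track_id), Track(int(row.track_id)))
        t.points.append((int(row.frame), float(row.x), float(row.y),
                         float(row.intensity)))
    for t in tracks.values():
        t.points.sort()
    return [tracks[k] for k in sorted(tracks)]


def write_track_summary_csv(path: str | Path, tracks: list[Track],
                            frame_interval_s: float) -> None:
    rows = [{"track_id": t.track_id, "t_start": t.t_start(frame_interval_s),
             "t_end": t.t_end(frame_interval_s),
             "lifetime_s": t.lifetime_s(frame_interval_s)} for t in tracks]
    _write_csv(path, pd.DataFrame(rows, columns=["track_id", "t_start",
                                                 "t_end", "lifetime_s"]),
               "track_summary")


# ---------------------------------------------------------------------------
# JSON / YAML
# ---------------------------------------------------------------------------


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def save_config(path: str | Path, config) -> None:
    """Write a pydantic config model as YAML."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"),
                                         sort_keys=False))


def load_config(path: str | Path, model_cls):
    """Read YAML into the given pydantic config model (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return model_cls.model_validate(data)
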