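"""Reading and writing the pipeline's file formats.

Images travel as 16-bit grayscale TIFF (single- or multi-page); all tabular
data (traces, tracks, titrations, decays, FACS events) as headered CSV; fits
and manifests as JSON. Intensities become float64 on read; writing integer
TIFF rounds and clips, so quantization is part of the write step.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .bindfit import DecayHistogram, TitrationSeries
from .frapfit import FrapTrace
from .motility import Track
from .spotdetect import PixelImage

__all__ = [
    "save_image",
    "save_stack",
    "read_image_stack",
    "write_frap_trace",
    "read_frap_trace",
    "write_tracks",
    "read_tracks",
    "write_titration",
    "read_titration",
    "write_decay",
    "read_decay",
    "read_facs_events",
]


def _quantize(values: np.ndarray, dtype) -> np.ndarray:
    info = np.iinfo(dtype)
    return np.clip(np.rint(values), info.min, info.max).astype(dtype)


def save_image(path: str | Path, image: PixelImage | np.ndarray, dtype=np.uint16) -> None:
    """Write one grayscale TIFF page, rounding/clipping to the integer dtype."""
    arr = image.values if isinstance(image, PixelImage) else np.asarray(image)
    tifffile.imwrite(str(path), _quantize(arr, dtype))


def save_stack(path: str | Path, frames: Sequence[PixelImage | np.ndarray], dtype=np.uint16) -> None:
    """Write a multi-page grayscale TIFF (one page per frame/channel)."""
    arrs = [f.values if isinstance(f, PixelImage) else np.asarray(f) for f in frames]
    stack = np.stack([_quantize(a, dtype) for a in arrs])
    tifffile.imwrite(str(path), stack)


_LAYOUTS = ("single", "multipage_time", "multipage_channel")


def read_image_stack(path: str | Path, layout: str = "single") -> list[PixelImage]:
    """Read a grayscale TIFF into PixelImages per the declared page layout.

    multipage_time maps pages to frame indices 0..n-1; multipage_channel maps
    pages to channels ch0, ch1, ... RGB or unreadable files are rejected.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}")
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            multisample = any(p.samplesperpixel != 1 for p in tif.pages)
            arr = None if multisample else tif.asarray()
    except Exception as exc:  # truncated/corrupt files must not pass silently
        raise ValueError(f"{path.name}: unreadable TIFF ({exc})") from exc
    if multisample:
        raise ValueError(f"{path.name}: RGB/multi-sample TIFF not supported")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: unsupported TIFF dimensionality {arr.ndim}")
    if layout == "single" and arr.shape[0] != 1:
        raise ValueError(f"{path.name}: expected a single page, found {arr.shape[0]}")
    out = []
    for i, page in enumerate(arr):
        if layout == "multipage_channel":
            out.append(PixelImage(page.astype(np.float64), channel_name=f"ch{i}"))
        else:
            out.append(PixelImage(page.astype(np.float64), frame_index=i))
    return out


def write_frap_trace(path: str | Path, trace: FrapTrace) -> None:
    lines = [f"# n_prebleach={trace.n_prebleach}", "time_s,roi_intensity,whole_image_intensity"]
    for t, r, w in zip(trace.times, trace.roi_intensity, trace.whole_image_intensity):
        lines.append(f"{float(t)!r},{float(r)!r},{float(w)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_frap_trace(path: str | Path, n_prebleach: int | None = None) -> FrapTrace:
    """Read a trace CSV; the '# n_prebleach=' header is used unless overridden."""
    path = Path(path)
    header_npre = None
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#") and "n_prebleach=" in first:
        header_npre = int(first.split("n_prebleach=")[1].strip())
    df = pd.read_csv(path, comment="#")
    npre = n_prebleach if n_prebleach is not None else (header_npre or 3)
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        roi_intensity=df["roi_intensity"].to_numpy(),
        whole_image_intensity=df["whole_image_intensity"].to_numpy(),
        n_prebleach=npre,
    )


def write_tracks(path: str | Path, tracks: Sequence[Track]) -> None:
    rows = []
    for tr in tracks:
        for frame, (x, y) in zip(tr.frames, tr.positions):
            rows.append({"cell_id": tr.cell_id, "frame": int(frame), "x": float(x), "y": float(y)})
    pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y"]).to_csv(path, index=False)


def read_tracks(
    path: str | Path, frame_interval: float = 10.0, pixel_size: float = 1.0
) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                cell_id=str(cid),
                frames=grp["frame"].to_numpy(),
                positions=grp[["x", "y"]].to_numpy(),
                frame_interval=frame_interval,
                pixel_size=pixel_size,
            )
        )
    return tracks


def write_titration(path: str | Path, series: TitrationSeries) -> None:
    pd.DataFrame(
        {"ligand_conc_M": series.ligand_conc, "response": series.response}
    ).to_csv(path, index=False)


def read_titration(path: str | Path, target_conc: float = 50e-9) -> TitrationSeries:
    df = pd.read_csv(path)
    return TitrationSeries(
        ligand_conc=df["ligand_conc_M"].to_numpy(),
        response=df["response"].to_numpy(),
        target_conc=target_conc,
    )


def write_decay(path: str | Path, decay: DecayHistogram) -> None:
    pd.DataFrame(
        {"time_ns": decay.bin_centers, "counts": decay.counts.astype(int)}
    ).to_csv(path, index=False)


def read_decay(path: str | Path) -> DecayHistogram:
    df = pd.read_csv(path)
    return DecayHistogram(bin_centers=df["time_ns"].to_numpy(), counts=df["counts"].to_numpy())


def read_facs_events(path: str | Path) -> np.ndarray:
    """One-column CSV of per-event fluorescence readings."""
    df = pd.read_csv(path)
    return df[df.columns[0]].to_numpy(dtype=float)
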