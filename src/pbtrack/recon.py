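"""Back projection of per-beam WET samples into per-frame 2-D radiographs.

Every WET sample is deposited at its measured lateral position with a
Gaussian kernel scaled by its weight; a pixel's value is the weight-normalised
mean WET of the samples reaching it.  Pixels whose accumulated weight stays
below a floor are masked out, never inpainted — downstream segmentation must
tolerate masked holes.  A frame's timestamp is the acquisition time of the
median beam in the frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .acquisition import PencilBeamRecord

__all__ = ["GridSpec", "FrameImage", "reconstruct_frame", "assemble_frames", "save_frames", "load_frames"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: ``spacing`` mm pixels covering ``field`` (w, h),
    centred on the field centre (default 0.5 mm — finer than the 5 mm spot
    spacing, coarser than the camera pixels)."""

    field: tuple[float, float]
    spacing: float = 0.5
    center: tuple[float, float] = (0.0, 0.0)
    deposition_sigma: float = 1.0  # mm, Gaussian deposition kernel
    coverage_floor: float = 0.02  # fraction of the maximum pixel weight

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx): images are indexed [row = y, column = x]."""
        w, h = self.field
        return (int(round(h / self.spacing)) + 1, int(round(w / self.spacing)) + 1)

    @property
    def origin(self) -> tuple[float, float]:
        """mm coordinates (x, y) of the centre of pixel [0, 0]."""
        ny, nx = self.shape
        return (
            self.center[0] - (nx - 1) / 2.0 * self.spacing,
            self.center[1] - (ny - 1) / 2.0 * self.spacing,
        )

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[1]) * self.spacing

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[0]) * self.spacing


@dataclass
class FrameImage:
    """A reconstructed 2-D WET map with a single frame timestamp.

    ``wet_map[iy, ix]`` is in mm water; ``coverage_mask`` marks pixels whose
    accumulated deposition weight cleared the floor.
    """

    wet_map: np.ndarray
    coverage_mask: np.ndarray
    grid: GridSpec
    frame_timestamp: float
    frame_index: int
    n_beams: int = 0
    n_missing_beams: int = 0
    weight_map: np.ndarray | None = None  # accumulated deposition weight

    @property
    def grid_spacing(self) -> float:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float]:
        return self.grid.origin


def reconstruct_frame(records: Sequence[PencilBeamRecord], grid: GridSpec) -> FrameImage:
    """Weight-normalised Gaussian back projection of one frame's WET samples.

    All records must share a frame index and at least one must carry samples.
    The Gaussian deposition kernel (sigma ``grid.deposition_sigma``, truncated
    at 3 sigma) stands in for the scatter-aware reprojection of the full
    estimator: samples are first splatted bilinearly onto the grid, then both
    the weight and the weighted-WET accumulators are smoothed by the same
    kernel, which is algebraically identical to depositing each sample with
    the kernel directly.
    """
    if not records:
        raise ValueError("empty frame: no records")
    frames = {r.frame_index for r in records}
    if len(frames) != 1:
        raise ValueError(f"records span multiple frames: {sorted(frames)}")
    ny, nx = grid.shape
    x0, y0 = grid.origin
    wsum = np.zeros((ny, nx))
    wwet = np.zeros((ny, nx))
    n_missing = 0
    for r in records:
        if r.samples is None or r.samples.size == 0:
            n_missing += 1
            continue
        s = r.samples
        fx = (s["x"] - x0) / grid.spacing
        fy = (s["y"] - y0) / grid.spacing
        ix = np.floor(fx).astype(int)
        iy = np.floor(fy).astype(int)
        ax = fx - ix
        ay = fy - iy
        for dx, dy, w in (
            (0, 0, (1 - ax) * (1 - ay)),
            (1, 0, ax * (1 - ay)),
            (0, 1, (1 - ax) * ay),
            (1, 1, ax * ay),
        ):
            gx = ix + dx
            gy = iy + dy
            ok = (gx >= 0) & (gx < nx) & (gy >= 0) & (gy < ny)
            ww = s["weight"][ok] * w[ok]
            flat = gy[ok] * nx + gx[ok]
            np.add.at(wsum.ravel(), flat, ww)
            np.add.at(wwet.ravel(), flat, ww * s["wet"][ok])
    if not np.any(wsum > 0):
        raise ValueError("empty frame: no WET samples")
    sig = grid.deposition_sigma / grid.spacing
    wsum = gaussian_filter(wsum, sig, truncate=3.0)
    wwet = gaussian_filter(wwet, sig, truncate=3.0)
    mask = wsum > grid.coverage_floor * wsum.max()
    wet = np.zeros_like(wsum)
    np.divide(wwet, wsum, out=wet, where=mask)
    np.clip(wet, 0.0, None, out=wet)
    ts = float(np.median([r.timestamp for r in records]))
    if n_missing:
        log.warning("frame %d: %d/%d beams contributed no samples", records[0].frame_index, n_missing, len(records))
    return FrameImage(wet, mask, grid, ts, int(records[0].frame_index), len(records), n_missing, wsum)


def assemble_frames(records: Sequence[PencilBeamRecord], grid: GridSpec) -> list[FrameImage]:
    """Sort records into frames and reconstruct each, ordered by time.

    Gaps in the frame-index sequence are reported (logged), never silently
    skipped; the output order follows the frame timestamps regardless of the
    input record order.
    """
    by_frame: dict[int, list[PencilBeamRecord]] = {}
    for r in sorted(records, key=lambda r: r.timestamp):
        by_frame.setdefault(r.frame_index, []).append(r)
    indices = sorted(by_frame)
    missing = sorted(set(range(indices[0], indices[-1] + 1)) - set(indices)) if indices else []
    if missing:
        log.warning("missing frames in record stream: %s", missing)
    frames = [reconstruct_frame(by_frame[i], grid) for i in indices]
    frames.sort(key=lambda f: f.frame_timestamp)
    return frames


def save_frames(frames: Sequence[FrameImage], directory: str | Path) -> None:
    """Write frames as 32-bit float TIFFs (`frame_####.tif`) + JSON metadata."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for f in frames:
        fn = f"frame_{f.frame_index:04d}.tif"
        tifffile.imwrite(directory / fn, f.wet_map.astype(np.float32))
        tifffile.imwrite(directory / f"mask_{f.frame_index:04d}.tif", f.coverage_mask.astype(np.uint8))
        meta.append(
            {
                "file": fn,
                "frame_index": f.frame_index,
                "timestamp": f.frame_timestamp,
                "grid": {
                    "field": list(f.grid.field),
                    "spacing": f.grid.spacing,
                    "center": list(f.grid.center),
                },
                "covered_fraction": float(f.coverage_mask.mean()),
                "n_beams": f.n_beams,
                "n_missing_beams": f.n_missing_beams,
            }
        )
    (directory / "frames.json").write_text(json.dumps(meta, indent=1))


def load_frames(directory: str | Path) -> list[FrameImage]:
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "frames.json").read_text())
    frames = []
    for m in meta:
        grid = GridSpec(tuple(m["grid"]["field"]), m["grid"]["spacing"], tuple(m["grid"]["center"]))
        wet = tifffile.imread(directory / m["file"]).astype(float)
        mask = tifffile.imread(directory / m["file"].replace("frame_", "mask_")).astype(bool)
        frames.append(FrameImage(wet, mask, grid, m["timestamp"], m["frame_index"], m["n_beams"], m["n_missing_beams"]))
    return frames
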