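"""Synthetic pencil-beam acquisition.

This module stands in for the experimental detector: a monolithic plastic
scintillator viewed by three cameras (top, lateral, distal).  For every
timestamped pencil-beam spot it produces the camera images the real system
would record: the beam is decomposed into sub-rays over its Gaussian
footprint, each sub-ray accumulates WET through the (moving) phantom at the
beam's timestamp and deposits an analytic Bragg depth-light curve at the
depth where its residual water-equivalent range is exhausted.  The 3-D light
distribution is summed along each camera axis, cos^4 vignetting is applied,
and multiplicative Gaussian noise plus an additive background are added.

Units: mm, s, MeV.  The depth-light curve uses the standard range-energy
power law R = alpha * E^p with a Gaussian range-straggling kernel; only the
peak position (not absolute dose) drives the downstream pipeline, so the
template is kept on a window around the peak.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .scene import MotionModel, PhantomModel, wet_parallel_rays

__all__ = [
    "BeamModel",
    "NoiseSpec",
    "OpticsModel",
    "ScanPattern",
    "CameraView",
    "PencilBeamRecord",
    "BraggTemplate",
    "make_scan_pattern",
    "field_for_insert",
    "simulate_pencil_beam",
    "simulate_frame",
    "simulate_spots",
    "apply_vignetting",
    "vignetting_factors",
    "save_beam_records",
    "load_beam_records",
    "pattern_to_csv",
]

PIXEL_SIZE_MM = 0.4004  # camera pixel size at the scintillator surface


@dataclass(frozen=True)
class BeamModel:
    """Pencil-beam and scintillator parameters.

    ``range_energy_alpha`` is in mm * MeV^-p so that R0 = alpha * E0^p is in
    mm of water.  The entrance spot size is the in-air FWHM of the lateral
    Gaussian profile.
    """

    energy_E0: float = 230.0
    fwhm_entrance: float = 7.8
    range_energy_alpha: float = 0.022
    range_energy_p: float = 1.77
    scintillator_rsp: float = 1.043
    scintillator_depth: float = 200.0
    straggling_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm_entrance <= 0:
            raise ValueError("fwhm_entrance must be > 0")
        if self.scintillator_rsp <= 0:
            raise ValueError("scintillator_rsp must be > 0")

    @property
    def range_R0(self) -> float:
        """Water-equivalent range alpha * E0^p (mm)."""
        return self.range_energy_alpha * self.energy_E0 ** self.range_energy_p

    @property
    def sigma_entrance(self) -> float:
        return self.fwhm_entrance / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def template(self) -> "BraggTemplate":
        return _bragg_template(self.range_energy_p, self.straggling_sigma)


class BraggTemplate:
    """Depth-light curve of a pristine Bragg peak, as a function of depth
    relative to the residual-range depth z_R.

    The underlying analytic shape is the power-law depth-dose
    d(z) ~ (R - z)^(1/p - 1) for z < R, convolved with a Gaussian
    range-straggling kernel.  The singular bin at z = R is handled by exact
    bin integration before the convolution.  The template is normalised to a
    peak of 1 and restricted to a window [u_min, u_max] around z_R; its
    ``peak_offset`` and ``distal80_offset`` (depth of the 80%-of-peak point on
    the falling edge) are precomputed for peak-localisation calibration.
    """

    U_MIN = -28.0  # mm proximal of z_R kept in the window
    U_MAX = 6.0  # mm distal

    def __init__(self, p: float = 1.77, straggling_sigma: float = 1.0, du: float = 0.02):
        self.p = p
        self.sigma = straggling_sigma
        self.du = du
        pad = 5.0 * straggling_sigma
        u = np.arange(self.U_MIN - pad, self.U_MAX + pad + du, du)
        # bin-averaged (R - z)^(1/p - 1): integrate the power law over each bin
        a = 1.0 / p  # exponent of the antiderivative of (-u)^(1/p - 1)
        lo = np.clip(-(u + du / 2.0), 0.0, None)
        hi = np.clip(-(u - du / 2.0), 0.0, None)
        raw = (hi ** a - lo ** a) / du
        k = np.arange(-math.ceil(4 * straggling_sigma / du), math.ceil(4 * straggling_sigma / du) + 1)
        g = np.exp(-0.5 * (k * du / straggling_sigma) ** 2)
        g /= g.sum()
        smooth = np.convolve(raw, g, mode="same")
        keep = (u >= self.U_MIN - 1e-9) & (u <= self.U_MAX + 1e-9)
        self.u = u[keep]
        self.values = smooth[keep] / smooth[keep].max()
        i_peak = int(np.argmax(self.values))
        self.peak_offset = float(self.u[i_peak])
        distal = self.values[i_peak:]
        j = int(np.argmax(distal < 0.8))
        frac = (self.values[i_peak + j - 1] - 0.8) / (self.values[i_peak + j - 1] - self.values[i_peak + j])
        self.distal80_offset = float(self.u[i_peak + j - 1] + frac * du)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return np.interp(u, self.u, self.values, left=0.0, right=0.0)

    def kernel(self, pitch: float) -> tuple[np.ndarray, int]:
        """Template sampled at ``pitch``; returns (kernel, index of u=0)."""
        n_lo = int(math.floor(-self.U_MIN / pitch))
        n_hi = int(math.floor(self.U_MAX / pitch))
        offsets = np.arange(-n_lo, n_hi + 1) * pitch
        return self(offsets), n_lo

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.u))


@lru_cache(maxsize=8)
def _bragg_template(p: float, sigma: float) -> BraggTemplate:
    return BraggTemplate(p, sigma)


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise: multiplicative Gaussian (sigma as a fraction of local
    intensity) plus an additive Gaussian background scaled to the view peak."""

    multiplicative_sigma: float = 0.02
    background_fraction: float = 0.005
    enabled: bool = True

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(enabled=False)


@dataclass(frozen=True)
class OpticsModel:
    """Idealised camera optics.

    Vignetting follows the cos^4 field-angle law for a lens focused at the
    scintillator centre at the given working distance.  Perspective/refraction
    reprojection is represented by the identity mapping (the contract slot for
    a per-camera homography lives in the signal module); lens distortion is
    not modelled.
    """

    working_distance: float = 425.0
    vignetting: bool = True
    correction_floor: float = 0.05


@dataclass
class CameraView:
    """One camera's (cropped) image of a single pencil beam.

    ``pixels`` is indexed [lateral, depth] for the top view (lateral = x) and
    the lateral view (lateral = y), and [x, y] for the distal view.
    ``origin`` gives the mm coordinates of the centre of pixel [0, 0] in the
    camera plane, so cropped views keep their absolute position (needed for
    vignetting and for reassembling fields of view).
    """

    view_id: str
    pixels: np.ndarray
    pixel_size: float = PIXEL_SIZE_MM
    origin: tuple[float, float] = (0.0, 0.0)
    reliable: np.ndarray | None = None  # set by optics correction when pixels fall below the cos^4 floor

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.pixels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.pixel_size


@dataclass
class PencilBeamRecord:
    """One pencil beam: nominal spot, timestamp, camera views, and (after the
    signal stage) the extracted WET samples."""

    spot_index: int
    nominal_position: tuple[float, float]
    timestamp: float
    frame_index: int
    views: dict[str, CameraView] = field(default_factory=dict)
    no_signal: bool = False
    samples: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Scan patterns
# ---------------------------------------------------------------------------


@dataclass
class ScanPattern:
    """Ordered, timestamped spot positions for one or more frames."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    frame_index: np.ndarray
    pattern_type: str
    field: tuple[float, float]
    spacing: float
    spot_time: float
    n_passes: int = 1

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.max()) + 1 if self.frame_index.size else 0

    @property
    def spots_per_frame(self) -> int:
        return int(np.sum(self.frame_index == 0))

    def frame(self, f: int) -> "ScanPattern":
        m = self.frame_index == f
        return ScanPattern(
            self.x[m], self.y[m], self.t[m], self.frame_index[m],
            self.pattern_type, self.field, self.spacing, self.spot_time, self.n_passes,
        )

    def frame_time(self, f: int) -> float:
        """Median beam timestamp of frame ``f`` (the frame's assigned time)."""
        return float(np.median(self.t[self.frame_index == f]))


def _grid(field: tuple[float, float], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    w, h = field
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if w < spacing or h < spacing:
        raise ValueError("field dimensions must be >= spacing")
    nx = int(round(w / spacing)) + 1
    ny = int(round(h / spacing)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    return xs, ys


def _spiral_order(nx: int, ny: int) -> list[tuple[int, int]]:
    """Outside-in rectangular spiral over an nx (columns) x ny (rows) grid."""
    order = []
    i0, i1, j0, j1 = 0, nx - 1, 0, ny - 1
    while i0 <= i1 and j0 <= j1:
        order.extend((i, j0) for i in range(i0, i1 + 1))
        order.extend((i1, j) for j in range(j0 + 1, j1 + 1))
        if j1 > j0:
            order.extend((i, j1) for i in range(i1 - 1, i0 - 1, -1))
        if i1 > i0:
            order.extend((i0, j) for j in range(j1 - 1, j0, -1))
        i0, i1, j0, j1 = i0 + 1, i1 - 1, j0 + 1, j1 - 1
    return order


def make_scan_pattern(
    field: tuple[float, float],
    spacing: float,
    pattern_type: str,
    spot_time: float,
    n_frames: int = 1,
    n_passes: int = 2,
) -> ScanPattern:
    """Build a timestamped scan pattern over the grid covering ``field``.

    Grid nodes lie at ``spacing`` over the field, inclusive of both edges.
    ``horizontal`` is a serpentine row-major raster (rows advance vertically,
    the beam sweeps laterally), ``vertical`` serpentine column-major,
    ``spiral`` an outside-in rectangular spiral, and ``interleaved`` performs
    ``n_passes`` passes over the horizontal raster, pass k visiting every
    n_passes-th spot starting at offset k (the optically-triggered multi-pass
    workaround).  The traversal direction reverses between consecutive frames.
    Timestamps accumulate globally in steps of ``spot_time``.
    """
    xs, ys = _grid(field, spacing)
    nx, ny = len(xs), len(ys)
    if pattern_type in ("horizontal", "interleaved"):
        base = [(i if j % 2 == 0 else nx - 1 - i, j) for j in range(ny) for i in range(nx)]
        if pattern_type == "interleaved":
            if n_passes < 1:
                raise ValueError("n_passes must be >= 1")
            base = [base[k] for p in range(n_passes) for k in range(p, len(base), n_passes)]
    elif pattern_type == "vertical":
        base = [(i, j if i % 2 == 0 else ny - 1 - j) for i in range(nx) for j in range(ny)]
    elif pattern_type == "spiral":
        base = _spiral_order(nx, ny)
    else:
        raise ValueError(f"unknown pattern_type {pattern_type!r}")

    n = len(base)
    xi, yi, ti, fi = [], [], [], []
    for f in range(n_frames):
        order = base if f % 2 == 0 else base[::-1]
        xi.extend(xs[i] for i, _ in order)
        yi.extend(ys[j] for _, j in order)
        t0 = f * n * spot_time
        ti.extend(t0 + k * spot_time for k in range(n))
        fi.extend([f] * n)
    return ScanPattern(
        np.asarray(xi), np.asarray(yi), np.asarray(ti), np.asarray(fi, int),
        pattern_type, tuple(field), spacing, spot_time, n_passes if pattern_type == "interleaved" else 1,
    )


def field_for_insert(insert_diameter: float, amplitude: float, spacing: float = 5.0) -> tuple[float, float]:
    """Field size encompassing the insert over the largest programmed motion
    with a 1 cm margin around the edge, rounded up to spot-spacing multiples.

    Reproduces the published fields: 90x50 mm for a 30 mm insert with 20 mm
    motion, 80x40 for 20 mm, 70x30 for 10 mm.
    """
    if insert_diameter <= 0 or amplitude < 0:
        raise ValueError("insert_diameter must be > 0 and amplitude >= 0")
    w = insert_diameter + 2.0 * amplitude + 20.0
    h = insert_diameter + 20.0
    w = spacing * math.ceil(w / spacing - 1e-9)
    h = spacing * math.ceil(h / spacing - 1e-9)
    return (w, h)


def pattern_to_csv(pattern: ScanPattern, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "spot_index": np.arange(pattern.x.size),
            "x_mm": pattern.x,
            "y_mm": pattern.y,
            "t_s": pattern.t,
            "frame": pattern.frame_index,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Vignetting
# ---------------------------------------------------------------------------


def _cos4(r2: np.ndarray, working_distance: float) -> np.ndarray:
    return (1.0 + r2 / working_distance ** 2) ** -2


def vignetting_factors(view: CameraView, optics: OpticsModel, scint_depth: float = 200.0) -> np.ndarray:
    """cos^4 field-angle factor per pixel (1 on the optical axis).

    The optical axis of each camera points at the centre of the scintillator:
    for the top and lateral views that is (lateral = 0, depth = L/2); for the
    distal view, (x, y) = (0, 0).
    """
    a0 = view.axis_coords(0)
    a1 = view.axis_coords(1)
    if view.view_id in ("top", "lateral"):
        a1 = a1 - scint_depth / 2.0
    r2 = a0[:, None] ** 2 + a1[None, :] ** 2
    return _cos4(r2, optics.working_distance)


def apply_vignetting(view: CameraView, optics: OpticsModel, scint_depth: float = 200.0) -> CameraView:
    """Attenuate a view by the cos^4 vignetting law (no-op if disabled)."""
    if not optics.vignetting:
        return view
    f = vignetting_factors(view, optics, scint_depth)
    return CameraView(view.view_id, view.pixels * f, view.pixel_size, view.origin)


# ---------------------------------------------------------------------------
# Pencil-beam simulation
# ---------------------------------------------------------------------------


def _subray_offsets(beam: BeamModel, sub_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-ray offset grid (0.5 mm pitch over +-2 sigma) and its 1-D Gaussian
    weights (the 2-D weight is the outer product)."""
    sigma = beam.sigma_entrance
    half = math.floor(2.0 * sigma / sub_spacing) * sub_spacing
    off = np.arange(-half, half + sub_spacing / 2.0, sub_spacing)
    w = np.exp(-0.5 * (off / sigma) ** 2)
    return off, w / w.sum()


def simulate_spots(
    phantom: PhantomModel,
    motion: MotionModel | None,
    beam: BeamModel,
    xs: np.ndarray,
    ys: np.ndarray,
    ts: np.ndarray,
    frame_indices: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
    optics: OpticsModel = OpticsModel(),
    rng: np.random.Generator | None = None,
    sub_spacing: float = 0.5,
    spot_offset: int = 0,
) -> list[PencilBeamRecord]:
    """Simulate camera views for a batch of pencil beams (vectorised core).

    All beams share one cropped depth window (chosen from the span of their
    Bragg-peak depths); each record's views keep their absolute origin.
    """
    rng = rng or np.random.default_rng()
    xs = np.atleast_1d(np.asarray(xs, float))
    ys = np.atleast_1d(np.asarray(ys, float))
    ts = np.atleast_1d(np.asarray(ts, float))
    frame_indices = np.atleast_1d(np.asarray(frame_indices, int))
    n = xs.size
    off, w1 = _subray_offsets(beam, sub_spacing)
    k = off.size
    X = xs[:, None, None] + off[None, :, None]
    Y = ys[:, None, None] + off[None, None, :]
    wet = wet_parallel_rays(phantom, X, Y, ts[:, None, None], motion)
    r0 = beam.range_R0
    z_r = (r0 - wet) / beam.scintillator_rsp
    valid = (wet < r0) & (z_r <= beam.scintillator_depth)
    no_signal = ~valid.any(axis=(1, 2))

    tmpl = beam.template()
    px = PIXEL_SIZE_MM
    if valid.any():
        z_lo = max(0.0, float(z_r[valid].min()) + tmpl.U_MIN - 2.0)
        z_hi = min(beam.scintillator_depth, float(z_r[valid].max()) + tmpl.U_MAX + 2.0)
    else:
        z_lo, z_hi = 0.0, beam.scintillator_depth
    nz = max(int(math.ceil((z_hi - z_lo) / px)), 8)

    # lateral pixel grid shared (relative to each beam's nominal position)
    half_lat = off[-1] + 1.0
    nlat = int(math.ceil(2.0 * half_lat / px)) + 1
    lat0 = -((nlat - 1) / 2.0) * px  # centre of pixel 0 relative to nominal
    col = np.clip(np.round((off - lat0) / px).astype(int), 0, nlat - 1)

    w2 = w1[:, None] * w1[None, :]
    raw_top = np.zeros((n, nlat, nz))
    raw_lat = np.zeros((n, nlat, nz))
    distal = np.zeros((n, nlat, nlat))

    b_idx, i_idx, j_idx = np.nonzero(valid)
    if b_idx.size:
        zf = (z_r[b_idx, i_idx, j_idx] - z_lo) / px - 0.5
        z0i = np.floor(zf).astype(int)
        fz = zf - z0i
        wv = w2[i_idx, j_idx]
        for zi, wz in ((z0i, wv * (1 - fz)), (z0i + 1, wv * fz)):
            ok = (zi >= 0) & (zi < nz)
            flat_t = (b_idx[ok] * nlat + col[i_idx[ok]]) * nz + zi[ok]
            np.add.at(raw_top.ravel(), flat_t, wz[ok])
            flat_l = (b_idx[ok] * nlat + col[j_idx[ok]]) * nz + zi[ok]
            np.add.at(raw_lat.ravel(), flat_l, wz[ok])
        flat_d = (b_idx * nlat + col[i_idx]) * nlat + col[j_idx]
        np.add.at(distal.ravel(), flat_d, wv * tmpl.integral)

    kern, n_lo = tmpl.kernel(px)
    full_t = fftconvolve(raw_top, kern[None, None, :], mode="full")
    full_l = fftconvolve(raw_lat, kern[None, None, :], mode="full")
    top = np.clip(full_t[:, :, n_lo : n_lo + nz], 0.0, None)
    lat = np.clip(full_l[:, :, n_lo : n_lo + nz], 0.0, None)

    if optics.vignetting:
        zc = z_lo + (np.arange(nz) + 0.5) * px - beam.scintillator_depth / 2.0
        lat_abs_t = xs[:, None] + lat0 + np.arange(nlat)[None, :] * px
        lat_abs_l = ys[:, None] + lat0 + np.arange(nlat)[None, :] * px
        top *= _cos4(lat_abs_t[:, :, None] ** 2 + zc[None, None, :] ** 2, optics.working_distance)
        lat *= _cos4(lat_abs_l[:, :, None] ** 2 + zc[None, None, :] ** 2, optics.working_distance)
        dx = xs[:, None] + lat0 + np.arange(nlat)[None, :] * px
        dy = ys[:, None] + lat0 + np.arange(nlat)[None, :] * px
        distal *= _cos4(dx[:, :, None] ** 2 + dy[:, None, :] ** 2, optics.working_distance)

    if noise.enabled:
        for arr in (top, lat, distal):
            arr *= 1.0 + noise.multiplicative_sigma * rng.standard_normal(arr.shape)
            peak = arr.max(axis=(1, 2), keepdims=True)
            arr += noise.background_fraction * peak * rng.standard_normal(arr.shape)
            np.clip(arr, 0.0, None, out=arr)

    records = []
    for b in range(n):
        z_origin = z_lo + 0.5 * px  # centre of the first depth pixel
        views = {
            "top": CameraView("top", np.ascontiguousarray(top[b]), px, (xs[b] + lat0, z_origin)),
            "lateral": CameraView("lateral", np.ascontiguousarray(lat[b]), px, (ys[b] + lat0, z_origin)),
            "distal": CameraView("distal", np.ascontiguousarray(distal[b]), px, (xs[b] + lat0, ys[b] + lat0)),
        }
        records.append(
            PencilBeamRecord(
                spot_index=spot_offset + b,
                nominal_position=(float(xs[b]), float(ys[b])),
                timestamp=float(ts[b]),
                frame_index=int(frame_indices[b]),
                views=views,
                no_signal=bool(no_signal[b]),
            )
        )
    return records


def simulate_pencil_beam(
    phantom: PhantomModel,
    motion: MotionModel | None,
    beam: BeamModel,
    spot: tuple[float, float],
    t: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    optics: OpticsModel = OpticsModel(),
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
    sub_spacing: float = 0.5,
) -> PencilBeamRecord:
    """Simulate the camera views of a single pencil beam at ``spot`` (mm)."""
    return simulate_spots(
        phantom, motion, beam,
        np.array([spot[0]]), np.array([spot[1]]), np.array([t]), np.array([frame_index]),
        noise, optics, rng, sub_spacing,
    )[0]


def simulate_frame(
    phantom: PhantomModel,
    motion: MotionModel | None,
    beam: BeamModel,
    pattern: ScanPattern,
    frame: int,
    noise: NoiseSpec = NoiseSpec(),
    optics: OpticsModel = OpticsModel(),
    rng: np.random.Generator | None = None,
    sub_spacing: float = 0.5,
) -> list[PencilBeamRecord]:
    """Simulate every pencil beam of one frame of a scan pattern."""
    m = pattern.frame_index == frame
    if not m.any():
        raise ValueError(f"pattern has no frame {frame}")
    return simulate_spots(
        phantom, motion, beam,
        pattern.x[m], pattern.y[m], pattern.t[m], pattern.frame_index[m],
        noise, optics, rng, sub_spacing, spot_offset=int(np.nonzero(m)[0][0]),
    )


# ---------------------------------------------------------------------------
# Per-beam view persistence (32-bit float TIFF stacks + JSON sidecar)
# ---------------------------------------------------------------------------


def save_beam_records(records: Sequence[PencilBeamRecord], directory: str | Path) -> None:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for r in records:
        entry = {
            "spot_index": r.spot_index,
            "nominal_position": list(r.nominal_position),
            "timestamp": r.timestamp,
            "frame_index": r.frame_index,
            "no_signal": r.no_signal,
            "views": {},
        }
        for vid, v in r.views.items():
            fn = f"beam_{r.spot_index:05d}_{vid}.tif"
            tifffile.imwrite(directory / fn, v.pixels.astype(np.float32))
            entry["views"][vid] = {"file": fn, "pixel_size": v.pixel_size, "origin": list(v.origin)}
        meta.append(entry)
    (directory / "beams.json").write_text(json.dumps(meta, indent=1))


def load_beam_records(directory: str | Path) -> list[PencilBeamRecord]:
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "beams.json").read_text())
    records = []
    for entry in meta:
        views = {
            vid: CameraView(
                vid,
                tifffile.imread(directory / v["file"]).astype(float),
                v["pixel_size"],
                tuple(v["origin"]),
            )
            for vid, v in entry["views"].items()
        }
        records.append(
            PencilBeamRecord(
                spot_index=entry["spot_index"],
                nominal_position=tuple(entry["nominal_position"]),
                timestamp=entry["timestamp"],
                frame_index=entry["frame_index"],
                views=views,
                no_signal=entry["no_signal"],
            )
        )
    return records
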