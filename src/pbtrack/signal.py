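"""Per-beam signal chain: optics correction, pristine-peak extraction, and
depth-to-WET conversion.

Each pencil beam yields two 1-D WET profiles: the top view resolves WET along
the lateral (x) axis, the lateral view along the vertical (y) axis.  For every
camera column whose integrated intensity clears a noise floor, the depth of
the pristine Bragg peak is localised on the falling (distal) edge at 80% of
the column peak, converted to the residual-range depth via the template
calibration, and then to the WET traversed:

    WET = R0 - depth * RSP_scint

The two profiles are combined into 2-D WET samples for the reconstruction
stage by pairing every lateral position with every vertical position of the
same beam (weights multiply; WETs average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import BeamModel, CameraView, OpticsModel, PencilBeamRecord, vignetting_factors

__all__ = [
    "WETSample",
    "WET_SAMPLE_DTYPE",
    "BeamProfiles",
    "correct_vignetting",
    "extract_pristine_peaks",
    "depth_to_wet",
    "beam_wet_samples",
    "samples_to_csv",
]

# WET samples are held in structured arrays for speed; WETSample mirrors one row.
WET_SAMPLE_DTYPE = np.dtype(
    [("x", "f8"), ("y", "f8"), ("wet", "f8"), ("weight", "f8")]
)


@dataclass(frozen=True)
class WETSample:
    """A single (lateral position, WET) measurement with a deposition weight."""

    lateral_x: float
    lateral_y: float
    wet: float
    weight: float

    def __post_init__(self) -> None:
        if self.wet < 0 or self.weight < 0:
            raise ValueError("wet and weight must be >= 0")


@dataclass
class BeamProfiles:
    """Per-beam 1-D WET-relevant profiles extracted from the two side views.

    ``x_*`` come from the top view (positions along the lateral/x axis),
    ``y_*`` from the lateral view (positions along the vertical/y axis);
    ``*_depth`` is the residual-range depth in the scintillator (mm).
    """

    x_pos: np.ndarray
    x_depth: np.ndarray
    x_weight: np.ndarray
    y_pos: np.ndarray
    y_depth: np.ndarray
    y_weight: np.ndarray

    @property
    def empty(self) -> bool:
        return self.x_pos.size == 0 or self.y_pos.size == 0


def correct_vignetting(
    view: CameraView, optics: OpticsModel, scint_depth: float = 200.0
) -> CameraView:
    """Exact inverse of the cos^4 vignetting attenuation.

    Pixels whose cos^4 factor falls below ``optics.correction_floor`` are
    flagged unreliable in the returned view's ``reliable`` mask (the
    correction there amplifies noise beyond use); their values are still
    divided out.
    """
    if not optics.vignetting:
        return view
    f = vignetting_factors(view, optics, scint_depth)
    out = CameraView(view.view_id, view.pixels / f, view.pixel_size, view.origin)
    out.reliable = f >= optics.correction_floor
    return out


def _extract_columns(
    view: CameraView,
    distal80_offset: float,
    noise_floor: float,
    method: str,
    peak_offset: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise peak depths for one view.

    Returns (lateral positions mm, residual-range depths mm, weights).
    """
    img = view.pixels
    if view.reliable is not None:
        img = np.where(view.reliable, img, 0.0)
    col_int = img.sum(axis=1)
    if col_int.max() <= 0:
        return (np.empty(0),) * 3
    keep = np.nonzero(col_int >= noise_floor * col_int.max())[0]
    if keep.size == 0:
        return (np.empty(0),) * 3
    prof = img[keep]  # (ncols, ndepth)
    nz = prof.shape[1]
    m = np.argmax(prof, axis=1)
    pm = prof[np.arange(keep.size), m]
    if method == "argmax":
        depth_px = m.astype(float)
        calib = peak_offset
    elif method == "distal80":
        target = 0.8 * pm
        idx = np.arange(nz)[None, :]
        below = (idx > m[:, None]) & (prof < target[:, None])
        has = below.any(axis=1)
        j = np.argmax(below, axis=1)
        jm1 = np.maximum(j - 1, 0)
        p_hi = prof[np.arange(keep.size), jm1]
        p_lo = prof[np.arange(keep.size), j]
        denom = np.where(p_hi > p_lo, p_hi - p_lo, 1.0)
        frac = (p_hi - target) / denom
        depth_px = jm1 + frac
        keep = keep[has]
        depth_px = depth_px[has]
        calib = distal80_offset
        if keep.size == 0:
            return (np.empty(0),) * 3
    else:
        raise ValueError(f"unknown peak localisation method {method!r}")
    lat = view.origin[0] + keep * view.pixel_size
    depth = view.origin[1] + depth_px * view.pixel_size - calib
    return lat, depth, col_int[keep]


def extract_pristine_peaks(
    top: CameraView,
    lateral: CameraView,
    beam: BeamModel,
    noise_floor: float = 0.05,
    method: str = "distal80",
) -> BeamProfiles:
    """Extract pristine-peak depths per lateral position from the two views.

    A camera column enters the profile if its integrated intensity is at
    least ``noise_floor`` (default 5%) of the strongest column, which rejects
    scatter tails without dropping the beam penumbra.  The peak is localised
    at the 80%-of-peak point on the distal falling edge by linear
    interpolation (more robust to peak-shape distortion than the argmax,
    which remains available via ``method="argmax"``); the template's known
    falloff-to-range offset is subtracted so the returned depth estimates the
    residual-range depth z_R.
    """
    if top.pixel_size != lateral.pixel_size:
        raise ValueError("views must share pixel_size")
    tmpl = beam.template()
    xp, xd, xw = _extract_columns(top, tmpl.distal80_offset, noise_floor, method, tmpl.peak_offset)
    yp, yd, yw = _extract_columns(lateral, tmpl.distal80_offset, noise_floor, method, tmpl.peak_offset)
    return BeamProfiles(xp, xd, xw, yp, yd, yw)


def depth_to_wet(depth, beam: BeamModel):
    """WET (mm water) traversed upstream, from the residual-range depth in
    the scintillator: WET = R0 - depth * RSP_scint.  Monotone decreasing in
    depth; negative results are clipped to zero with a warning."""
    wet = beam.range_R0 - np.asarray(depth, float) * beam.scintillator_rsp
    if np.any(wet < 0):
        warnings.warn("depth beyond beam range: WET clipped to 0", stacklevel=2)
        wet = np.clip(wet, 0.0, None)
    if wet.ndim == 0:
        return float(wet)
    return wet


def beam_wet_samples(
    record: PencilBeamRecord,
    beam: BeamModel,
    optics: OpticsModel = OpticsModel(),
    noise_floor: float = 0.05,
    method: str = "distal80",
) -> np.ndarray:
    """Full per-beam chain: optics correction -> peak extraction -> WET.

    Returns a structured array (fields x, y, wet, weight).  The lateral (x)
    and vertical (y) profiles are combined as an outer product: sample WET is
    the mean of the two 1-D estimates and weights multiply (each profile's
    weights are normalised to unit sum, so every beam carries unit total
    weight).  Beams flagged ``no_signal`` or with empty profiles yield an
    empty array, which propagates as a missing beam.
    """
    if record.no_signal:
        return np.empty(0, dtype=WET_SAMPLE_DTYPE)
    top = correct_vignetting(record.views["top"], optics)
    lat = correct_vignetting(record.views["lateral"], optics)
    prof = extract_pristine_peaks(top, lat, beam, noise_floor, method)
    if prof.empty:
        return np.empty(0, dtype=WET_SAMPLE_DTYPE)
    wet_x = depth_to_wet(prof.x_depth, beam)
    wet_y = depth_to_wet(prof.y_depth, beam)
    wx = prof.x_weight / prof.x_weight.sum()
    wy = prof.y_weight / prof.y_weight.sum()
    nx, ny = wet_x.size, wet_y.size
    out = np.empty(nx * ny, dtype=WET_SAMPLE_DTYPE)
    out["x"] = np.repeat(prof.x_pos, ny)
    out["y"] = np.tile(prof.y_pos, nx)
    out["wet"] = 0.5 * (np.repeat(wet_x, ny) + np.tile(wet_y, nx))
    out["weight"] = np.repeat(wx, ny) * np.tile(wy, nx)
    return out


def samples_to_csv(records, path) -> None:
    """Persist the WET samples of a set of beams as CSV."""
    import pandas as pd

    rows = [
        pd.DataFrame(
            {
                "beam_id": r.spot_index,
                "x_mm": r.samples["x"],
                "y_mm": r.samples["y"],
                "wet_mm": r.samples["wet"],
                "weight": r.samples["weight"],
            }
        )
        for r in records
        if r.samples is not None and r.samples.size
    ]
    (pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["beam_id", "x_mm", "y_mm", "wet_mm", "weight"]
    )).to_csv(path, index=False)
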