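"""Phantoms, materials and periodic motion.

The scene layer answers one physical question: how much water-equivalent
thickness (WET) does a ray accumulate through the phantom at time ``t``?
Phantoms are small collections of geometric primitives, each tagged with a
material of known relative stopping power (RSP); WET along a ray is the sum of
``chord length x RSP`` over the materials traversed.  One primitive (the tumor
insert) translates along a fixed axis following a periodic breathing-like
waveform.

Coordinate conventions: right-handed millimetre coordinates, the beam travels
along +z, the motion axis is +x (the lateral axis of the radiograph), image
coordinates are (x lateral, y vertical) with the origin at the field centre.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Material",
    "AIR",
    "LUNG",
    "SOFT_TISSUE",
    "BONE_TRABECULAR",
    "BONE_CORTICAL",
    "PMMA",
    "WATER",
    "Primitive",
    "PhantomModel",
    "MotionModel",
    "displacement",
    "build_thorax_phantom",
    "build_slab_phantom",
    "center_moving_primitive",
    "wet_line_integral",
    "wet_parallel_rays",
    "phantom_to_json",
    "phantom_from_json",
    "motion_from_dict",
    "phantom_from_dict",
]


@dataclass(frozen=True)
class Material:
    """A material with a relative stopping power (RSP) > 0 (water = 1)."""

    name: str
    rsp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rsp) or self.rsp < 0:
            raise ValueError(f"material {self.name!r}: rsp must be finite and >= 0")


# Default RSP values approximate the mass densities quoted for the phantom
# materials (RSP ~ density in g/cm^3 holds well for tissue-like media at this
# fidelity); PMMA and the water-equivalent insert use their standard values.
AIR = Material("air", 0.0)
LUNG = Material("lung", 0.21)
SOFT_TISSUE = Material("soft_tissue", 1.04)
BONE_TRABECULAR = Material("bone_trabecular", 1.20)
BONE_CORTICAL = Material("bone_cortical", 1.91)
PMMA = Material("pmma", 1.16)
WATER = Material("water", 1.00)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Primitive:
    """One geometric primitive of a phantom.

    Shapes
    ------
    slab
        axis-aligned box; params ``lo``/``hi`` are the corner coordinates.
    sphere
        params ``center`` and ``radius``.
    cylinder
        circular cylinder; params ``axis`` ("x"/"y"/"z"), ``center``,
        ``radius``, ``half_length``.
    elliptic_cylinder
        like cylinder but with two semi-axes for the cross-section, named
        after the two coordinates perpendicular to ``axis`` in x, y, z order
        (``semi_a``, ``semi_b``).

    ``parent`` names the primitive this one is nested inside (or ``None`` for
    the background); inside the child, the child's material replaces the
    parent's.  The list order of primitives in a phantom is the override
    priority: later primitives win where primitives overlap along a ray.
    """

    name: str
    shape: str
    material: Material
    params: dict
    parent: str | None = None
    moving: bool = False

    def center(self) -> np.ndarray:
        if self.shape == "slab":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            return 0.5 * (lo + hi)
        return np.asarray(self.params["center"], float)

    def translated(self, offset: Sequence[float]) -> "Primitive":
        off = np.asarray(offset, float)
        p = dict(self.params)
        if self.shape == "slab":
            p["lo"] = (np.asarray(p["lo"], float) + off).tolist()
            p["hi"] = (np.asarray(p["hi"], float) + off).tolist()
        else:
            p["center"] = (np.asarray(p["center"], float) + off).tolist()
        return replace(self, params=p)

    # -- point membership (used by the exact integrator) ------------------
    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self.shape == "slab":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            return np.all((pts >= lo) & (pts <= hi), axis=1)
        if self.shape == "sphere":
            c = np.asarray(self.params["center"], float)
            r = float(self.params["radius"])
            return np.sum((pts - c) ** 2, axis=1) <= r * r
        if self.shape in ("cylinder", "elliptic_cylinder"):
            ax = _AXES[self.params["axis"]]
            perp = [i for i in range(3) if i != ax]
            c = np.asarray(self.params["center"], float)
            hl = float(self.params["half_length"])
            d0 = pts[:, perp[0]] - c[perp[0]]
            d1 = pts[:, perp[1]] - c[perp[1]]
            if self.shape == "cylinder":
                r = float(self.params["radius"])
                inside = d0 * d0 + d1 * d1 <= r * r
            else:
                a = float(self.params["semi_a"])
                b = float(self.params["semi_b"])
                inside = (d0 / a) ** 2 + (d1 / b) ** 2 <= 1.0
            return inside & (np.abs(pts[:, ax] - c[ax]) <= hl)
        raise ValueError(f"unknown shape {self.shape!r}")

    # -- ray interval [t_in, t_out] (used by the exact integrator) ---------
    def ray_interval(self, origin: np.ndarray, direction: np.ndarray) -> tuple[float, float] | None:
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        if self.shape == "slab":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            t0, t1 = -np.inf, np.inf
            for i in range(3):
                if d[i] == 0.0:
                    if not (lo[i] <= o[i] <= hi[i]):
                        return None
                else:
                    a = (lo[i] - o[i]) / d[i]
                    b = (hi[i] - o[i]) / d[i]
                    t0 = max(t0, min(a, b))
                    t1 = min(t1, max(a, b))
            return (t0, t1) if t1 > t0 else None
        if self.shape == "sphere":
            c = np.asarray(self.params["center"], float)
            r = float(self.params["radius"])
            oc = o - c
            b = float(np.dot(oc, d))
            disc = b * b - (float(np.dot(oc, oc)) - r * r)
            if disc <= 0:
                return None
            s = math.sqrt(disc)
            return (-b - s, -b + s)
        if self.shape in ("cylinder", "elliptic_cylinder"):
            ax = _AXES[self.params["axis"]]
            perp = [i for i in range(3) if i != ax]
            c = np.asarray(self.params["center"], float)
            hl = float(self.params["half_length"])
            if self.shape == "cylinder":
                a = b = float(self.params["radius"])
            else:
                a = float(self.params["semi_a"])
                b = float(self.params["semi_b"])
            # scaled coordinates turn the ellipse into a unit circle
            ox = (o[perp[0]] - c[perp[0]]) / a
            oy = (o[perp[1]] - c[perp[1]]) / b
            dx = d[perp[0]] / a
            dy = d[perp[1]] / b
            A = dx * dx + dy * dy
            if A == 0.0:
                if ox * ox + oy * oy > 1.0:
                    return None
                t0, t1 = -np.inf, np.inf
            else:
                B = ox * dx + oy * dy
                disc = B * B - A * (ox * ox + oy * oy - 1.0)
                if disc <= 0:
                    return None
                s = math.sqrt(disc)
                t0 = (-B - s) / A
                t1 = (-B + s) / A
            # clip to the end caps
            if d[ax] == 0.0:
                if abs(o[ax] - c[ax]) > hl:
                    return None
            else:
                a0 = (c[ax] - hl - o[ax]) / d[ax]
                a1 = (c[ax] + hl - o[ax]) / d[ax]
                t0 = max(t0, min(a0, a1))
                t1 = min(t1, max(a0, a1))
            return (t0, t1) if t1 > t0 else None
        raise ValueError(f"unknown shape {self.shape!r}")

    # -- chord length along +z for a bundle of parallel rays ---------------
    def chords_z(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        if self.shape == "slab":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            inside = (xs >= lo[0]) & (xs <= hi[0]) & (ys >= lo[1]) & (ys <= hi[1])
            return np.where(inside, hi[2] - lo[2], 0.0)
        if self.shape == "sphere":
            c = np.asarray(self.params["center"], float)
            r = float(self.params["radius"])
            d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2
            return 2.0 * np.sqrt(np.clip(r * r - d2, 0.0, None))
        if self.shape in ("cylinder", "elliptic_cylinder"):
            ax = self.params["axis"]
            c = np.asarray(self.params["center"], float)
            hl = float(self.params["half_length"])
            if self.shape == "cylinder":
                r = float(self.params["radius"])
                if ax == "z":
                    d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2
                    return np.where(d2 <= r * r, 2.0 * hl, 0.0)
                if ax == "x":
                    chord = 2.0 * np.sqrt(np.clip(r * r - (ys - c[1]) ** 2, 0.0, None))
                    return np.where(np.abs(xs - c[0]) <= hl, chord, 0.0)
                chord = 2.0 * np.sqrt(np.clip(r * r - (xs - c[0]) ** 2, 0.0, None))
                return np.where(np.abs(ys - c[1]) <= hl, chord, 0.0)
            # elliptic cylinder: semi_a/semi_b follow coordinate order
            if ax == "x":  # cross-section in (y, z)
                a = float(self.params["semi_a"])  # y
                b = float(self.params["semi_b"])  # z
                u = (ys - c[1]) / a
                chord = 2.0 * b * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
                return np.where(np.abs(xs - c[0]) <= hl, chord, 0.0)
            if ax == "y":  # cross-section in (x, z)
                a = float(self.params["semi_a"])  # x
                b = float(self.params["semi_b"])  # z
                u = (xs - c[0]) / a
                chord = 2.0 * b * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
                return np.where(np.abs(ys - c[1]) <= hl, chord, 0.0)
            raise ValueError("elliptic cylinder along z has no z-chord shortcut")
        raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class PhantomModel:
    """An ordered set of primitives plus the identity of the moving insert.

    Exactly one primitive must be flagged ``moving``; overlaps are resolved
    deterministically (later primitives override earlier ones along a ray).
    """

    primitives: list[Primitive]
    moving_primitive_id: str
    background: Material = AIR

    def __post_init__(self) -> None:
        movers = [p for p in self.primitives if p.moving]
        if len(movers) != 1:
            raise ValueError("exactly one primitive must be flagged moving")
        if movers[0].name != self.moving_primitive_id:
            raise ValueError("moving_primitive_id does not match the flagged primitive")
        names = [p.name for p in self.primitives]
        if len(set(names)) != len(names):
            raise ValueError("primitive names must be unique")

    @property
    def moving_primitive(self) -> Primitive:
        return next(p for p in self.primitives if p.moving)

    def get(self, name: str) -> Primitive:
        return next(p for p in self.primitives if p.name == name)

    def material_rsp(self, name: str | None) -> float:
        if name is None:
            return self.background.rsp
        return self.get(name).material.rsp

    def at_time(self, t: float, motion: "MotionModel | None") -> list[Primitive]:
        """Primitives with the moving insert translated to its position at t."""
        if motion is None:
            return list(self.primitives)
        off = displacement(t, motion) * np.asarray(motion.axis, float)
        return [p.translated(off) if p.moving else p for p in self.primitives]

    def translated_moving(self, offset_mm: float, axis: Sequence[float] = (1.0, 0.0, 0.0)) -> "PhantomModel":
        """Copy with the moving primitive's rest position shifted."""
        off = offset_mm * np.asarray(axis, float)
        prims = [p.translated(off) if p.moving else p for p in self.primitives]
        return PhantomModel(prims, self.moving_primitive_id, self.background)

    def translated(self, offset: Sequence[float]) -> "PhantomModel":
        """Copy with every primitive shifted by ``offset`` (mm)."""
        prims = [p.translated(offset) for p in self.primitives]
        return PhantomModel(prims, self.moving_primitive_id, self.background)

    def centered_on_insert(self) -> "PhantomModel":
        """Copy translated so the moving primitive's rest centre is at the
        origin — the experimental alignment of insert and isocenter."""
        return self.translated(-self.moving_primitive.center())


@dataclass
class MotionModel:
    """Periodic 1-D displacement of the tumor insert.

    ``variant="as_printed"`` evaluates y(t) = -2A cos(4 pi t / T) + A, the
    waveform exactly as published; note it sweeps a 4A excursion with
    fundamental period T/2.  ``variant="peak_to_peak"`` (the default used for
    the tracking study) reads A as the peak-to-peak excursion:
    y(t) = (A/2) (1 - cos(2 pi t / T)), range [0, A], fundamental period T.
    """

    amplitude_A: float
    period_T: float
    variant: str = "peak_to_peak"
    phase_offset: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ValueError("period_T must be > 0")
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be >= 0")
        if self.variant not in ("as_printed", "peak_to_peak"):
            raise ValueError(f"unknown motion variant {self.variant!r}")
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0):
            object.__setattr__(self, "axis", tuple(np.asarray(self.axis, float) / n))

    @property
    def fundamental_period(self) -> float:
        return self.period_T / 2.0 if self.variant == "as_printed" else self.period_T

    @property
    def mean_displacement(self) -> float:
        """Time average of the displacement over one period (the cosine term
        averages to zero for both variants)."""
        return self.amplitude_A if self.variant == "as_printed" else self.amplitude_A / 2.0

    def displacement(self, t) -> np.ndarray | float:
        return displacement(t, self)


def displacement(t, motion: MotionModel):
    """Insert displacement (mm) along ``motion.axis`` at time ``t`` (s)."""
    t = np.asarray(t, float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    tt = t + motion.phase_offset
    A, T = motion.amplitude_A, motion.period_T
    if motion.variant == "as_printed":
        out = -2.0 * A * np.cos(4.0 * np.pi * tt / T) + A
    else:
        out = 0.5 * A * (1.0 - np.cos(2.0 * np.pi * tt / T))
    return out if out.ndim else float(out)


def build_thorax_phantom(
    insert_diameter: float,
    *,
    body_semi_y: float = 150.0,
    body_semi_z: float = 120.0,
    body_half_length: float = 200.0,
    lung_radius: float = 50.0,
    second_lung_offset_y: float = -90.0,
    second_lung_radius: float = 30.0,
    lung_half_length: float = 180.0,
    materials: dict[str, Material] | None = None,
) -> PhantomModel:
    """Thorax phantom: soft-tissue body, two lung compartments, spine, and a
    water-equivalent spherical tumor insert centred in one lung.

    The body is an elliptical cylinder whose axis lies along +x, the
    superior-inferior direction along which the insert moves; the lung
    compartments are cylinders with the same axis, so the lung path length of
    a beam-axis ray does not vary along the motion direction (the anatomy
    varies across the scan's slow axis instead, which is what the strip-wise
    segmentation is designed to absorb).  The imaged lung is concentric with
    the body cross-section, which makes the background of the imaging field
    symmetric about the insert; the second lung and the spine (cortical shell
    around a trabecular core) sit outside the field of view.
    """
    if insert_diameter <= 0:
        raise ValueError("insert_diameter must be > 0")
    m = {
        "soft_tissue": SOFT_TISSUE,
        "lung": LUNG,
        "bone_cortical": BONE_CORTICAL,
        "bone_trabecular": BONE_TRABECULAR,
        "insert": WATER,
    }
    if materials:
        m.update(materials)
    prims = [
        Primitive(
            "body",
            "elliptic_cylinder",
            m["soft_tissue"],
            dict(axis="x", center=[0.0, 0.0, 0.0], semi_a=body_semi_y, semi_b=body_semi_z, half_length=body_half_length),
        ),
        Primitive(
            "lung_second",
            "cylinder",
            m["lung"],
            dict(axis="x", center=[0.0, second_lung_offset_y, 0.0], radius=second_lung_radius, half_length=lung_half_length),
            parent="body",
        ),
        Primitive(
            "lung_imaged",
            "cylinder",
            m["lung"],
            dict(axis="x", center=[0.0, 0.0, 0.0], radius=lung_radius, half_length=lung_half_length),
            parent="body",
        ),
        Primitive(
            "spine_cortical",
            "cylinder",
            m["bone_cortical"],
            dict(axis="x", center=[0.0, second_lung_offset_y / 2.0, 85.0], radius=14.0, half_length=body_half_length),
            parent="body",
        ),
        Primitive(
            "spine_core",
            "cylinder",
            m["bone_trabecular"],
            dict(axis="x", center=[0.0, second_lung_offset_y / 2.0, 85.0], radius=9.0, half_length=body_half_length),
            parent="spine_cortical",
        ),
        Primitive(
            "insert",
            "sphere",
            m["insert"],
            dict(center=[0.0, 0.0, 0.0], radius=insert_diameter / 2.0),
            parent="lung_imaged",
            moving=True,
        ),
    ]
    return PhantomModel(prims, "insert")


def build_slab_phantom(
    *,
    proximal_mm: float = 70.0,
    distal_mm: float = 40.0,
    sphere_diameter: float = 30.0,
    gap_mm: float = 30.0,
    lateral_half: float = 150.0,
    pmma: Material = PMMA,
    sphere_material: Material = WATER,
) -> PhantomModel:
    """Simplified lung model: PMMA slabs with a water-equivalent sphere in the
    air gap between them (70 mm proximal, 40 mm distal along the beam)."""
    hg = gap_mm / 2.0
    prims = [
        Primitive(
            "proximal_slab",
            "slab",
            pmma,
            dict(lo=[-lateral_half, -lateral_half, -hg - proximal_mm], hi=[lateral_half, lateral_half, -hg]),
        ),
        Primitive(
            "distal_slab",
            "slab",
            pmma,
            dict(lo=[-lateral_half, -lateral_half, hg], hi=[lateral_half, lateral_half, hg + distal_mm]),
        ),
        Primitive(
            "insert",
            "sphere",
            sphere_material,
            dict(center=[0.0, 0.0, 0.0], radius=sphere_diameter / 2.0),
            moving=True,
        ),
    ]
    return PhantomModel(prims, "insert")


def center_moving_primitive(phantom: PhantomModel, motion: MotionModel) -> PhantomModel:
    """Shift the insert's rest position so that its *time-averaged* position
    over one motion period coincides with its nominal (field-centre) position.

    This is the registration used when comparing measured centroids against
    the programmed waveform: the field of view is centred on the mean insert
    position.
    """
    return phantom.translated_moving(-motion.mean_displacement, motion.axis)


# ---------------------------------------------------------------------------
# WET integrals
# ---------------------------------------------------------------------------

def wet_line_integral(
    phantom: PhantomModel,
    origin: Sequence[float],
    direction: Sequence[float],
    t: float = 0.0,
    motion: MotionModel | None = None,
) -> float:
    """Exact WET (mm water) along an arbitrary ray at time ``t``.

    The ray is partitioned at every primitive entry/exit point; each elementary
    segment is attributed to the highest-priority primitive containing its
    midpoint (priority = list order, later wins), or to the background.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or n == 0.0 or not np.all(np.isfinite(o)):
        raise ValueError("degenerate ray")
    d = d / n
    prims = phantom.at_time(t, motion)
    breakpoints: list[float] = []
    intervals = []
    for p in prims:
        iv = p.ray_interval(o, d)
        intervals.append(iv)
        if iv is not None:
            breakpoints.extend(iv)
    if not breakpoints:
        return 0.0
    bp = np.unique(np.asarray(breakpoints, float))
    if bp.size < 2:
        return 0.0
    mids = 0.5 * (bp[:-1] + bp[1:])
    pts = o[None, :] + mids[:, None] * d[None, :]
    rsp = np.full(mids.shape, phantom.background.rsp)
    for p in prims:  # later primitives override earlier ones
        inside = p.contains(pts)
        rsp[inside] = p.material.rsp
    lengths = np.diff(bp)
    return float(np.sum(lengths * rsp))


def wet_parallel_rays(
    phantom: PhantomModel,
    xs: np.ndarray,
    ys: np.ndarray,
    t: np.ndarray | float = 0.0,
    motion: MotionModel | None = None,
) -> np.ndarray:
    """Vectorised WET for bundles of rays parallel to +z.

    Valid for phantoms whose primitives form a containment hierarchy along
    every ray (child fully inside parent where both are hit), as the built-in
    phantoms do: the WET is then ``sum_p chord_p * (rsp_p - rsp_parent(p))``.
    ``t`` may be scalar or per-ray, allowing every pencil beam of a scan to
    see the insert at its own timestamp.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if motion is not None:
        off = np.multiply.outer(np.asarray(displacement(t, motion)), np.asarray(motion.axis, float))
    else:
        off = None
    wet = np.zeros(np.broadcast(xs, ys).shape, float)
    for p in phantom.primitives:
        drsp = p.material.rsp - phantom.material_rsp(p.parent)
        if p.moving and off is not None:
            # shift the rays instead of the primitive (equivalent, vectorised)
            chord = p.chords_z(xs - off[..., 0], ys - off[..., 1])
        else:
            chord = p.chords_z(xs, ys)
        wet = wet + drsp * chord
    return wet


# ---------------------------------------------------------------------------
# (De)serialisation — YAML config blocks and JSON scene descriptions
# ---------------------------------------------------------------------------

def _material_to_dict(m: Material) -> dict:
    return {"name": m.name, "rsp": m.rsp}


def phantom_to_dict(phantom: PhantomModel) -> dict:
    return {
        "background": _material_to_dict(phantom.background),
        "moving_primitive_id": phantom.moving_primitive_id,
        "primitives": [
            {
                "name": p.name,
                "shape": p.shape,
                "material": _material_to_dict(p.material),
                "params": p.params,
                "parent": p.parent,
                "moving": p.moving,
            }
            for p in phantom.primitives
        ],
    }


def phantom_from_dict(d: dict) -> PhantomModel:
    if "builder" in d:  # convenience: phantom: {builder: thorax, insert_diameter: 30}
        kind = d["builder"]
        kwargs = {k: v for k, v in d.items() if k != "builder"}
        if kind == "thorax":
            return build_thorax_phantom(**kwargs)
        if kind == "slab":
            return build_slab_phantom(**kwargs)
        raise ValueError(f"unknown phantom builder {kind!r}")
    prims = [
        Primitive(
            name=p["name"],
            shape=p["shape"],
            material=Material(**p["material"]),
            params=p["params"],
            parent=p.get("parent"),
            moving=p.get("moving", False),
        )
        for p in d["primitives"]
    ]
    bg = Material(**d.get("background", {"name": "air", "rsp": 0.0}))
    return PhantomModel(prims, d["moving_primitive_id"], bg)


def phantom_to_json(phantom: PhantomModel) -> str:
    return json.dumps(phantom_to_dict(phantom), indent=1)


def phantom_from_json(s: str) -> PhantomModel:
    return phantom_from_dict(json.loads(s))


def motion_from_dict(d: dict) -> MotionModel:
    return MotionModel(
        amplitude_A=float(d["amplitude_A"]),
        period_T=float(d["period_T"]),
        variant=d.get("variant", "peak_to_peak"),
        phase_offset=float(d.get("phase_offset", 0.0)),
        axis=tuple(d.get("axis", (1.0, 0.0, 0.0))),
    )


def motion_to_dict(m: MotionModel) -> dict:
    return {
        "amplitude_A": m.amplitude_A,
        "period_T": m.period_T,
        "variant": m.variant,
        "phase_offset": m.phase_offset,
        "axis": list(m.axis),
    }
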