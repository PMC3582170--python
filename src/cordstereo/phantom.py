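"""Parametric spinal-cord phantoms with analytically known geometry.

A phantom is an ordered stack of segments (C1..C8 by default).  Each
segment's gross cross-section (GS) is an ellipse whose semi-axes taper
linearly along the segment; the grey-matter "butterfly" is modelled as four
elliptical lobes (two dorsal horns DH, two ventral horns VH) joined by a
rectangular isthmus, with a small elliptical central canal (CC) at the
centre.  All compartment areas and volumes have closed forms, so the
phantom serves as an exact oracle for the point-counting and Cavalieri
estimators.

Conventions
-----------
* All geometry is in millimetres; the transverse (TD) axis is x and the
  vertical (VD) axis is y, dorsal being +y.
* White matter (WM) is GS minus the grey-matter union minus CC.
* A cross-section taken exactly at a segment boundary belongs to the
  caudal (later) segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "Ellipse",
    "Rect",
    "SegmentGeom",
    "PhantomSpec",
    "LabeledSection",
    "GroundTruth",
    "Phantom",
    "build_phantom",
    "apply_shrinkage",
    "default_spec",
    "DEFAULT_LABELS",
    "COMPOSITES",
]

#: default compartment label map; background is always 0
DEFAULT_LABELS: dict[str, int] = {"WM": 1, "DH": 2, "VH": 3, "GM_ISTHMUS": 4, "CC": 5}

#: composite regions measured as unions of base labels
COMPOSITES: dict[str, tuple[str, ...]] = {
    "GS": ("WM", "DH", "VH", "GM_ISTHMUS", "CC"),
    "GM": ("DH", "VH", "GM_ISTHMUS"),
}


class GeometryError(ValueError):
    """Raised when compartments overlap or escape the gross section."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: centre (cx, cy), semi-axes (a, b), in mm."""

    cx: float
    cy: float
    a: float
    b: float

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x - self.cx) / self.a) ** 2 + ((y - self.cy) / self.b) ** 2 <= 1.0

    def boundary(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return self.cx + self.a * np.cos(t), self.cy + self.b * np.sin(t)

    def scaled(self, fx: float, fy: float) -> "Ellipse":
        return Ellipse(self.cx * fx, self.cy * fy, self.a * fx, self.b * fy)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: centre (cx, cy), half-extents, in mm."""

    cx: float
    cy: float
    half_w: float
    half_h: float

    @property
    def area(self) -> float:
        return 4.0 * self.half_w * self.half_h

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (np.abs(x - self.cx) <= self.half_w) & (np.abs(y - self.cy) <= self.half_h)

    def scaled(self, fx: float, fy: float) -> "Rect":
        return Rect(self.cx * fx, self.cy * fy, self.half_w * fx, self.half_h * fy)


@dataclass(frozen=True)
class SegmentGeom:
    """Geometry of one segment.

    ``gs_start``/``gs_end`` are the (a, b) semi-axes of the gross-section
    ellipse at the cranial and caudal face; they interpolate linearly in
    between.  Horn lobes, isthmus and central canal are constant along the
    segment, which keeps their volumes exactly area x length.
    """

    name: str
    length: float
    gs_start: tuple[float, float]
    gs_end: tuple[float, float]
    dh: tuple[Ellipse, Ellipse]
    vh: tuple[Ellipse, Ellipse]
    isthmus: Rect
    cc: Ellipse

    def gs_semiaxes(self, frac: float) -> tuple[float, float]:
        """Semi-axes of the GS ellipse at fractional position ``frac`` in [0, 1]."""
        a = self.gs_start[0] + (self.gs_end[0] - self.gs_start[0]) * frac
        b = self.gs_start[1] + (self.gs_end[1] - self.gs_start[1]) * frac
        return a, b

    @property
    def lobes(self) -> tuple[Ellipse, ...]:
        return (*self.dh, *self.vh)

    def validate(self) -> None:
        if self.length <= 0:
            raise GeometryError(f"{self.name}: segment length must be > 0")
        for e in (*self.lobes, self.cc):
            if e.a <= 0 or e.b <= 0:
                raise GeometryError(f"{self.name}: semi-axes must be > 0")
        # every interior compartment must sit strictly inside the GS ellipse
        # at both faces (taper is linear, so the faces bound the interior)
        for face in (self.gs_start, self.gs_end):
            gs = Ellipse(0.0, 0.0, *face)
            for e in (*self.lobes, self.cc):
                bx, by = e.boundary()
                if not np.all((bx / gs.a) ** 2 + (by / gs.b) ** 2 < 1.0):
                    raise GeometryError(
                        f"{self.name}: compartment escapes the gross section"
                    )
            cx = np.array([self.isthmus.cx - self.isthmus.half_w,
                           self.isthmus.cx + self.isthmus.half_w])
            cy = np.array([self.isthmus.cy - self.isthmus.half_h,
                           self.isthmus.cy + self.isthmus.half_h])
            xx, yy = np.meshgrid(cx, cy)
            if not np.all((xx / gs.a) ** 2 + (yy / gs.b) ** 2 < 1.0):
                raise GeometryError(f"{self.name}: isthmus escapes the gross section")
        # structural disjointness: left/right lobes split by x, DH/VH by y,
        # lobes clear of the isthmus slab in x
        for pair in (self.dh, self.vh):
            left, right = sorted(pair, key=lambda e: e.cx)
            if left.cx + left.a > right.cx - right.a + 1e-12:
                raise GeometryError(f"{self.name}: left/right lobes overlap")
        for d in self.dh:
            for v in self.vh:
                same_side = (d.cx - d.a < v.cx + v.a) and (v.cx - v.a < d.cx + d.a)
                if same_side and d.cy - d.b < v.cy + v.b - 1e-12:
                    raise GeometryError(f"{self.name}: DH and VH lobes overlap")
        for e in self.lobes:
            if abs(e.cx) - e.a < self.isthmus.half_w - 1e-9:
                raise GeometryError(f"{self.name}: lobe overlaps the isthmus")
        # CC nested inside the grey isthmus
        bx, by = self.cc.boundary()
        if not np.all(self.isthmus.contains(bx, by)):
            raise GeometryError(f"{self.name}: central canal escapes the grey matter")

    def scaled(self, fx: float, fy: float, fz: float) -> "SegmentGeom":
        return SegmentGeom(
            name=self.name,
            length=self.length * fz,
            gs_start=(self.gs_start[0] * fx, self.gs_start[1] * fy),
            gs_end=(self.gs_end[0] * fx, self.gs_end[1] * fy),
            dh=tuple(e.scaled(fx, fy) for e in self.dh),
            vh=tuple(e.scaled(fx, fy) for e in self.vh),
            isthmus=self.isthmus.scaled(fx, fy),
            cc=self.cc.scaled(fx, fy),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: ordered segments plus rendering defaults."""

    segments: tuple[SegmentGeom, ...]
    pixel_size: float = 0.02
    label_map: Mapping[str, int] = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.label_map is None:
            object.__setattr__(self, "label_map", dict(DEFAULT_LABELS))
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        labels = list(self.label_map.values())
        if len(set(labels)) != len(labels) or 0 in labels:
            raise ValueError("labels must be distinct and nonzero (0 is background)")


@dataclass
class LabeledSection:
    """A rendered cross-section: integer label mask plus physical metadata.

    ``mask[row, col]`` covers the pixel whose centre is at
    ``(origin[0] + col * pixel_size, origin[1] + row * pixel_size)``;
    row index increases towards dorsal (+y).
    """

    mask: np.ndarray
    pixel_size: float
    z: float
    segment: str
    label_map: Mapping[str, int]
    origin: tuple[float, float]
    unit: str = "mm"

    def labels_for(self, compartment: str) -> tuple[int, ...]:
        if compartment in COMPOSITES:
            return tuple(self.label_map[name] for name in COMPOSITES[compartment])
        return (self.label_map[compartment],)

    def compartment_mask(self, compartment: str) -> np.ndarray:
        return np.isin(self.mask, self.labels_for(compartment))

    def pixel_area(self, compartment: str) -> float:
        """Pixel-count area of a compartment, in ``unit``^2."""
        return float(self.compartment_mask(compartment).sum()) * self.pixel_size**2

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the full image, pixel edges included."""
        h = self.pixel_size
        ny, nx = self.mask.shape
        x0, y0 = self.origin
        return (x0 - h / 2, x0 + (nx - 0.5) * h, y0 - h / 2, y0 + (ny - 0.5) * h)

    def to_unit(self, unit: str) -> "LabeledSection":
        """Return a copy expressed in another length unit ('mm' or 'um')."""
        factors = {("mm", "um"): 1e3, ("um", "mm"): 1e-3}
        if unit == self.unit:
            return self
        try:
            f = factors[(self.unit, unit)]
        except KeyError:
            raise ValueError(f"cannot convert {self.unit!r} to {unit!r}") from None
        return LabeledSection(
            mask=self.mask,
            pixel_size=self.pixel_size * f,
            z=self.z * f,
            segment=self.segment,
            label_map=self.label_map,
            origin=(self.origin[0] * f, self.origin[1] * f),
            unit=unit,
        )


class GroundTruth:
    """Closed-form areas and volumes of every phantom compartment."""

    def __init__(self, phantom: "Phantom"):
        self._p = phantom

    def area(self, compartment: str, z: float) -> float:
        """True cross-sectional area (mm^2) of ``compartment`` at height ``z``."""
        seg, frac = self._p.locate(z)
        return self._segment_area(seg, compartment, frac)

    @staticmethod
    def _segment_area(seg: SegmentGeom, compartment: str, frac: float) -> float:
        dh = sum(e.area for e in seg.dh)
        vh = sum(e.area for e in seg.vh)
        isth = seg.isthmus.area
        cc = seg.cc.area
        a, b = seg.gs_semiaxes(frac)
        gs = math.pi * a * b
        if compartment == "GS":
            return gs
        if compartment == "DH":
            return dh
        if compartment == "VH":
            return vh
        if compartment == "GM_ISTHMUS":
            return isth - cc
        if compartment == "CC":
            return cc
        if compartment == "GM":
            return dh + vh + isth - cc
        if compartment == "WM":
            return gs - dh - vh - isth
        raise KeyError(compartment)

    def volume(self, compartment: str, segment: str | int) -> float:
        """True volume (mm^3) of ``compartment`` within one segment.

        The GS integral of pi*a(z)*b(z) over a linear taper is closed form;
        constant compartments are area x length.
        """
        seg = self._p.segment(segment)
        L = seg.length
        a0, b0 = seg.gs_start
        da = seg.gs_end[0] - a0
        db = seg.gs_end[1] - b0
        gs_vol = math.pi * L * (a0 * b0 + (a0 * db + b0 * da) / 2.0 + da * db / 3.0)
        if compartment == "GS":
            return gs_vol
        if compartment == "WM":
            dh = sum(e.area for e in seg.dh)
            vh = sum(e.area for e in seg.vh)
            return gs_vol - (dh + vh + seg.isthmus.area) * L
        return self._segment_area(seg, compartment, 0.0) * L

    def quadrature_volume(
        self, compartment: str, segment: str | int, n: int = 10_000
    ) -> float:
        """Volume by fine-step trapezoidal quadrature of the area profile."""
        seg = self._p.segment(segment)
        fracs = np.linspace(0.0, 1.0, n + 1)
        areas = [self._segment_area(seg, compartment, f) for f in fracs]
        return float(np.trapezoid(areas, fracs) * seg.length)


class Phantom:
    """A buildable/sectionable multi-segment organ with exact ground truth."""

    def __init__(self, spec: PhantomSpec):
        for seg in spec.segments:
            seg.validate()
        names = [s.name for s in spec.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        self.spec = spec
        lengths = np.array([s.length for s in spec.segments])
        self.starts = np.concatenate([[0.0], np.cumsum(lengths)])
        self.total_length = float(self.starts[-1])
        self.truth = GroundTruth(self)

    @property
    def segments(self) -> tuple[SegmentGeom, ...]:
        return self.spec.segments

    def segment(self, key: str | int) -> SegmentGeom:
        if isinstance(key, int):
            return self.spec.segments[key]
        for seg in self.spec.segments:
            if seg.name == key:
                return seg
        raise KeyError(key)

    def locate(self, z: float) -> tuple[SegmentGeom, float]:
        """Segment containing ``z`` and the fractional position within it.

        A boundary position belongs to the caudal (later) segment.
        """
        if not (0.0 <= z < self.total_length):
            raise ValueError(
                f"z={z} outside [0, {self.total_length}) mm"
            )
        idx = int(np.searchsorted(self.starts, z, side="right")) - 1
        seg = self.spec.segments[idx]
        return seg, (z - self.starts[idx]) / seg.length

    def segment_span(self, key: str | int) -> tuple[float, float]:
        seg = self.segment(key)
        idx = self.spec.segments.index(seg)
        return float(self.starts[idx]), float(self.starts[idx + 1])

    def section_at(
        self,
        z: float,
        pixel_size: float | None = None,
        bbox: tuple[float, float, float, float] | None = None,
    ) -> LabeledSection:
        """Rasterize the cross-section at height ``z``.

        Each pixel carries the label of the innermost compartment containing
        its centre.  ``bbox=(xmin, xmax, ymin, ymax)`` restricts the render
        to a region of interest (used for the micrometre-scale CC imagery).
        """
        h = pixel_size if pixel_size is not None else self.spec.pixel_size
        if h <= 0:
            raise ValueError("pixel_size must be > 0")
        seg, frac = self.locate(z)
        a, b = seg.gs_semiaxes(frac)
        if bbox is None:
            pad = 2 * h
            bbox = (-a - pad, a + pad, -b - pad, b + pad)
        xmin, xmax, ymin, ymax = bbox
        xs = np.arange(xmin + h / 2, xmax, h)
        ys = np.arange(ymin + h / 2, ymax, h)
        xx, yy = np.meshgrid(xs, ys)
        lm = self.spec.label_map
        mask = np.zeros(xx.shape, dtype=np.int16)
        gs = Ellipse(0.0, 0.0, a, b)
        mask[gs.contains(xx, yy)] = lm["WM"]
        inside = mask > 0
        mask[inside & seg.isthmus.contains(xx, yy)] = lm["GM_ISTHMUS"]
        for e in seg.dh:
            mask[inside & e.contains(xx, yy)] = lm["DH"]
        for e in seg.vh:
            mask[inside & e.contains(xx, yy)] = lm["VH"]
        mask[inside & seg.cc.contains(xx, yy)] = lm["CC"]
        return LabeledSection(
            mask=mask,
            pixel_size=h,
            z=z,
            segment=seg.name,
            label_map=lm,
            origin=(float(xs[0]), float(ys[0])),
        )


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Validate a spec and return the sectionable phantom."""
    return Phantom(spec)


def apply_shrinkage(
    phantom: Phantom, factors: Sequence[float]
) -> Phantom:
    """Shrink a phantom anisotropically.

    ``factors`` are the fractional linear reductions (transverse, vertical,
    longitudinal), each in [0, 1); semi-axes and lengths are scaled by
    (1 - factor), so volumes scale by the product of the three survivals.
    """
    ft, fv, fl = factors
    for f in (ft, fv, fl):
        if not (0.0 <= f < 1.0):
            raise ValueError("shrinkage factors must lie in [0, 1)")
    segs = tuple(s.scaled(1.0 - ft, 1.0 - fv, 1.0 - fl) for s in phantom.spec.segments)
    return Phantom(replace(phantom.spec, segments=segs))


def _make_segment(
    name: str,
    length: float,
    gs_start: tuple[float, float],
    gs_end: tuple[float, float],
    dh_semi: tuple[float, float],
    vh_semi: tuple[float, float],
    cc_semi: tuple[float, float],
    isthmus_half: tuple[float, float] = (0.6, 0.3),
) -> SegmentGeom:
    """Assemble a symmetric butterfly segment from semi-axis tables.

    Horn lobes are placed flush against the isthmus slab in x (so the union
    area is an exact sum) and stacked clear of each other in y.
    """
    iw, ih = isthmus_half
    da, db = dh_semi
    va, vb = vh_semi
    dh_cy = ih + 0.15 + db
    vh_cy = -(ih + 0.15 + vb)
    dh = (Ellipse(-(iw + da), dh_cy, da, db), Ellipse(iw + da, dh_cy, da, db))
    vh = (Ellipse(-(iw + va), vh_cy, va, vb), Ellipse(iw + va, vh_cy, va, vb))
    return SegmentGeom(
        name=name,
        length=length,
        gs_start=gs_start,
        gs_end=gs_end,
        dh=dh,
        vh=vh,
        isthmus=Rect(0.0, 0.0, iw, ih),
        cc=Ellipse(0.0, 0.0, *cc_semi),
    )


# Default 8-segment cervical-cord-like phantom (pre-shrinkage geometry, mm).
# Segment lengths rise from C1 to a C3 maximum and fall to C8; gross-section
# semi-axes dip around C3/C4 and widen towards the cervical enlargement at
# C7/C8; ventral horns outgrow dorsal horns caudally; the central canal is a
# dorsoventrally flattened ellipse a few hundred micrometres across whose
# vertical diameter declines towards C7.
_DEFAULT_ROWS = [
    # name, length, a_node pairs handled below, dh (a,b), vh (a,b), cc (a,b)
    ("C1", 40.0, (0.95, 2.55), (1.10, 1.13), (0.185, 0.142)),
    ("C2", 75.0, (0.95, 1.55), (1.10, 0.93), (0.190, 0.136)),
    ("C3", 110.0, (0.95, 1.22), (1.10, 0.79), (0.195, 0.135)),
    ("C4", 100.0, (0.95, 1.20), (1.10, 0.79), (0.190, 0.125)),
    ("C5", 90.0, (0.95, 1.29), (1.10, 0.95), (0.190, 0.119)),
    ("C6", 80.0, (0.95, 1.55), (1.10, 1.25), (0.195, 0.111)),
    ("C7", 65.0, (0.95, 2.23), (1.10, 2.55), (0.185, 0.092)),
    ("C8", 45.0, (0.95, 2.70), (1.10, 3.32), (0.180, 0.092)),
]
_GS_A_NODES = [8.6, 8.4, 8.1, 8.0, 8.2, 8.6, 9.1, 9.6, 9.9]
_GS_B_NODES = [6.9, 6.75, 6.5, 6.45, 6.6, 6.85, 7.3, 7.75, 7.9]


def default_spec(pixel_size: float = 0.02, seed: int = 0) -> PhantomSpec:
    """Eight-segment cervical-cord-like phantom with table-scale compartments."""
    segs = []
    for i, (name, length, dh, vh, cc) in enumerate(_DEFAULT_ROWS):
        segs.append(
            _make_segment(
                name,
                length,
                gs_start=(_GS_A_NODES[i], _GS_B_NODES[i]),
                gs_end=(_GS_A_NODES[i + 1], _GS_B_NODES[i + 1]),
                dh_semi=dh,
                vh_semi=vh,
                cc_semi=cc,
            )
        )
    return PhantomSpec(segments=tuple(segs), pixel_size=pixel_size, seed=seed)
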