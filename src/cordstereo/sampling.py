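"""Systematic-uniform-random slab and section sampling.

A segment of length L is cut into slabs of constant thickness with a single
uniformly random first-cut position, then every k-th slab is kept for a
sampling fraction 1/k (with a random phase), which preserves the
unbiasedness of systematic sampling.  One measurement section is taken near
the cranial face of each kept slab, at a random offset within the first 30
consecutive 10-um microtome sections.

The distance between consecutive kept sections *after* histological
processing, ``t_effective``, is a measured input: the shrunken tissue is
sectioned, so the spacing entering the Cavalieri formula is the
post-processing one (3.4 mm per slab at full sampling by default), not a
value derived from any shrinkage model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = ["SamplingDesign", "Slab", "SlabPlan", "plan_slabs", "section_positions"]

#: thickness of one microtome section (mm); the measurement section is drawn
#: from the first 30 of these within each kept slab
MICROTOME_SECTION = 0.010
SECTIONS_PER_DRAW = 30

ALLOWED_FRACTIONS = (Fraction(1), Fraction(1, 2), Fraction(1, 3))


@dataclass(frozen=True)
class SamplingDesign:
    """Slab-cutting and subsampling parameters for one segment.

    Parameters
    ----------
    slab_thickness : mm between consecutive cuts before processing (default 3.8).
    fraction : kept-slab fraction, one of 1, 1/2, 1/3.
    phase : index of the first kept slab within each group of k; ``None``
        means draw it uniformly from {0..k-1}.
    t_effective : post-processing spacing (mm) between consecutive kept
        sections, the ``t`` of the Cavalieri volume formula.  ``None``
        selects the default 3.4 mm x k (3.4 / 6.8 / 10.2 for 1, 1/2, 1/3).
    """

    slab_thickness: float = 3.8
    fraction: Fraction = Fraction(1)
    phase: int | None = None
    t_effective: float | None = None

    def __post_init__(self):
        frac = Fraction(self.fraction)
        object.__setattr__(self, "fraction", frac)
        if frac not in ALLOWED_FRACTIONS:
            raise ValueError(f"fraction must be one of {ALLOWED_FRACTIONS}")
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be > 0")
        if self.phase is not None and not (0 <= self.phase < frac.denominator):
            raise ValueError("phase must lie in {0..k-1}")
        if self.t_effective is None:
            object.__setattr__(self, "t_effective", 3.4 * frac.denominator)
        if self.t_effective <= 0:
            raise ValueError("t_effective must be > 0")

    @property
    def period(self) -> int:
        """k: every k-th slab is kept."""
        return self.fraction.denominator

    @property
    def spacing_pre(self) -> float:
        """Spacing between kept-slab faces before processing (mm)."""
        return self.slab_thickness * self.period


@dataclass(frozen=True)
class Slab:
    index: int
    z_start: float
    z_end: float
    kept: bool

    @property
    def thickness(self) -> float:
        return self.z_end - self.z_start


@dataclass(frozen=True)
class SlabPlan:
    segment_length: float
    design: SamplingDesign
    random_start: float
    phase: int
    slabs: tuple[Slab, ...]

    @property
    def kept(self) -> tuple[Slab, ...]:
        return tuple(s for s in self.slabs if s.kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slab_index": s.index,
                    "z_start": s.z_start,
                    "z_end": s.z_end,
                    "kept": s.kept,
                }
                for s in self.slabs
            ]
        )


def plan_slabs(
    segment_length: float, design: SamplingDesign, rng: np.random.Generator
) -> SlabPlan:
    """Cut a segment into slabs with a uniform random first cut and subsample.

    The first cut falls at ``u ~ U[0, slab_thickness)``; when u > 0 the
    leading partial slab [0, u) is kept in the plan as slab 0 (dropping it
    would bias the systematic sample).  For fraction 1/k every k-th slab is
    kept starting at a (possibly random) phase.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    T = design.slab_thickness
    u = float(rng.uniform(0.0, T))
    edges = [0.0] if u == 0.0 else [0.0, u]
    z = u
    while z < segment_length - 1e-12:
        z = min(z + T, segment_length)
        edges.append(z)
    if edges[-1] < segment_length:
        edges.append(segment_length)
    k = design.period
    phase = design.phase if design.phase is not None else int(rng.integers(k))
    slabs = tuple(
        Slab(i, edges[i], edges[i + 1], kept=(i % k == phase % k))
        for i in range(len(edges) - 1)
    )
    return SlabPlan(segment_length, design, u, phase % k, slabs)


def section_positions(
    plan: SlabPlan, rng: np.random.Generator | None = None
) -> list[float]:
    """Measurement positions z over the kept slabs (mm, pre-processing).

    Each kept slab is sectioned at its cranial face plus a random choice
    among the first 30 microtome sections (10 um each); the draw is shared
    by all slabs of the segment so consecutive kept positions keep the
    constant spacing the Cavalieri spacing ``t`` requires.  The leading
    partial slab (when the first cut fell at u > 0) is the clipped tail of
    a notional slab whose cranial face lies at u - slab_thickness: the
    whole series is then one uniform lattice, and the partial slab yields
    a section only when the offset lands inside its remaining material.
    A trailing partial slab likewise yields no section when it is thinner
    than the offset.  Dropping only happens at the ends, so the surviving
    positions stay equidistant and the section series remains a systematic
    uniform random sample of [0, L).
    """
    kept = plan.kept
    if not kept:
        raise ValueError("plan has no kept slabs")
    T = plan.design.slab_thickness
    offset = 0.0
    if rng is not None:
        offset = (float(rng.integers(SECTIONS_PER_DRAW)) + 0.5) * MICROTOME_SECTION
    out = []
    for s in kept:
        face = s.z_start if s.index > 0 or plan.random_start == 0.0 else plan.random_start - T
        z = face + offset
        if 0.0 <= z < s.z_end:
            out.append(z)
    if not out:
        raise ValueError("no section position falls inside the segment")
    return out
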