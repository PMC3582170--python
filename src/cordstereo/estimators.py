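"""Point-count area, Cavalieri volume, and coefficient-of-error estimators.

Given the per-section mean tallies sigma_p of a compartment in one segment:

* mean area       A_mean = (sum_i sigma_p_i) * a/p / Sn          (Sn sections)
* Cavalieri vol.  V_est  = (sum_i sigma_p_i) * a/p * t           (spacing t)

with ``t`` the post-processing distance between consecutive sections.  The
predicted precision of V_est under systematic uniform random sampling is
the Gundersen-Jensen coefficient of error computed from the ordered section
tallies P_i:

    A = sum P_i^2,  B = sum P_i P_{i+1},  C = sum P_i P_{i+2}
    noise  = 0.0724 * shape * sqrt(n * sum P_i)       (shape ~ b/sqrt(a))
    VarSRS = (3 (A - noise) - 4 B + C) / 240          (clipped at 0)
    CE     = sqrt(noise + VarSRS) / sum P_i

The shape coefficient defaults to 6, an oblong-profile value; both it and
the 1/240 smoothness constant are exposed because published CE variants
differ in them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pointcount import CountRecord

__all__ = [
    "AreaEstimate",
    "VolumeEstimate",
    "WMConsistency",
    "area_mean",
    "volume_cavalieri",
    "ce_systematic",
    "wm_consistency",
]


@dataclass(frozen=True)
class AreaEstimate:
    compartment: str
    a_mean: float
    sn: int
    per_section: tuple[float, ...]
    a_per_p: float


@dataclass(frozen=True)
class VolumeEstimate:
    compartment: str
    v_est: float
    t: float
    sn: int
    ce: float | None = None


@dataclass(frozen=True)
class WMConsistency:
    """Direct vs subtraction-defined white-matter area for one segment."""

    wm_direct: float
    wm_subtracted: float

    @property
    def gap(self) -> float:
        return self.wm_direct - self.wm_subtracted

    @property
    def relative_gap(self) -> float:
        ref = max(abs(self.wm_direct), abs(self.wm_subtracted))
        return 0.0 if ref == 0 else abs(self.gap) / ref


def _sigmas(records: Sequence[CountRecord | float]) -> np.ndarray:
    vals = [r.sigma_p if isinstance(r, CountRecord) else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def _check_homogeneous(records: Sequence[CountRecord | float], a_per_p: float) -> None:
    comps = {r.compartment for r in records if isinstance(r, CountRecord)}
    if len(comps) > 1:
        raise ValueError(f"records mix compartments: {sorted(comps)}")
    for r in records:
        if isinstance(r, CountRecord) and not np.isclose(r.a_per_p, a_per_p):
            raise ValueError("records carry a different a/p than requested")


def area_mean(
    records: Sequence[CountRecord | float], a_per_p: float, sn: int | None = None
) -> AreaEstimate:
    """Mean cross-sectional area of a segment compartment.

    ``records`` are per-section tallies (CountRecord or bare sigma_p values),
    all sharing one a/p.  Sn defaults to the record count.
    """
    if len(records) == 0:
        raise ValueError("no count records")
    _check_homogeneous(records, a_per_p)
    sig = _sigmas(records)
    n = len(sig) if sn is None else sn
    if n < 1:
        raise ValueError("Sn must be >= 1")
    comp = next(
        (r.compartment for r in records if isinstance(r, CountRecord)), "?"
    )
    return AreaEstimate(
        compartment=comp,
        a_mean=float(sig.sum()) * a_per_p / n,
        sn=n,
        per_section=tuple(sig * a_per_p),
        a_per_p=a_per_p,
    )


def volume_cavalieri(
    records: Sequence[CountRecord | float],
    a_per_p: float,
    t: float,
    positions: Sequence[float] | None = None,
    shape_coefficient: float = 6.0,
) -> VolumeEstimate:
    """Cavalieri volume of a segment compartment from ordered section tallies.

    ``t`` is the constant post-processing spacing between consecutive
    sections.  When section ``positions`` are supplied their spacing must be
    constant to within 1% of t (the estimator assumes equidistant planes);
    positions may be pre-processing coordinates, so only their uniformity is
    checked, not their absolute scale.
    """
    if len(records) == 0:
        raise ValueError("no count records")
    if t <= 0:
        raise ValueError("t must be > 0")
    _check_homogeneous(records, a_per_p)
    if positions is not None and len(positions) >= 2:
        d = np.diff(np.asarray(positions, dtype=float))
        if np.any(np.abs(d - d.mean()) > 0.01 * t):
            raise ValueError(
                "section spacing is nonuniform beyond 1% of t; the Cavalieri "
                "sum assumes equidistant sections"
            )
    sig = _sigmas(records)
    comp = next(
        (r.compartment for r in records if isinstance(r, CountRecord)), "?"
    )
    ce = ce_systematic(sig, shape_coefficient) if len(sig) >= 3 else None
    return VolumeEstimate(
        compartment=comp,
        v_est=float(sig.sum()) * a_per_p * t,
        t=t,
        sn=len(sig),
        ce=ce,
    )


def ce_systematic(
    per_section_counts: Sequence[float],
    shape_coefficient: float = 6.0,
    noise_constant: float = 0.0724,
    smoothness_divisor: float = 240.0,
) -> float:
    """Gundersen-Jensen coefficient of error of a systematic section series."""
    p = np.asarray(per_section_counts, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("CE needs at least 3 sections")
    total = float(p.sum())
    if total <= 0:
        raise ValueError("CE undefined for an all-zero series")
    A = float(np.dot(p, p))
    B = float(np.dot(p[:-1], p[1:]))
    C = float(np.dot(p[:-2], p[2:]))
    noise = noise_constant * shape_coefficient * np.sqrt(n * total)
    var_srs = (3.0 * (A - noise) - 4.0 * B + C) / smoothness_divisor
    var_srs = max(var_srs, 0.0)
    return float(np.sqrt(noise + var_srs) / total)


def wm_consistency(
    gs: AreaEstimate,
    gm: AreaEstimate,
    cc: AreaEstimate | float,
    wm_direct: AreaEstimate,
) -> WMConsistency:
    """Compare directly counted WM area with GS - GM - CC.

    ``cc`` may be a bare area (already in the same unit as GS, i.e. mm^2) to
    make the 10^-3 mm^2 bookkeeping of the canal explicit at the call site.
    """
    cc_area = cc.a_mean if isinstance(cc, AreaEstimate) else float(cc)
    return WMConsistency(
        wm_direct=wm_direct.a_mean,
        wm_subtracted=gs.a_mean - gm.a_mean - cc_area,
    )
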