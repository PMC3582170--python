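"""Reading and writing section stacks, manifests, and phantom configs.

Label masks are written as 16-bit PNG (one file per section) or as a single
multi-page TIFF, always alongside a CSV manifest carrying the physical
metadata (animal, segment, z position, pixel size, unit, kind).  Images
store rows top-to-bottom with dorsal at the top; in-memory sections use
row index increasing towards dorsal, so masks are flipped on write/read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .phantom import (
    DEFAULT_LABELS,
    Ellipse,
    LabeledSection,
    PhantomSpec,
    Rect,
    SegmentGeom,
)

__all__ = [
    "write_mask",
    "read_mask",
    "write_section_stack",
    "write_stack_tiff",
    "read_stack_tiff",
    "read_section_stack",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
]

MANIFEST_COLUMNS = [
    "filename",
    "animal",
    "segment",
    "z_mm",
    "pixel_size_mm",
    "unit",
    "kind",
    "origin_x",
    "origin_y",
    "t_mm",
]


def write_mask(section: LabeledSection, path: Path) -> None:
    """Write one label mask as 16-bit PNG (dorsal-up on screen)."""
    img = np.flipud(section.mask).astype(np.uint16)
    Image.fromarray(img).save(path)


def read_mask(path: Path) -> np.ndarray:
    """Read a label mask back into the internal (+y up) row convention."""
    arr = np.asarray(Image.open(path), dtype=np.int16)
    return np.flipud(arr).copy()


def write_section_stack(
    sections: Iterable[tuple[LabeledSection, dict]],
    outdir: Path,
    manifest_name: str = "manifest.csv",
) -> pd.DataFrame:
    """Write sections plus a manifest; the per-section dict supplies the
    manifest metadata (animal, kind, t_mm, filename stem)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for section, meta in sections:
        fname = meta["stem"] + ".png"
        write_mask(section, outdir / fname)
        rows.append(
            {
                "filename": fname,
                "animal": meta.get("animal", "A1"),
                "segment": section.segment,
                "z_mm": round(section.z, 6),
                "pixel_size_mm": section.pixel_size
                if section.unit == "mm"
                else section.pixel_size * 1e-3,
                "unit": section.unit,
                "kind": meta.get("kind", "section"),
                "origin_x": round(section.origin[0], 9),
                "origin_y": round(section.origin[1], 9),
                "t_mm": meta.get("t_mm", np.nan),
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / manifest_name, index=False)
    return manifest


def read_section_stack(
    indir: Path, manifest_name: str = "manifest.csv"
) -> list[tuple[LabeledSection, pd.Series]]:
    """Load a stack written by :func:`write_section_stack`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / manifest_name)
    out = []
    for _, row in manifest.iterrows():
        mask = read_mask(indir / row["filename"])
        unit = row["unit"]
        px = row["pixel_size_mm"] if unit == "mm" else row["pixel_size_mm"] * 1e3
        section = LabeledSection(
            mask=mask,
            pixel_size=float(px),
            z=float(row["z_mm"]) if unit == "mm" else float(row["z_mm"]) * 1e3,
            segment=str(row["segment"]),
            label_map=dict(DEFAULT_LABELS),
            origin=(float(row["origin_x"]), float(row["origin_y"])),
            unit=unit,
        )
        out.append((section, row))
    return out


def write_stack_tiff(sections: Iterable[LabeledSection], path: Path) -> None:
    """Write same-shape sections as one multi-page TIFF (dorsal-up pages)."""
    import tifffile

    pages = np.stack([np.flipud(s.mask).astype(np.uint16) for s in sections])
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_stack_tiff(path: Path) -> list[np.ndarray]:
    """Read a multi-page TIFF back into internal-convention masks."""
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return [np.flipud(p).astype(np.int16) for p in pages]


def _ellipse_to_list(e: Ellipse) -> list[float]:
    return [e.cx, e.cy, e.a, e.b]


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain key-value form of a phantom spec (YAML/JSON serializable)."""
    return {
        "pixel_size": spec.pixel_size,
        "seed": spec.seed,
        "label_map": dict(spec.label_map),
        "segments": [
            {
                "name": s.name,
                "length": s.length,
                "gs_start": list(s.gs_start),
                "gs_end": list(s.gs_end),
                "dh": [_ellipse_to_list(e) for e in s.dh],
                "vh": [_ellipse_to_list(e) for e in s.vh],
                "isthmus": [s.isthmus.cx, s.isthmus.cy, s.isthmus.half_w, s.isthmus.half_h],
                "cc": _ellipse_to_list(s.cc),
            }
            for s in spec.segments
        ],
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    segs = tuple(
        SegmentGeom(
            name=s["name"],
            length=float(s["length"]),
            gs_start=tuple(s["gs_start"]),
            gs_end=tuple(s["gs_end"]),
            dh=tuple(Ellipse(*e) for e in s["dh"]),
            vh=tuple(Ellipse(*e) for e in s["vh"]),
            isthmus=Rect(*s["isthmus"]),
            cc=Ellipse(*s["cc"]),
        )
        for s in d["segments"]
    )
    return PhantomSpec(
        segments=segs,
        pixel_size=float(d.get("pixel_size", 0.02)),
        label_map=d.get("label_map"),
        seed=int(d.get("seed", 0)),
    )


def save_spec(spec: PhantomSpec, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def load_spec(path: Path) -> PhantomSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))
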