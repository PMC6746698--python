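"""Data model and I/O for patch-level tissue prediction maps.

A prediction map is the argmax output of a patch classifier run over a
whole-slide image: one categorical label per non-overlapping patch (by
default 128x128 pixels at 20x magnification).  The lattice uses raster
conventions — row-major, 0-based, origin at the slide's top-left; patch
(r, c) covers the half-open pixel interval [r*P, (r+1)*P) x [c*P, (c+1)*P).

Two on-disk dialects are supported:

* ``label_table`` — UTF-8 CSV with header ``row,col,label``; 0-based integer
  coordinates and integer codes 0-4; coordinates absent from the table are
  BACKGROUND.
* ``indexed_image`` — single-channel 8-bit raster, one pixel per patch,
  same code table.

Physical metadata (``slide_id``, ``patch_size_px``, ``microns_per_pixel``)
travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from tilab.errors import FormatError, ValidationError

__all__ = [
    "TissueClass",
    "PredictionMap",
    "SectionLabels",
    "MapDiagnostics",
    "load_prediction_map",
    "save_prediction_map",
    "label_sections",
    "validate_map",
]


class TissueClass(IntEnum):
    """Fixed label code table for the five patch classes."""

    BACKGROUND = 0
    TUMOUR = 1
    LYMPHOCYTE = 2
    STROMA = 3
    NONROI = 4


_VALID_CODES = frozenset(int(c) for c in TissueClass)


@dataclass(frozen=True)
class PredictionMap:
    """A validated lattice of patch class labels with physical-scale metadata.

    Parameters
    ----------
    labels
        2D integer array of :class:`TissueClass` codes, shape (rows, cols).
    patch_size_px
        Side length of one patch in pixels at analysis magnification.
    microns_per_pixel
        Physical pixel size in micrometres at analysis magnification.
    slide_id
        Identifier of the originating slide.
    """

    labels: np.ndarray
    patch_size_px: int
    microns_per_pixel: float
    slide_id: str = "unnamed"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.shape[0] < 1 or labels.shape[1] < 1:
            raise ValidationError(
                f"labels must be a 2D lattice of size >= 1x1, got shape {labels.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("label lattice must be integer-typed")
        bad = ~np.isin(labels, list(_VALID_CODES))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"unknown label code {int(labels[r, c])} at row {int(r)}, col {int(c)}"
            )
        labels = np.ascontiguousarray(labels, dtype=np.uint8)
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        if int(self.patch_size_px) <= 0:
            raise ValidationError(f"patch_size_px must be positive, got {self.patch_size_px}")
        if not (float(self.microns_per_pixel) > 0):
            raise ValidationError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )
        object.__setattr__(self, "patch_size_px", int(self.patch_size_px))
        object.__setattr__(self, "microns_per_pixel", float(self.microns_per_pixel))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def patch_side_mm(self) -> float:
        """Physical side length of one patch in millimetres."""
        return self.patch_size_px * self.microns_per_pixel / 1000.0

    def class_counts(self) -> dict[TissueClass, int]:
        counts = np.bincount(self.labels.ravel(), minlength=5)
        return {cls: int(counts[cls.value]) for cls in TissueClass}


@dataclass(frozen=True)
class SectionLabels:
    """Connected tissue sections of a prediction map.

    ``section_id`` aligns with ``PredictionMap.labels``; 0 marks background,
    k >= 1 the k-th section in row-major order of first occurrence.
    """

    section_id: np.ndarray
    n_sections: int

    def __post_init__(self) -> None:
        sid = np.ascontiguousarray(np.asarray(self.section_id), dtype=np.int32)
        sid.setflags(write=False)
        object.__setattr__(self, "section_id", sid)
        present = np.unique(sid)
        nonbg = present[present != 0]
        if (sid < 0).any() or not np.array_equal(nonbg, np.arange(1, self.n_sections + 1)):
            raise ValidationError("section ids must be contiguous 1..n_sections (0 = background)")


@dataclass(frozen=True)
class MapDiagnostics:
    """Result of :func:`validate_map`: per-class counts and sanity warnings."""

    class_counts: dict[TissueClass, int]
    n_patches: int
    tissue_fraction: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _read_sidecar(meta: dict | str | Path) -> dict:
    if isinstance(meta, (str, Path)):
        with open(meta, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    required = {"slide_id", "patch_size_px", "microns_per_pixel"}
    missing = required - set(meta)
    if missing:
        raise FormatError(f"metadata missing keys: {sorted(missing)}")
    return meta


def load_prediction_map(
    path: str | Path,
    format: Literal["label_table", "indexed_image"] = "label_table",
    *,
    meta: dict | str | Path,
) -> PredictionMap:
    """Load a prediction map from disk.

    ``meta`` is either the sidecar JSON path or an already-parsed dict with
    keys ``slide_id``, ``patch_size_px``, ``microns_per_pixel``.  Unknown
    label codes are rejected with the offending cell named, never coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(meta)

    if format == "label_table":
        table = pd.read_csv(path)
        expected_cols = ["row", "col", "label"]
        if list(table.columns) != expected_cols:
            raise FormatError(
                f"label_table header must be {expected_cols}, got {list(table.columns)}"
            )
        if len(table) == 0:
            raise FormatError("label_table contains no entries")
        rows = table["row"].to_numpy()
        cols = table["col"].to_numpy()
        codes = table["label"].to_numpy()
        if (rows < 0).any() or (cols < 0).any():
            raise FormatError("negative patch coordinates in label_table")
        bad = ~np.isin(codes, list(_VALID_CODES))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"unknown label code {int(codes[i])} at row {int(rows[i])}, col {int(cols[i])}"
            )
        if table.duplicated(subset=["row", "col"]).any():
            raise FormatError("duplicate (row, col) entries in label_table")
        labels = np.zeros((int(rows.max()) + 1, int(cols.max()) + 1), dtype=np.uint8)
        labels[rows, cols] = codes
    elif format == "indexed_image":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("P") if img.mode == "P" else img)
        if arr.ndim != 2:
            raise FormatError("indexed_image must be single-channel")
        labels = arr.astype(np.uint8)
        bad = ~np.isin(labels, list(_VALID_CODES))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"unknown label code {int(labels[r, c])} at row {int(r)}, col {int(c)}"
            )
    else:
        raise ValidationError(f"unknown format {format!r}")

    return PredictionMap(
        labels=labels,
        patch_size_px=meta["patch_size_px"],
        microns_per_pixel=meta["microns_per_pixel"],
        slide_id=str(meta["slide_id"]),
    )


def save_prediction_map(
    pmap: PredictionMap,
    path: str | Path,
    format: Literal["label_table", "indexed_image"] = "label_table",
    *,
    meta_path: str | Path | None = None,
) -> None:
    """Write a prediction map in the named dialect (plus optional JSON sidecar).

    The label_table dialect lists every patch, including BACKGROUND, so the
    lattice shape round-trips exactly.
    """
    path = Path(path)
    if format == "label_table":
        rows, cols = np.indices(pmap.shape)
        pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "label": pmap.labels.ravel().astype(int),
            }
        ).to_csv(path, index=False)
    elif format == "indexed_image":
        Image.fromarray(pmap.labels, mode="L").save(path)
    else:
        raise ValidationError(f"unknown format {format!r}")

    if meta_path is not None:
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "slide_id": pmap.slide_id,
                    "patch_size_px": pmap.patch_size_px,
                    "microns_per_pixel": pmap.microns_per_pixel,
                },
                fh,
                sort_keys=True,
                indent=1,
            )


def label_sections(pmap: PredictionMap, connectivity: int = 8) -> SectionLabels:
    """Delineate tissue sections as connected components of non-background patches.

    Sections are numbered 1..n in row-major order of first occurrence.  The
    default 8-connectivity treats fragments touching at corners as one
    physical section; non-ROI (artefact) patches count as tissue.
    """
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    tissue = pmap.labels != TissueClass.BACKGROUND
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    raw, n = ndimage.label(tissue, structure=structure)
    if n == 0:
        return SectionLabels(section_id=np.zeros(pmap.shape, dtype=np.int32), n_sections=0)
    # renumber by first occurrence in row-major scan order
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    return SectionLabels(section_id=remap[raw], n_sections=int(n))


def validate_map(pmap: PredictionMap) -> MapDiagnostics:
    """Summarise a map's composition and emit sanity warnings.

    A warning is raised in the report (never an exception) when the map holds
    no tumour and no lymphocyte patches: the TILAb score of such a map is a
    degenerate case, not a measurement of infiltration.
    """
    counts = pmap.class_counts()
    n = pmap.labels.size
    tissue = n - counts[TissueClass.BACKGROUND]
    warnings: list[str] = []
    if counts[TissueClass.TUMOUR] + counts[TissueClass.LYMPHOCYTE] == 0:
        warnings.append("map contains no tumour and no lymphocyte patches")
    if tissue == 0:
        warnings.append("map is entirely background")
    return MapDiagnostics(
        class_counts=counts,
        n_patches=n,
        tissue_fraction=tissue / n,
        warnings=tuple(warnings),
    )
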