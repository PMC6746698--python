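"""Grid construction and tumour-lymphocyte co-localization scoring.

A prediction map is tiled into square grid-cells of a chosen physical side
length (the canonical preset spans 0.28 mm to 1.26 mm in 0.14 mm steps).  For
cell (i, j) the lymphocyte and tumour areal fractions

    p_ij^l = (# lymphocyte patches in cell) / (# patch positions in cell)
    p_ij^t = (# tumour patches in cell)     / (# patch positions in cell)

feed three scores:

* Morisita-Horn co-localization
      M = 2 * sum(p^l * p^t) / (sum((p^l)^2) + sum((p^t)^2)),  0 <= M <= 1,
  1 when every cell holds equal tumour and lymphocyte fractions, 0 when every
  cell is single-class (fully segregated).

* Shannon diversity
      S = -sum(p^l ln p^l + p^t ln p^t) / (m*n),   0 ln 0 := 0,
  which peaks at ln 2 (printed 0.7) along the constraint p^l + p^t = 1.

* TILAb score
      T = (C/2) * sum(p^l) / sum(p^t)   if sum(p^t) > 0,   else  T = 1,
  with C either of the two co-localization measures.  The factor 1/2
  normalizes the uniform-composition sweep to [0, 1]; on non-uniform grids
  T can exceed 1, so a cap-at-one clip policy is the default and the pre-clip
  value is always retained.

Both M and T (with C = M) are invariant under a uniform density rescaling
(p^l, p^t) -> (a*p^l, a*p^t); S is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from tilab.errors import ValidationError
from tilab.predmap import PredictionMap, SectionLabels, TissueClass

__all__ = [
    "CANONICAL_CELL_SIZES_MM",
    "GridComposition",
    "SectionScore",
    "ColocReport",
    "build_grid",
    "morisita_horn",
    "shannon_diversity",
    "tilab_score",
    "score_wsi",
]

#: Eight canonical grid-cell sizes: 0.28 mm smallest, fixed 0.14 mm step.
CANONICAL_CELL_SIZES_MM: tuple[float, ...] = tuple(
    round(0.28 + 0.14 * k, 2) for k in range(8)
)

IndexChoice = Literal["mh", "sd"]
ClipPolicy = Literal["cap_at_one", "none"]


@dataclass(frozen=True)
class GridComposition:
    """Per-cell lymphocyte and tumour fractions on an m x n grid.

    ``valid`` marks cells that contain at least one in-scope patch position;
    cells outside a section mask are invalid and excluded from every sum and
    from the Shannon divisor.  For unmasked grids all cells are valid.
    """

    p_l: np.ndarray
    p_t: np.ndarray
    cell_size_mm: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        p_l = np.ascontiguousarray(np.asarray(self.p_l, dtype=float))
        p_t = np.ascontiguousarray(np.asarray(self.p_t, dtype=float))
        if p_l.ndim != 2 or p_l.shape != p_t.shape or p_l.size == 0:
            raise ValidationError("p_l and p_t must be equal-shaped 2D arrays, >= 1x1")
        if (p_l < 0).any() or (p_t < 0).any() or (p_l + p_t > 1 + 1e-12).any():
            raise ValidationError("cell fractions must satisfy 0 <= p_l, p_t and p_l + p_t <= 1")
        if not (float(self.cell_size_mm) > 0):
            raise ValidationError("cell_size_mm must be positive")
        valid = self.valid
        if valid is None:
            valid = np.ones(p_l.shape, dtype=bool)
        else:
            valid = np.ascontiguousarray(np.asarray(valid, dtype=bool))
            if valid.shape != p_l.shape:
                raise ValidationError("valid mask must match grid shape")
            if not valid.any():
                raise ValidationError("grid has no valid cells")
        for a in (p_l, p_t, valid):
            a.setflags(write=False)
        object.__setattr__(self, "p_l", p_l)
        object.__setattr__(self, "p_t", p_t)
        object.__setattr__(self, "valid", valid)
        object.__setattr__(self, "cell_size_mm", float(self.cell_size_mm))

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_l.shape

    @property
    def n_cells(self) -> int:
        """Number of cells contributing to the scores (valid cells)."""
        return int(self.valid.sum())


def _block_sum(a: np.ndarray, k: int) -> np.ndarray:
    """Sum a 2D array over k x k tiles anchored at the top-left (edges truncated)."""
    rows, cols = a.shape
    ri = np.arange(0, rows, k)
    ci = np.arange(0, cols, k)
    return np.add.reduceat(np.add.reduceat(a, ri, axis=0), ci, axis=1)


def cell_side_in_patches(pmap: PredictionMap, cell_size_mm: float) -> int:
    """Nearest-integer number of patches per grid-cell side for a physical size."""
    side = cell_size_mm / pmap.patch_side_mm
    return int(round(side))


def build_grid(
    pmap: PredictionMap,
    cell_size_mm: float,
    *,
    sections: SectionLabels | None = None,
    section_id: int | None = None,
) -> GridComposition:
    """Tile a prediction map into grid-cells and compute per-cell class fractions.

    The cell side in patches is the nearest integer to the requested physical
    size; the lattice is tiled from the top-left and edge cells are truncated
    but kept.  The per-cell denominator counts all patch positions in the
    cell, whatever their class.  When a section mask is given, patches outside
    the section count neither in numerator nor denominator, the grid is
    restricted to the section's bounding cells, and cells with zero in-section
    patches are marked invalid.
    """
    if cell_size_mm < pmap.patch_side_mm - 1e-12:
        raise ValidationError(
            f"cell_size_mm={cell_size_mm} is smaller than one patch "
            f"({pmap.patch_side_mm:.4f} mm)"
        )
    k = cell_side_in_patches(pmap, cell_size_mm)
    if k < 1:
        raise ValidationError("grid-cell must span at least one patch")

    lymph = (pmap.labels == TissueClass.LYMPHOCYTE).astype(np.float64)
    tum = (pmap.labels == TissueClass.TUMOUR).astype(np.float64)
    if sections is not None and section_id is not None:
        in_scope = sections.section_id == section_id
        if not in_scope.any():
            raise ValidationError(f"section {section_id} is empty or absent")
        lymph *= in_scope
        tum *= in_scope
        denom_src = in_scope.astype(np.float64)
    else:
        denom_src = np.ones(pmap.shape, dtype=np.float64)

    denom = _block_sum(denom_src, k)
    l_cnt = _block_sum(lymph, k)
    t_cnt = _block_sum(tum, k)

    valid = denom > 0
    if sections is not None and section_id is not None:
        # restrict to the bounding box of cells that contain section patches
        rows_any = valid.any(axis=1)
        cols_any = valid.any(axis=0)
        r0, r1 = np.flatnonzero(rows_any)[[0, -1]]
        c0, c1 = np.flatnonzero(cols_any)[[0, -1]]
        sl = (slice(r0, r1 + 1), slice(c0, c1 + 1))
        denom, l_cnt, t_cnt, valid = denom[sl], l_cnt[sl], t_cnt[sl], valid[sl]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_l = np.where(valid, l_cnt / np.where(denom > 0, denom, 1.0), 0.0)
        p_t = np.where(valid, t_cnt / np.where(denom > 0, denom, 1.0), 0.0)
    return GridComposition(p_l=p_l, p_t=p_t, cell_size_mm=cell_size_mm, valid=valid)


def morisita_horn(grid: GridComposition) -> float:
    """Morisita-Horn co-localization of lymphocyte and tumour fractions.

    Returns 0 when the grid holds neither class anywhere (empty denominator).
    """
    pl = grid.p_l[grid.valid]
    pt = grid.p_t[grid.valid]
    denom = float(np.sum(pl * pl) + np.sum(pt * pt))
    if denom == 0.0:
        return 0.0
    return float(2.0 * np.sum(pl * pt) / denom)


def shannon_diversity(grid: GridComposition) -> float:
    """Two-class Shannon diversity averaged over grid-cells (0 ln 0 := 0)."""
    pl = grid.p_l[grid.valid]
    pt = grid.p_t[grid.valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pl > 0, pl * np.log(pl), 0.0) + np.where(
            pt > 0, pt * np.log(pt), 0.0
        )
    return float(-terms.sum() / pl.size)


def tilab_score(
    grid: GridComposition,
    index: IndexChoice = "mh",
    clip: ClipPolicy = "cap_at_one",
) -> float:
    """TILAb score: half the co-localization index times the lymphocyte/tumour ratio.

    A grid with no tumour at all takes the otherwise-branch value 1 —
    maximal infiltration by convention, flagged upstream in reports.
    """
    raw = tilab_score_raw(grid, index)
    return min(raw, 1.0) if clip == "cap_at_one" else raw


def tilab_score_raw(grid: GridComposition, index: IndexChoice = "mh") -> float:
    """TILAb score before any clip policy is applied."""
    if index == "mh":
        c = morisita_horn(grid)
    elif index == "sd":
        c = shannon_diversity(grid)
    else:
        raise ValidationError(f"index must be 'mh' or 'sd', got {index!r}")
    sum_t = float(grid.p_t[grid.valid].sum())
    if sum_t > 0:
        sum_l = float(grid.p_l[grid.valid].sum())
        return (c / 2.0) * (sum_l / sum_t)
    return 1.0


@dataclass(frozen=True)
class SectionScore:
    """Scores of one tissue section."""

    section_id: int
    morisita_horn: float
    shannon: float
    tilab: float
    tilab_preclip: float
    n_cells: int
    no_tumour_or_lymph: bool


@dataclass(frozen=True)
class ColocReport:
    """Per-section and WSI-level co-localization scores with their configuration."""

    slide_id: str
    per_section: tuple[SectionScore, ...]
    wsi_morisita_horn: float
    wsi_shannon: float
    wsi_tilab: float
    wsi_tilab_preclip: float
    cell_size_mm: float
    index: IndexChoice
    clip: ClipPolicy
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "config": {
                "cell_size_mm": self.cell_size_mm,
                "index": self.index,
                "clip": self.clip,
            },
            "wsi": {
                "morisita_horn": self.wsi_morisita_horn,
                "shannon": self.wsi_shannon,
                "tilab": self.wsi_tilab,
                "tilab_preclip": self.wsi_tilab_preclip,
            },
            "per_section": [
                {
                    "section_id": s.section_id,
                    "n_cells": s.n_cells,
                    "morisita_horn": s.morisita_horn,
                    "shannon": s.shannon,
                    "tilab": s.tilab,
                    "tilab_preclip": s.tilab_preclip,
                    "no_tumour_or_lymph": s.no_tumour_or_lymph,
                }
                for s in self.per_section
            ],
            "warnings": list(self.warnings),
        }


def _score_grid(grid: GridComposition, index: IndexChoice, clip: ClipPolicy):
    m = morisita_horn(grid)
    s = shannon_diversity(grid)
    raw = tilab_score_raw(grid, index)
    t = min(raw, 1.0) if clip == "cap_at_one" else raw
    empty = (
        float(grid.p_t[grid.valid].sum()) == 0.0
        and float(grid.p_l[grid.valid].sum()) == 0.0
    )
    return m, s, t, raw, empty


def score_wsi(
    pmap: PredictionMap,
    sections: SectionLabels,
    cell_size_mm: float,
    index: IndexChoice = "mh",
    clip: ClipPolicy = "cap_at_one",
) -> ColocReport:
    """Score every tissue section and the whole slide.

    Per-section scores come from grids restricted to each section; the
    WSI-level score uses a single grid over the full lattice, consistent with
    the global sums in the index definitions.
    """
    if sections.section_id.shape != pmap.shape:
        raise ValidationError("sections are not aligned with the map")
    warnings: list[str] = []
    per_section: list[SectionScore] = []
    for sid in range(1, sections.n_sections + 1):
        grid = build_grid(pmap, cell_size_mm, sections=sections, section_id=sid)
        m, s, t, raw, empty = _score_grid(grid, index, clip)
        if empty:
            warnings.append(
                f"section {sid}: no tumour or lymphocyte patches; "
                "TILAb takes the no-tumour convention value 1"
            )
        per_section.append(
            SectionScore(
                section_id=sid,
                morisita_horn=m,
                shannon=s,
                tilab=t,
                tilab_preclip=raw,
                n_cells=grid.n_cells,
                no_tumour_or_lymph=empty,
            )
        )
    wsi_grid = build_grid(pmap, cell_size_mm)
    m, s, t, raw, empty = _score_grid(wsi_grid, index, clip)
    if empty:
        warnings.append(
            "slide: no tumour or lymphocyte patches; "
            "TILAb takes the no-tumour convention value 1"
        )
    return ColocReport(
        slide_id=pmap.slide_id,
        per_section=tuple(per_section),
        wsi_morisita_horn=m,
        wsi_shannon=s,
        wsi_tilab=t,
        wsi_tilab_preclip=raw,
        cell_size_mm=cell_size_mm,
        index=index,
        clip=clip,
        warnings=tuple(warnings),
    )
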