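"""Seeded generators for synthetic prediction maps and survival cohorts.

The map generator emulates the qualitative co-localization regimes seen in
real slides — a fully mixed tumour/lymphocyte interface, spatially
segregated compartments, mixing confined to a narrow interface band, and
blob-like tissue niches — with controlled overall class composition.  The
cohort generator draws exponential event times whose hazard is linked to a
per-subject score either through a step (hazard jump at a threshold) or
log-linearly, with uniform administrative censoring.  Everything is
bit-reproducible from (spec, seed); there is no hidden global random state.

These fixtures emulate composition and spatial arrangement only: no H&E
texture, no classifier noise, no correlation structure between covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from tilab.coloc import GridComposition
from tilab.errors import ValidationError
from tilab.predmap import PredictionMap, TissueClass
from tilab.survival import SurvivalRecord

__all__ = [
    "MapSpec",
    "CohortSpec",
    "generate_map",
    "uniform_composition_grid",
    "generate_cohort",
]

Regime = Literal["uniform_mix", "segregated", "interface_band", "random_blobs"]


@dataclass(frozen=True)
class MapSpec:
    """Recipe for one synthetic prediction map."""

    rows: int = 128
    cols: int = 128
    regime: Regime = "uniform_mix"
    lymph_fraction: float = 0.25
    tumour_fraction: float = 0.25
    blob_count: int = 12
    blob_mean_radius: float = 4.0
    band_width: int = 16
    seed: int = 0
    patch_size_px: int = 128
    microns_per_pixel: float = 0.55

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("lattice size must be >= 1x1")
        lam, tau = self.lymph_fraction, self.tumour_fraction
        if not (0 <= lam <= 1 and 0 <= tau <= 1 and lam + tau <= 1 + 1e-12):
            raise ValidationError(
                f"need lymph_fraction + tumour_fraction <= 1, got {lam} + {tau}"
            )


def _place_exact(
    labels: np.ndarray,
    positions: np.ndarray,
    cls: TissueClass,
    count: int,
    rng: np.random.Generator,
) -> None:
    """Assign ``cls`` to exactly ``count`` randomly chosen free positions."""
    if count > positions.size:
        raise ValidationError(
            f"cannot place {count} {cls.name} patches in a region of {positions.size}"
        )
    chosen = rng.choice(positions, size=count, replace=False)
    labels.ravel()[chosen] = cls


def _paint_blobs(
    labels: np.ndarray,
    cls: TissueClass,
    target: int,
    mean_radius: float,
    rng: np.random.Generator,
) -> None:
    """Paint random discs of ``cls`` over stroma until ``target`` patches are
    covered, then trim the excess at random so the count is exact."""
    rows, cols = labels.shape
    rr, cc = np.indices(labels.shape)
    guard = 0
    while int((labels == cls).sum()) < target:
        guard += 1
        if guard > 10000:
            raise ValidationError("blob painting failed to reach target fraction")
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        radius = max(1.0, rng.normal(mean_radius, mean_radius / 3.0))
        disc = ((rr + 0.5 - cy) ** 2 + (cc + 0.5 - cx) ** 2) <= radius**2
        labels[disc & (labels == TissueClass.STROMA)] = cls
    painted = np.flatnonzero(labels.ravel() == cls)
    excess = painted.size - target
    if excess > 0:
        drop = rng.choice(painted, size=excess, replace=False)
        labels.ravel()[drop] = TissueClass.STROMA


def generate_map(spec: MapSpec) -> PredictionMap:
    """Generate a synthetic prediction map; deterministic given the spec's seed.

    All regimes except ``uniform_mix`` realise the requested class fractions
    exactly; ``uniform_mix`` scatters classes independently per patch, so its
    realised fractions fluctuate at the multinomial scale.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols
    n = rows * cols
    lam, tau = spec.lymph_fraction, spec.tumour_fraction
    n_l, n_t = round(lam * n), round(tau * n)
    labels = np.full((rows, cols), int(TissueClass.STROMA), dtype=np.uint8)

    if spec.regime == "uniform_mix":
        u = rng.random(n).reshape(rows, cols)
        labels[u < lam] = TissueClass.LYMPHOCYTE
        labels[(u >= lam) & (u < lam + tau)] = TissueClass.TUMOUR
    elif spec.regime == "segregated":
        half = cols // 2
        flat_idx = np.arange(n).reshape(rows, cols)
        left = flat_idx[:, :half].ravel()
        right = flat_idx[:, half:].ravel()
        _place_exact(labels, left, TissueClass.LYMPHOCYTE, n_l, rng)
        _place_exact(labels, right, TissueClass.TUMOUR, n_t, rng)
    elif spec.regime == "interface_band":
        w = min(spec.band_width, rows)
        top_end = max(0, (rows - w) // 2)
        bot_start = min(rows, top_end + w)
        flat_idx = np.arange(n).reshape(rows, cols)
        tumour_region = flat_idx[:bot_start, :].ravel()       # top + band
        _place_exact(labels, tumour_region, TissueClass.TUMOUR, n_t, rng)
        free = np.flatnonzero(labels.ravel() == TissueClass.STROMA)
        lymph_region = flat_idx[top_end:, :].ravel()          # band + bottom
        lymph_free = np.intersect1d(free, lymph_region, assume_unique=False)
        _place_exact(labels, lymph_free, TissueClass.LYMPHOCYTE, n_l, rng)
    elif spec.regime == "random_blobs":
        _paint_blobs(labels, TissueClass.TUMOUR, n_t, spec.blob_mean_radius, rng)
        _paint_blobs(labels, TissueClass.LYMPHOCYTE, n_l, spec.blob_mean_radius, rng)
    else:
        raise ValidationError(f"unknown regime {spec.regime!r}")

    return PredictionMap(
        labels=labels,
        patch_size_px=spec.patch_size_px,
        microns_per_pixel=spec.microns_per_pixel,
        slide_id=f"synthetic-{spec.regime}-{spec.seed}",
    )


def uniform_composition_grid(
    lymph_fraction: float,
    tumour_fraction: float,
    m: int = 4,
    n: int = 4,
    cell_size_mm: float = 0.28,
) -> GridComposition:
    """Exact uniform-composition grid: every cell holds the same (p_l, p_t).

    The analytic workhorse for sweep checks — no sampling involved.
    """
    if lymph_fraction + tumour_fraction > 1 + 1e-12:
        raise ValidationError("fractions must sum to <= 1")
    return GridComposition(
        p_l=np.full((m, n), lymph_fraction, dtype=float),
        p_t=np.full((m, n), tumour_fraction, dtype=float),
        cell_size_mm=cell_size_mm,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated survival cohort with a known score-hazard link.

    The hazard of subject i is ``baseline_hazard * exp(log_hr * z_i)`` where
    z is 1[score < threshold] under the ``binary_at_threshold`` link (low
    score = high risk, matching the protective-score convention) or the raw
    score under ``linear_in_score``.  Censoring is uniform on
    (0, censoring_window] months.
    """

    n_subjects: int = 200
    baseline_hazard: float = 0.02
    log_hr: float = 0.7
    link: Literal["binary_at_threshold", "linear_in_score"] = "binary_at_threshold"
    threshold: float = 0.5
    censoring_window: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not (self.baseline_hazard > 0):
            raise ValidationError("baseline_hazard must be positive")
        if not (self.censoring_window > 0):
            raise ValidationError("censoring_window must be positive")


def generate_cohort(
    spec: CohortSpec, scores: Sequence[float]
) -> list[SurvivalRecord]:
    """Simulate follow-up for subjects with the given scores.

    Event times are exponential under the linked hazard; censoring times are
    uniform on the window; the observed time is the minimum.  Each record
    carries the true linked covariate as covariate ``z_true`` (and, for the
    binary link, ``true_group``) so recovery experiments can condition on it.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != spec.n_subjects:
        raise ValidationError(
            f"expected {spec.n_subjects} scores, got {scores.size}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.link == "binary_at_threshold":
        z = (scores < spec.threshold).astype(float)
    elif spec.link == "linear_in_score":
        z = scores
    else:
        raise ValidationError(f"unknown link {spec.link!r}")
    hazard = spec.baseline_hazard * np.exp(spec.log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, spec.censoring_window, size=spec.n_subjects)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-9)
    event = (t_event <= t_cens).astype(int)

    records = []
    for i in range(spec.n_subjects):
        covs: dict[str, object] = {"z_true": float(z[i])}
        if spec.link == "binary_at_threshold":
            covs["true_group"] = "high_risk" if z[i] == 1.0 else "low_risk"
        records.append(
            SurvivalRecord(
                subject_id=f"S{i:04d}",
                time=float(time[i]),
                event=int(event[i]),
                score=float(scores[i]),
                covariates=covs,
            )
        )
    return records
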