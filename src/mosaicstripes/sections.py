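"""Grid-based scoring of stained sections.

Mirrors the manual protocol for liver frozen sections: five square scoring
regions of roughly 200 cells each are placed at random positions on the
section, each subdivided by a 10 x 10 graticule, and positive/negative
cells are tallied.  Scoring never sees genotype metadata (that join happens
at the inference stage), mirroring blinded manual counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .circular import GeometryError
from .synthetic import SyntheticSection

__all__ = [
    "SectionCount",
    "place_scoring_regions",
    "count_region",
    "score_section",
    "section_percent_positive",
]

GRID_SHAPE = (10, 10)


@dataclass(frozen=True)
class SectionCount:
    """Positive/negative cell tallies for one square scoring region."""

    region_id: int
    n_positive: int
    n_negative: int
    region_origin: tuple[int, int]  # (row, col) of the square's top-left
    grid_positive: np.ndarray = field(default=None, repr=False)  # 10x10 tallies
    grid_negative: np.ndarray = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_total if self.n_total else float("nan")


def _tissue_mask(section) -> np.ndarray:
    if isinstance(section, SyntheticSection):
        return section.tissue_mask
    mask = np.asarray(section, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("tissue mask must be 2-D")
    return mask


def place_scoring_regions(
    section,
    region_size: int,
    n_regions: int = 5,
    seed: int | None = None,
    allow_overlap: bool = False,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Draw region origins uniformly over positions fully inside tissue.

    Origins are the top-left corners of ``region_size`` x ``region_size``
    squares.  By default regions may not overlap one another (rejection
    sampling), since overlapping fields would double-count cells.
    Deterministic for a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be at least 1")
    mask = _tissue_mask(section)
    s = int(region_size)
    if s < 1:
        raise ValueError("region_size must be positive")

    # a square at (r, c) is valid iff all s*s pixels under it are tissue;
    # exact sliding-window sums via an integral image
    h, w = mask.shape
    if h < s or w < s:
        raise GeometryError("scoring region larger than the section")
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    window_sums = (
        integral[s:, s:] - integral[:-s, s:] - integral[s:, :-s] + integral[:-s, :-s]
    )
    origins_all = np.argwhere(window_sums == s * s)
    if origins_all.shape[0] == 0:
        raise GeometryError("no position admits a fully-in-tissue scoring region")

    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(chosen) == n_regions:
            break
        r, c = origins_all[rng.integers(origins_all.shape[0])]
        if not allow_overlap and any(
            abs(r - r0) < s and abs(c - c0) < s for r0, c0 in chosen
        ):
            continue
        chosen.append((int(r), int(c)))
    if len(chosen) < n_regions:
        raise GeometryError(
            f"could not place {n_regions} non-overlapping regions of size {s}"
        )
    return chosen


def count_region(
    section: SyntheticSection,
    origin: tuple[int, int],
    region_size: int,
    region_id: int = 0,
) -> SectionCount:
    """Tally positive/negative cells whose centroid lies in the square.

    Centroid assignment puts every cell in exactly one region, avoiding the
    double counting that edge-spanning cells would otherwise cause.  The
    square is also subdivided into a 10 x 10 grid of tallies, mirroring the
    eyepiece graticule used for manual counting.
    """
    labels = section.label_mask
    n_cells = section.n_cells
    if labels.max() > n_cells:
        raise ValueError("label mask references a cell without a class")
    centroids = np.asarray(
        ndimage.center_of_mass(labels > 0, labels, index=np.arange(1, n_cells + 1))
    )
    r0, c0 = origin
    s = int(region_size)
    inside = (
        (centroids[:, 0] >= r0)
        & (centroids[:, 0] < r0 + s)
        & (centroids[:, 1] >= c0)
        & (centroids[:, 1] < c0 + s)
    )
    cls = section.cell_classes[inside]
    gp = np.zeros(GRID_SHAPE, dtype=int)
    gn = np.zeros(GRID_SHAPE, dtype=int)
    if inside.any():
        sub_r = np.clip(((centroids[inside, 0] - r0) / s * GRID_SHAPE[0]).astype(int),
                        0, GRID_SHAPE[0] - 1)
        sub_c = np.clip(((centroids[inside, 1] - c0) / s * GRID_SHAPE[1]).astype(int),
                        0, GRID_SHAPE[1] - 1)
        np.add.at(gp, (sub_r[cls == 1], sub_c[cls == 1]), 1)
        np.add.at(gn, (sub_r[cls == 0], sub_c[cls == 0]), 1)
    return SectionCount(
        region_id=int(region_id),
        n_positive=int((cls == 1).sum()),
        n_negative=int((cls == 0).sum()),
        region_origin=(int(r0), int(c0)),
        grid_positive=gp,
        grid_negative=gn,
    )


def score_section(
    section: SyntheticSection,
    region_size: int,
    n_regions: int = 5,
    seed: int | None = None,
    allow_overlap: bool = False,
) -> list[SectionCount]:
    """Place scoring regions and count each one (the full blinded protocol)."""
    origins = place_scoring_regions(
        section, region_size, n_regions=n_regions, seed=seed,
        allow_overlap=allow_overlap,
    )
    return [
        count_region(section, o, region_size, region_id=i)
        for i, o in enumerate(origins)
    ]


def section_percent_positive(counts: list[SectionCount]) -> float:
    """Pooled fraction positive across regions (the per-animal value).

    Pooling the raw tallies rather than averaging per-region proportions
    gives the minimum-variance estimate when region sizes are near-equal.
    Returns NaN when the regions contain no cells at all.
    """
    if not counts:
        raise ValueError("need at least one scoring region")
    pos = sum(c.n_positive for c in counts)
    tot = sum(c.n_total for c in counts)
    return pos / tot if tot else float("nan")
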