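"""Synthetic mosaic tissue and breeding-cross generators.

Every downstream stage of the stripe/section analysis is exercised on
synthetic inputs whose ground truth is known exactly: a ring of angular
clones standing in for the corneal epithelium sampled around a circle,
a cell-label mask standing in for a stained liver section, and offspring
counts from the heterozygous-female x transgenic-male cross.

Angles follow the mathematical convention (counter-clockwise from the
positive x-axis), stored in radians in [0, 2*pi). Images are row-major
with pixel (0, 0) at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circular import BACKGROUND, NEGATIVE, POSITIVE, MosaicImage

TWO_PI = 2.0 * np.pi

__all__ = [
    "CloneRing",
    "SyntheticCornea",
    "SyntheticSection",
    "GenotypeCounts",
    "simulate_clone_ring",
    "render_cornea",
    "simulate_section",
    "simulate_cross",
]


@dataclass(frozen=True)
class CloneRing:
    """A circumference partitioned into contiguous angular clones.

    Clone ``i`` spans the arc from ``boundaries[i]`` counter-clockwise to
    the next boundary (wrapping past 2*pi for the last clone).  Each clone
    carries an independent Bernoulli(p) stain label (1 = beta-gal positive).
    """

    boundaries: np.ndarray  # sorted, unique, radians in [0, 2*pi)
    labels: np.ndarray      # uint8, 1 = positive, same length
    p_true: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        lab = np.asarray(self.labels, dtype=np.uint8)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("boundaries must be a non-empty 1-D array")
        if lab.shape != b.shape:
            raise ValueError("labels and boundaries must have equal length")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if b[0] < 0 or b[-1] >= TWO_PI:
            raise ValueError("boundaries must lie in [0, 2*pi)")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "labels", lab)

    @property
    def n_clones(self) -> int:
        return int(self.boundaries.size)

    @property
    def widths(self) -> np.ndarray:
        """Angular width of each clone in radians; sums to 2*pi."""
        d = np.diff(self.boundaries, append=self.boundaries[0] + TWO_PI)
        return d

    @property
    def positive_fraction(self) -> float:
        """Realized arc-length fraction of the circumference that is positive."""
        return float(self.widths[self.labels == 1].sum() / TWO_PI)

    def label_at(self, theta: np.ndarray | float) -> np.ndarray:
        """Stain label (0/1) of the clone containing each angle ``theta``."""
        t = np.mod(np.asarray(theta, dtype=float), TWO_PI)
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        # angles before the first boundary belong to the clone that wraps
        idx = np.where(idx < 0, self.n_clones - 1, idx)
        return self.labels[idx]

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        """Write the ground-truth sidecar used next to rendered images."""
        payload = {
            "n_clones": self.n_clones,
            "boundaries": self.boundaries.tolist(),
            "labels": self.labels.tolist(),
            "p_true": self.p_true,
            "seed": seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CloneRing":
        d = json.loads(Path(path).read_text())
        return cls(
            boundaries=np.asarray(d["boundaries"], dtype=float),
            labels=np.asarray(d["labels"], dtype=np.uint8),
            p_true=float(d["p_true"]),
        )


@dataclass(frozen=True)
class SyntheticCornea:
    """A rendered whole-mount-like disc image plus its generating ring."""

    image: MosaicImage
    center: tuple[float, float]  # (row, col)
    corneal_radius: float
    ring: CloneRing
    seed: int | None
    flipped_fraction: float = 0.0  # realized salt-pepper flip rate inside the disc


@dataclass(frozen=True)
class SyntheticSection:
    """A cell-label mask standing in for a stained frozen section.

    ``label_mask`` holds integer cell identities (0 = no tissue); cell ``i``
    (label ``i + 1``) has stain class ``cell_classes[i]`` (1 = positive).
    """

    label_mask: np.ndarray
    cell_classes: np.ndarray
    p_true: float
    seed: int | None

    @property
    def n_cells(self) -> int:
        return int(self.cell_classes.size)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_mask > 0


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed offspring counts by class, with an optional expected ratio."""

    labels: tuple[str, ...]
    observed: np.ndarray
    expected_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        if obs.ndim != 1 or obs.size != len(self.labels):
            raise ValueError("observed must be 1-D and match labels")
        if np.any(obs < 0):
            raise ValueError("counts must be non-negative")
        if obs.sum() <= 0:
            raise ValueError("total count must be positive")
        object.__setattr__(self, "observed", obs)
        if self.expected_ratio is not None:
            r = np.asarray(self.expected_ratio, dtype=float)
            if r.shape != obs.shape or np.any(r <= 0):
                raise ValueError("expected_ratio must be positive and match observed")
            object.__setattr__(self, "expected_ratio", r)


def _check_probability(p: float, name: str = "p") -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return p


def simulate_clone_ring(
    n_clones: int,
    p: float,
    width_model: str = "equal",
    seed: int | None = None,
    alpha: float = 5.0,
    rng: np.random.Generator | None = None,
) -> CloneRing:
    """Draw a ring of ``n_clones`` contiguous clones with Bernoulli(p) labels.

    ``width_model`` is ``"equal"`` (all clones span 2*pi/N) or ``"dirichlet"``
    (widths proportional to a symmetric Dirichlet(alpha) draw, modelling
    clone-size heterogeneity).  The whole ring is given a random rotation so
    boundaries are not axis-aligned.  Deterministic for a fixed seed.
    """
    if int(n_clones) != n_clones or n_clones < 1:
        raise ValueError(f"n_clones must be a positive integer, got {n_clones}")
    n_clones = int(n_clones)
    p = _check_probability(p)
    if rng is None:
        rng = np.random.default_rng(seed)

    if width_model == "equal":
        widths = np.full(n_clones, TWO_PI / n_clones)
    elif width_model == "dirichlet":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        widths = rng.dirichlet(np.full(n_clones, float(alpha))) * TWO_PI
    else:
        raise ValueError(f"unknown width_model {width_model!r}")

    offset = rng.uniform(0.0, TWO_PI)
    boundaries = np.mod(offset + np.concatenate(([0.0], np.cumsum(widths[:-1]))), TWO_PI)
    labels = (rng.random(n_clones) < p).astype(np.uint8)
    order = np.argsort(boundaries, kind="stable")
    return CloneRing(boundaries=boundaries[order], labels=labels[order], p_true=p)


def render_cornea(
    ring: CloneRing,
    image_size: int = 512,
    corneal_radius: float | None = None,
    center: tuple[float, float] | None = None,
    noise_rate: float = 0.0,
    seed: int | None = None,
) -> SyntheticCornea:
    """Render a clone ring as a radially striped disc label image.

    Every pixel inside the disc takes the stain class of the clone at its
    polar angle; pixels outside are background.  ``noise_rate`` flips the
    class of each in-disc pixel independently (salt-and-pepper), applied
    after class assignment; the generating ring is kept as ground truth.
    """
    if corneal_radius is None:
        corneal_radius = 0.45 * image_size
    if center is None:
        center = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    noise_rate = _check_probability(noise_rate, "noise_rate")
    cr, cc = center
    if (cr - corneal_radius < -0.5 or cc - corneal_radius < -0.5
            or cr + corneal_radius > image_size - 0.5
            or cc + corneal_radius > image_size - 0.5):
        raise ValueError("corneal disc does not fit inside the image canvas")

    rows, cols = np.mgrid[0:image_size, 0:image_size]
    x = cols - cc
    y = cr - rows  # flip rows so angles run counter-clockwise on screen
    r = np.hypot(x, y)
    inside = r <= corneal_radius
    theta = np.mod(np.arctan2(y, x), TWO_PI)

    pixels = np.full((image_size, image_size), BACKGROUND, dtype=np.uint8)
    lab = ring.label_at(theta[inside])
    pixels[inside] = np.where(lab == 1, POSITIVE, NEGATIVE)

    flipped_fraction = 0.0
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        flip = np.zeros_like(inside)
        flip[inside] = rng.random(int(inside.sum())) < noise_rate
        pixels[flip & (pixels == POSITIVE)] = 255  # placeholder to avoid double flip
        pixels[flip & (pixels == NEGATIVE)] = POSITIVE
        pixels[pixels == 255] = NEGATIVE
        flipped_fraction = float(flip.sum() / inside.sum())

    return SyntheticCornea(
        image=MosaicImage(pixels),
        center=center,
        corneal_radius=float(corneal_radius),
        ring=ring,
        seed=seed,
        flipped_fraction=flipped_fraction,
    )


def simulate_section(
    n_cells: int,
    p: float,
    seed: int | None = None,
    cell_size: int = 8,
) -> SyntheticSection:
    """Generate a patchwork section: a grid of square cells with i.i.d. labels.

    Cells are laid out in a near-square grid of ``cell_size`` x ``cell_size``
    pixel blocks; each cell is beta-gal positive independently with
    probability ``p``.  The layout is deliberately simple — the statistics
    downstream depend only on the per-cell Bernoulli classes and centroids.
    """
    if int(n_cells) != n_cells or n_cells < 1:
        raise ValueError(f"n_cells must be a positive integer, got {n_cells}")
    n_cells = int(n_cells)
    p = _check_probability(p)
    rng = np.random.default_rng(seed)

    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    mask = np.zeros((nrows * cell_size, ncols * cell_size), dtype=np.int32)
    for i in range(n_cells):
        rr, cc = divmod(i, ncols)
        mask[rr * cell_size:(rr + 1) * cell_size,
             cc * cell_size:(cc + 1) * cell_size] = i + 1
    classes = (rng.random(n_cells) < p).astype(np.uint8)
    return SyntheticSection(label_mask=mask, cell_classes=classes, p_true=p, seed=seed)


def simulate_cross(
    n_conceptions: int,
    lethality_het: float = 0.0,
    seed: int | None = None,
) -> GenotypeCounts:
    """Simulate offspring of the heterozygous-female x transgenic-male cross.

    Conceptions fall into four Mendelian classes with probability 1/4 each:
    heterozygous (mutant-carrying) females, wild-type females, hemizygous
    mutant males and wild-type males.  Hemizygous mutant males die before
    birth; heterozygous females die with probability ``lethality_het``.
    Surviving males are not genotyped, so the returned classes are
    ``het_female``, ``wt_female`` and (pooled) ``male``.
    """
    if int(n_conceptions) != n_conceptions or n_conceptions < 1:
        raise ValueError("n_conceptions must be a positive integer")
    lethality_het = _check_probability(lethality_het, "lethality_het")
    rng = np.random.default_rng(seed)

    het_f, wt_f, mut_m, wt_m = rng.multinomial(int(n_conceptions), [0.25] * 4)
    het_f_surviving = rng.binomial(het_f, 1.0 - lethality_het)
    del mut_m  # hemizygous mutant males die in utero
    return GenotypeCounts(
        labels=("het_female", "wt_female", "male"),
        observed=np.array([het_f_surviving, wt_f, wt_m], dtype=float),
    )
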