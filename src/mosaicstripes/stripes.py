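"""Per-eye stripe summary statistics and the clone-merging correction.

A beta-gal-positive stripe seen on the sampling circle is typically the
fusion of several adjacent positive clones.  With clones labelled
independently with probability ``p``, the expected number of consecutive
positive clones in one positive stripe is the geometric run length
``1/(1-p)``.  Dividing the observed mean positive-stripe width by this
factor gives the corrected mean stripe width

    w_corr = w_obs * (1 - p_hat),

an estimate of the width of a single coherent clone; its reciprocal,
``n_corr = 1/w_corr``, estimates the total number of active coherent
clones (positive and negative together) per circumference.

Statistics are undefined when the circle is entirely one class
(``p_hat`` of 0 or 1); they propagate as NaN, never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .circular import RunSegment

__all__ = [
    "StripeStats",
    "MouseSummary",
    "percent_positive",
    "observed_mean_stripe_width",
    "corrected_stripe_stats",
    "stripe_stats_from_runs",
    "summarize_mouse",
]


@dataclass(frozen=True)
class StripeStats:
    """Per-eye summary of the circular clonal analysis."""

    p_hat: float          # fraction of the circumference that is positive
    n_pos_stripes: int    # observed count of positive stripes
    w_obs: float          # observed mean positive-stripe width (fraction)
    w_corr: float         # corrected mean stripe width = w_obs * (1 - p_hat)
    n_corr: float         # corrected stripe number per circumference = 1/w_corr

    @property
    def defined(self) -> bool:
        return np.isfinite(self.n_corr)


@dataclass(frozen=True)
class MouseSummary:
    """Per-mouse values: means of left and right eyes."""

    mouse_id: str
    genotype: str
    age_weeks: float
    p_hat_mean: float
    n_corr_mean: float
    n_eyes: int
    complete: bool  # both eyes present and defined


def _validate_runs(runs: Sequence[RunSegment]) -> None:
    if not runs:
        raise ValueError("runs must be non-empty")
    total = sum(r.width for r in runs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"run widths must sum to 1 (got {total!r})")


def percent_positive(runs: Sequence[RunSegment]) -> float:
    """Fraction of the circumference covered by positive runs."""
    _validate_runs(runs)
    return float(sum(r.width for r in runs if r.positive))


def observed_mean_stripe_width(runs: Sequence[RunSegment]) -> float:
    """Arithmetic mean width of the positive runs; NaN when there are none."""
    _validate_runs(runs)
    pos = [r.width for r in runs if r.positive]
    if not pos:
        return float("nan")
    return float(np.mean(pos))


def corrected_stripe_stats(w_obs: float, p_hat: float) -> tuple[float, float]:
    """Apply the geometric clone-merging correction.

    Returns ``(w_corr, n_corr)`` with ``w_corr = w_obs * (1 - p_hat)`` and
    ``n_corr = 1 / w_corr``.  At ``p_hat == 1`` the correction degenerates
    (``w_corr == 0``) and ``n_corr`` is NaN.
    """
    if not np.isfinite(w_obs) or w_obs <= 0:
        raise ValueError(f"w_obs must be positive, got {w_obs}")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError(f"p_hat must lie in [0, 1], got {p_hat}")
    w_corr = w_obs * (1.0 - p_hat)
    n_corr = 1.0 / w_corr if w_corr > 0 else float("nan")
    return float(w_corr), float(n_corr)


def stripe_stats_from_runs(runs: Sequence[RunSegment]) -> StripeStats:
    """Full per-eye summary from the extracted runs of one sampling circle."""
    p_hat = percent_positive(runs)
    n_pos = sum(1 for r in runs if r.positive)
    w_obs = observed_mean_stripe_width(runs)
    if not np.isfinite(w_obs) or p_hat >= 1.0:
        # all-negative (no positive stripe) or all-positive circle
        w_corr = float("nan") if not np.isfinite(w_obs) else 0.0
        n_corr = float("nan")
    else:
        w_corr, n_corr = corrected_stripe_stats(w_obs, p_hat)
    return StripeStats(p_hat=p_hat, n_pos_stripes=n_pos, w_obs=w_obs,
                       w_corr=w_corr, n_corr=n_corr)


def summarize_mouse(
    per_eye_stats: Iterable[tuple[str, StripeStats]],
    mouse_id: str,
    genotype: str,
    age_weeks: float,
) -> MouseSummary:
    """Average the per-eye statistics of one mouse over its available eyes.

    Accepts one or two eyes labelled 'L'/'R'; duplicate labels are an
    error.  Undefined per-eye statistics are excluded from the mean with a
    warning, and the summary is flagged incomplete.
    """
    items = list(per_eye_stats)
    if not 1 <= len(items) <= 2:
        raise ValueError("a mouse has 1 or 2 analysed eyes")
    eyes = [e for e, _ in items]
    if len(set(eyes)) != len(eyes):
        raise ValueError(f"duplicate eye labels for mouse {mouse_id}: {eyes}")

    p_vals = np.array([s.p_hat for _, s in items], dtype=float)
    n_vals = np.array([s.n_corr for _, s in items], dtype=float)
    undefined = ~np.isfinite(n_vals)
    if undefined.any():
        warnings.warn(
            f"mouse {mouse_id}: corrected stripe number undefined for "
            f"{int(undefined.sum())} eye(s); excluded from the mouse mean",
            stacklevel=2,
        )
    n_corr_mean = float(np.nanmean(n_vals)) if np.isfinite(n_vals).any() else float("nan")
    return MouseSummary(
        mouse_id=str(mouse_id),
        genotype=str(genotype),
        age_weeks=float(age_weeks),
        p_hat_mean=float(np.mean(p_vals)),
        n_corr_mean=n_corr_mean,
        n_eyes=len(items),
        complete=len(items) == 2 and not undefined.any(),
    )
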