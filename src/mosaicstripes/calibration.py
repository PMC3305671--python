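"""Large-scale simulation drivers for estimator calibration.

These routines evaluate the corrected-stripe-number estimator over many
replicate clone rings at once.  Per-ring analysis on equal-width rings has
a closed vectorized form — the positive fraction is the label mean and
positive stripes are circular 0->1 transitions — so tens of thousands of
replicates run in milliseconds.  The batch path is asserted equal to the
run-segment pipeline in the test-suite.
"""

from __future__ import annotations

import numpy as np

from .inference import batch_two_way_anova

__all__ = [
    "expected_positive_runs",
    "batch_ring_n_corr",
    "recovery_simulation",
    "null_cohort_type1_error",
    "simulate_cohort_n_corr",
]


def expected_positive_runs(n_clones: int, p: float, exact: bool = False) -> float:
    """Expected number of positive stripes on a ring of N Bernoulli(p) clones.

    Each of the N clones starts a positive stripe iff it is positive and its
    counter-clockwise predecessor is negative, hence N * p * (1 - p).  The
    all-positive ring is the one exception — one visible stripe but no 0->1
    transition — so the exact expected count of maximal positive runs is
    N*p*(1-p) + p**N; ``exact=True`` includes that (vanishing) term.
    """
    base = n_clones * p * (1.0 - p)
    return base + p**n_clones if exact else base


def batch_ring_n_corr(labels: np.ndarray) -> np.ndarray:
    """Corrected stripe number for each row of a (replicates, N) label matrix.

    Assumes equal clone widths, so the positive fraction is the label mean
    and each circular 0->1 transition starts one positive stripe.  Rings
    that are entirely one class have an undefined estimate (NaN).
    """
    L = np.asarray(labels, dtype=bool)
    p_hat = L.mean(axis=1)
    n_runs = (L & ~np.roll(L, 1, axis=1)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_obs = p_hat / n_runs                 # mean positive-stripe width
        n_corr = 1.0 / (w_obs * (1.0 - p_hat))  # = n_runs / (p_hat*(1-p_hat))
    n_corr[(p_hat == 0) | (p_hat == 1)] = np.nan
    return n_corr


def recovery_simulation(
    n_clones: int,
    p: float,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Distribution of the corrected stripe number over replicate rings.

    Draws ``n_replicates`` equal-width rings of ``n_clones`` Bernoulli(p)
    clones and applies the full per-eye estimator to each.  Returns the mean
    and SD of the defined estimates, the fraction of undefined (monochrome)
    rings, and the relative bias of the mean with respect to the true N.
    """
    rng = np.random.default_rng(seed)
    labels = rng.random((n_replicates, n_clones)) < p
    n_corr = batch_ring_n_corr(labels)
    defined = np.isfinite(n_corr)
    mean = float(np.mean(n_corr[defined])) if defined.any() else float("nan")
    return {
        "n_clones": float(n_clones),
        "p": float(p),
        "n_replicates": float(n_replicates),
        "mean_n_corr": mean,
        "sd_n_corr": float(np.std(n_corr[defined], ddof=1)) if defined.sum() > 1 else float("nan"),
        "frac_undefined": float(1.0 - defined.mean()),
        "relative_bias": float(mean / n_clones - 1.0) if defined.any() else float("nan"),
    }


def simulate_cohort_n_corr(
    group_sizes: dict[tuple[str, str], int],
    n_clones: int = 100,
    p: float = 0.5,
    n_replicates: int = 1,
    seed: int | None = None,
    eyes_per_mouse: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-mouse corrected stripe numbers for replicate null cohorts.

    Every mouse in every group shares the same true clone number and stain
    probability (no genotype or age effect).  Each mouse contributes the
    mean of its eyes' estimates.  Returns ``(values, genotypes, ages)``
    where ``values`` has shape ``(n_mice, n_replicates)``.
    """
    rng = np.random.default_rng(seed)
    n_mice = sum(group_sizes.values())
    genotypes = np.concatenate([
        np.repeat(g, n) for (g, _a), n in group_sizes.items()
    ])
    ages = np.concatenate([
        np.repeat(a, n) for (_g, a), n in group_sizes.items()
    ])
    labels = rng.random(
        (n_mice * eyes_per_mouse * n_replicates, n_clones)
    ) < p
    n_corr = batch_ring_n_corr(labels).reshape(n_replicates, n_mice, eyes_per_mouse)
    values = np.nanmean(n_corr, axis=2).T  # (n_mice, n_replicates)
    return values, genotypes, ages


def null_cohort_type1_error(
    n_replicates: int = 10_000,
    group_sizes: dict[tuple[str, str], int] | None = None,
    n_clones: int = 100,
    p: float = 0.5,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict[str, float]:
    """Empirical per-term type-I error of the cohort ANOVA under the null.

    Simulates replicate cohorts with no genotype or age effect, runs the
    Type III two-way ANOVA on each (batched), and reports the fraction of
    replicates rejecting at ``alpha`` for each term.  Default group sizes
    mimic an unbalanced 2 genotypes x 2 ages cornea cohort (8, 9, 21, 22
    mice per cell).
    """
    if group_sizes is None:
        group_sizes = {
            ("het", "15"): 8, ("wt", "15"): 21,
            ("het", "30"): 9, ("wt", "30"): 22,
        }
    values, genotypes, ages = simulate_cohort_n_corr(
        group_sizes, n_clones=n_clones, p=p, n_replicates=n_replicates, seed=seed
    )
    res = batch_two_way_anova(values, genotypes, ages)
    return {
        "genotype": float((res["factor_a"]["p_value"] < alpha).mean()),
        "age": float((res["factor_b"]["p_value"] < alpha).mean()),
        "interaction": float((res["interaction"]["p_value"] < alpha).mean()),
        "n_replicates": float(n_replicates),
        "alpha": float(alpha),
    }
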