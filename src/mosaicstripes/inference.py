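"""Statistical inference: breeding-ratio goodness-of-fit tests and
two-way (genotype x age) analysis of variance with Bonferroni post-hocs.

The chi-square tests compare observed offspring class counts against
Mendelian expectations (Pearson statistic, no continuity correction).
The ANOVA uses Type III sums of squares with sum-to-zero factor coding
on possibly unbalanced designs, matching the convention of the commercial
package commonly used for this kind of group comparison; Type I and II
are available as options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GofResult",
    "PosthocResult",
    "chi_square_gof",
    "deficiency_percent",
    "two_way_anova",
    "batch_two_way_anova",
    "bonferroni_posthoc",
]


@dataclass(frozen=True)
class GofResult:
    """Pearson goodness-of-fit result."""

    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PosthocResult:
    """One Bonferroni-adjusted pairwise cell comparison."""

    comparison: tuple
    t: float
    p_unadjusted: float
    p_adjusted: float


def chi_square_gof(counts, expected_ratio=None) -> GofResult:
    """Pearson chi-square goodness-of-fit test against an expected ratio.

    ``counts`` is a sequence of observed class counts or a
    :class:`~mosaicstripes.synthetic.GenotypeCounts`; ``expected_ratio`` is
    a sequence of positive weights (any scale — e.g. ``(2, 1)`` for a 2:1
    expectation).  No continuity correction is applied.
    """
    observed = np.asarray(getattr(counts, "observed", counts), dtype=float)
    if expected_ratio is None:
        expected_ratio = getattr(counts, "expected_ratio", None)
    if expected_ratio is None:
        raise ValueError("an expected ratio is required")
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.ndim != 1 or observed.size < 2:
        raise ValueError("need at least two classes")
    if ratio.shape != observed.shape or np.any(ratio <= 0):
        raise ValueError("expected_ratio must be positive and match observed")
    if np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    total = observed.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")

    expected = total * ratio / ratio.sum()
    if np.any(expected < 1):
        raise ValueError("expected count below 1 in some class; test invalid")
    if np.any(expected < 5):
        warnings.warn("expected count below 5 in some class; chi-square "
                      "approximation may be poor", stacklevel=2)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    return GofResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def deficiency_percent(observed_class: float, reference_class: float) -> float:
    """Percent deficiency of one class relative to a same-expectation class.

    ``100 * (1 - observed/reference)``: e.g. 50 surviving heterozygous
    females against 88 wild-type littermates is a 43.2% deficiency.
    """
    if reference_class <= 0:
        raise ZeroDivisionError("reference class count must be positive")
    if observed_class < 0:
        raise ValueError("observed class count must be non-negative")
    return 100.0 * (1.0 - observed_class / reference_class)


def _prepare_frame(values, factor_a, factor_b, names=("genotype", "age")) -> pd.DataFrame:
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        names[0]: np.asarray(factor_a).astype(str),
        names[1]: np.asarray(factor_b).astype(str),
    })
    if len(df) != len(np.asarray(values)):
        raise ValueError("factor lengths must match values")
    for nm in names:
        if df[nm].nunique() < 2:
            raise ValueError(f"factor {nm!r} needs at least 2 levels")
    cells = df.groupby(list(names), observed=True).size()
    full = pd.MultiIndex.from_product([df[names[0]].unique(), df[names[1]].unique()])
    missing = full.difference(cells.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {list(missing)}; "
                         "Type III sums of squares are undefined")
    return df


def two_way_anova(
    values,
    factor_a,
    factor_b,
    ss_type: int = 3,
    names: tuple[str, str] = ("genotype", "age"),
) -> pd.DataFrame:
    """Two-way ANOVA with interaction on a possibly unbalanced design.

    Returns a table indexed by (factor A, factor B, interaction, Residual)
    with columns ``sum_sq``, ``df``, ``F`` and ``p_value``.  Default is
    Type III sums of squares with sum-to-zero factor coding; ``ss_type``
    of 1 or 2 selects sequential or hierarchical sums of squares.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    df = _prepare_frame(values, factor_a, factor_b, names)
    a, b = names
    model = smf.ols(f"value ~ C({a}, Sum) * C({b}, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.drop(index="Intercept", errors="ignore")
    rename = {
        f"C({a}, Sum)": a,
        f"C({b}, Sum)": b,
        f"C({a}, Sum):C({b}, Sum)": f"{a}:{b}",
    }
    table = table.rename(index=rename)
    table = table.rename(columns={"PR(>F)": "p_value"})
    return table[["sum_sq", "df", "F", "p_value"]]


def _effect_coding(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: columns for levels 0..L-2."""
    cols = np.zeros((codes.size, n_levels - 1))
    for lvl in range(n_levels - 1):
        cols[codes == lvl, lvl] = 1.0
    cols[codes == n_levels - 1, :] = -1.0
    return cols


def batch_two_way_anova(
    y: np.ndarray,
    factor_a,
    factor_b,
) -> dict[str, dict[str, np.ndarray]]:
    """Type III two-way ANOVA applied to many response vectors at once.

    ``y`` has shape ``(n_obs, n_datasets)``; the factor layout is shared by
    all datasets, so every dataset's full and reduced least-squares fits use
    the same design matrices and the whole batch reduces to a handful of
    matrix products.  Used for large-scale null calibration; agrees with
    :func:`two_way_anova` (asserted in the test-suite) but returns only the
    per-term ``sum_sq``, ``F`` and ``p_value`` arrays.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    a_codes, a_levels = pd.factorize(np.asarray(factor_a))
    b_codes, b_levels = pd.factorize(np.asarray(factor_b))
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least 2 levels")

    A = _effect_coding(a_codes, len(a_levels))
    B = _effect_coding(b_codes, len(b_levels))
    AB = np.einsum("ij,ik->ijk", A, B).reshape(y.shape[0], -1)
    ones = np.ones((y.shape[0], 1))

    def rss(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return np.einsum("ij,ij->j", resid, resid)

    full_X = np.hstack([ones, A, B, AB])
    rss_full = rss(full_X)
    df_res = y.shape[0] - full_X.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    out: dict[str, dict[str, np.ndarray]] = {}
    terms = {
        "factor_a": (np.hstack([ones, B, AB]), A.shape[1]),
        "factor_b": (np.hstack([ones, A, AB]), B.shape[1]),
        "interaction": (np.hstack([ones, A, B]), AB.shape[1]),
    }
    for name, (X_red, df_t) in terms.items():
        ss = np.maximum(rss(X_red) - rss_full, 0.0)
        F = (ss / df_t) / (rss_full / df_res)
        out[name] = {
            "sum_sq": ss,
            "df": df_t,
            "F": F,
            "p_value": stats.f.sf(F, df_t, df_res),
        }
    out["residual"] = {"sum_sq": rss_full, "df": df_res}
    return out


def bonferroni_posthoc(
    values,
    factor_a,
    factor_b,
    comparisons: list[tuple[tuple, tuple]],
    names: tuple[str, str] = ("genotype", "age"),
) -> list[PosthocResult]:
    """Bonferroni-adjusted pairwise cell comparisons after a two-way ANOVA.

    Each comparison is a pair of design cells ``((a1, b1), (a2, b2))``
    (e.g. the two genotypes at one age).  The t statistic uses the pooled
    residual variance of the full two-way model with interaction, and each
    p-value is multiplied by the number of comparisons requested, capped
    at 1.
    """
    if not comparisons:
        raise ValueError("at least one comparison is required")
    df = _prepare_frame(values, factor_a, factor_b, names)
    a, b = names
    groups = df.groupby([a, b], observed=True)["value"]
    means = groups.mean()
    sizes = groups.size()

    res = batch_two_way_anova(df["value"].to_numpy(), df[a], df[b])
    mse = float(res["residual"]["sum_sq"][0]) / res["residual"]["df"]
    df_res = res["residual"]["df"]

    m = len(comparisons)
    out = []
    for cell1, cell2 in comparisons:
        c1 = tuple(str(x) for x in cell1)
        c2 = tuple(str(x) for x in cell2)
        for c in (c1, c2):
            if c not in means.index:
                raise ValueError(f"comparison references empty cell {c}")
        se = np.sqrt(mse * (1.0 / sizes[c1] + 1.0 / sizes[c2]))
        t = (means[c1] - means[c2]) / se
        p = 2.0 * stats.t.sf(abs(t), df_res)
        out.append(PosthocResult(
            comparison=(c1, c2),
            t=float(t),
            p_unadjusted=float(p),
            p_adjusted=float(min(1.0, p * m)),
        ))
    return out
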