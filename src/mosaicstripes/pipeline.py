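"""Study orchestration: simulate or load a cohort, analyse every eye,
summarise per mouse, and run the group statistics.

A study is driven by a :class:`StudyConfig`, either constructed in code or
loaded from YAML.  Cohorts come from a manifest CSV of stained images
(columns ``mouse_id, genotype, age_weeks, eye, file``) or from a simulation
block; simulated eyes can be analysed at ring level (exact runs, fast) or
through full image rendering and circular sampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import (
    MosaicImage,
    SamplingCircle,
    extract_runs,
    fit_corneal_circle,
    runs_from_ring,
    sample_circle,
)
from .inference import GofResult, chi_square_gof, deficiency_percent, two_way_anova
from .stripes import StripeStats, stripe_stats_from_runs, summarize_mouse
from .synthetic import GenotypeCounts, render_cornea, simulate_clone_ring

__all__ = [
    "StudyConfig",
    "CorneaStudyResult",
    "SurvivalResult",
    "run_cornea_study",
    "run_survival_test",
    "load_image",
]


@dataclass
class StudyConfig:
    """Everything needed to run a cornea study reproducibly.

    Exactly one of ``manifest`` (CSV path) or ``simulation`` must be given.
    A simulation block maps ``(genotype, age_weeks)`` cells to mouse counts
    and states the generative parameters, e.g.::

        simulation = {
            "group_sizes": {("het", 15): 8, ("wt", 15): 21,
                            ("het", 30): 9, ("wt", 30): 22},
            "n_clones": 100, "p": 0.5, "width_model": "equal",
            "render": False,
        }
    """

    manifest: str | None = None
    simulation: dict | None = None
    radius_fraction: float = 0.8
    n_samples: int = 720
    min_run_width: float | None = None  # None -> 3 angular samples
    ss_type: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulation")
        if sim and "group_sizes" in sim:
            sim["group_sizes"] = {
                (str(g), ag): int(n)
                for (g, ag, n) in (
                    (d["genotype"], d["age_weeks"], d["n_mice"])
                    for d in sim["group_sizes"]
                )
            }
        return cls(
            manifest=raw.get("manifest"),
            simulation=sim,
            radius_fraction=float(raw.get("radius_fraction", 0.8)),
            n_samples=int(raw.get("n_samples", 720)),
            min_run_width=raw.get("min_run_width"),
            ss_type=int(raw.get("ss_type", 3)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class CorneaStudyResult:
    """Bundle of tables produced by :func:`run_cornea_study`."""

    per_eye: pd.DataFrame
    per_mouse: pd.DataFrame
    group_summary: pd.DataFrame
    anova_p_hat: pd.DataFrame | None
    anova_n_corr: pd.DataFrame | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_eye.to_csv(out / "per_eye_stats.csv", index=False)
        self.per_mouse.to_csv(out / "per_mouse_summary.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        if self.anova_p_hat is not None:
            self.anova_p_hat.to_csv(out / "anova_percent_positive.csv")
        if self.anova_n_corr is not None:
            self.anova_n_corr.to_csv(out / "anova_corrected_stripe_number.csv")


@dataclass
class SurvivalResult:
    """The three breeding-ratio tests plus the heterozygote deficiency."""

    counts: GenotypeCounts
    het_vs_wt_females_1to1: GofResult
    males_vs_wt_females_2to1: GofResult
    males_vs_wt_females_1to1: GofResult
    het_deficiency_percent: float

    def to_dict(self) -> dict:
        return {
            "counts": dict(zip(self.counts.labels, self.counts.observed.tolist())),
            "het_vs_wt_females_1to1": asdict(self.het_vs_wt_females_1to1),
            "males_vs_wt_females_2to1": asdict(self.males_vs_wt_females_2to1),
            "males_vs_wt_females_1to1": asdict(self.males_vs_wt_females_1to1),
            "het_deficiency_percent": self.het_deficiency_percent,
        }


def load_image(path: str | Path) -> MosaicImage:
    """Read a TIFF or PNG stained-mosaic image from disk."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return MosaicImage(tifffile.imread(path))
    from PIL import Image

    return MosaicImage(np.asarray(Image.open(path)))


def _analyse_eye_image(image: MosaicImage, config: StudyConfig) -> StripeStats:
    center, radius = fit_corneal_circle(image, mode="auto")
    circle = SamplingCircle.at_fraction(
        center, radius, fraction=config.radius_fraction, n_samples=config.n_samples
    )
    profile = sample_circle(image, circle)
    runs = extract_runs(profile, min_run_width=config.min_run_width)
    return stripe_stats_from_runs(runs)


def _simulated_eye_stats(
    config: StudyConfig, sim: dict, rng: np.random.Generator
) -> StripeStats:
    ring = simulate_clone_ring(
        n_clones=int(sim.get("n_clones", 100)),
        p=float(sim.get("p", 0.5)),
        width_model=sim.get("width_model", "equal"),
        rng=rng,
    )
    if sim.get("render", False):
        cornea = render_cornea(
            ring,
            image_size=int(sim.get("image_size", 512)),
            noise_rate=float(sim.get("noise_rate", 0.0)),
            seed=int(rng.integers(2**31)),
        )
        return _analyse_eye_image(cornea.image, config)
    runs = runs_from_ring(ring)
    return stripe_stats_from_runs(runs)


def run_cornea_study(config: StudyConfig) -> CorneaStudyResult:
    """Run the full cornea analysis: per-eye stats, per-mouse means,
    group summaries (mean, SEM, n) and the two-way genotype x age ANOVA.

    Every output row carries the study seed and software version.  Mice with
    a single analysable eye are kept but flagged incomplete; eyes whose
    statistics are undefined are excluded from means with a warning.
    """
    if (config.manifest is None) == (config.simulation is None):
        raise ValueError("exactly one of manifest or simulation must be set")

    eye_rows: list[dict] = []
    per_eye_stats: dict[str, list[tuple[str, StripeStats]]] = {}
    meta: dict[str, tuple[str, float]] = {}

    if config.manifest is not None:
        manifest = pd.read_csv(config.manifest)
        required = {"mouse_id", "genotype", "age_weeks", "eye", "file"}
        if not required.issubset(manifest.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        base = Path(config.manifest).parent
        for rec in manifest.to_dict("records"):
            path = Path(rec["file"])
            if not path.is_absolute():
                path = base / path
            mid = str(rec["mouse_id"])
            meta[mid] = (str(rec["genotype"]), float(rec["age_weeks"]))
            if not path.exists():
                warnings.warn(f"missing eye image {path}; mouse {mid} incomplete",
                              stacklevel=2)
                continue
            stats = _analyse_eye_image(load_image(path), config)
            per_eye_stats.setdefault(mid, []).append((str(rec["eye"]), stats))
            eye_rows.append(_eye_row(rec, stats, config))
    else:
        sim = config.simulation
        rng = np.random.default_rng(config.seed)
        counter = 0
        for (genotype, age_weeks), n_mice in sim["group_sizes"].items():
            for _ in range(int(n_mice)):
                counter += 1
                mid = f"m{counter:03d}"
                meta[mid] = (str(genotype), float(age_weeks))
                for eye in ("L", "R"):
                    stats = _simulated_eye_stats(config, sim, rng)
                    rec = {"mouse_id": mid, "genotype": genotype,
                           "age_weeks": age_weeks, "eye": eye}
                    per_eye_stats.setdefault(mid, []).append((eye, stats))
                    eye_rows.append(_eye_row(rec, stats, config))

    per_eye = pd.DataFrame(eye_rows)
    mouse_rows = []
    for mid, eyes in per_eye_stats.items():
        genotype, age_weeks = meta[mid]
        summary = summarize_mouse(eyes, mid, genotype, age_weeks)
        row = asdict(summary)
        row.update(seed=config.seed, version=__version__)
        mouse_rows.append(row)
    per_mouse = pd.DataFrame(mouse_rows)

    grouped = per_mouse.groupby(["genotype", "age_weeks"], observed=True)
    group_summary = grouped.agg(
        n_mice=("mouse_id", "size"),
        p_hat_mean=("p_hat_mean", "mean"),
        p_hat_sem=("p_hat_mean", "sem"),
        n_corr_mean=("n_corr_mean", "mean"),
        n_corr_sem=("n_corr_mean", "sem"),
    ).reset_index()
    group_summary["seed"] = config.seed
    group_summary["version"] = __version__

    anova_p = anova_n = None
    if per_mouse["genotype"].nunique() >= 2 and per_mouse["age_weeks"].nunique() >= 2:
        anova_p = two_way_anova(
            per_mouse["p_hat_mean"], per_mouse["genotype"],
            per_mouse["age_weeks"], ss_type=config.ss_type,
            names=("genotype", "age"),
        )
        ok = per_mouse["n_corr_mean"].notna()
        anova_n = two_way_anova(
            per_mouse.loc[ok, "n_corr_mean"], per_mouse.loc[ok, "genotype"],
            per_mouse.loc[ok, "age_weeks"], ss_type=config.ss_type,
            names=("genotype", "age"),
        )
    return CorneaStudyResult(
        per_eye=per_eye,
        per_mouse=per_mouse,
        group_summary=group_summary,
        anova_p_hat=anova_p,
        anova_n_corr=anova_n,
    )


def _eye_row(rec: dict, stats: StripeStats, config: StudyConfig) -> dict:
    return {
        "mouse_id": str(rec["mouse_id"]),
        "genotype": str(rec["genotype"]),
        "age_weeks": float(rec["age_weeks"]),
        "eye": str(rec["eye"]),
        "p_hat": stats.p_hat,
        "n_pos_stripes": stats.n_pos_stripes,
        "w_obs": stats.w_obs,
        "w_corr": stats.w_corr,
        "n_corr": stats.n_corr,
        "seed": config.seed,
        "version": __version__,
    }


def run_survival_test(counts) -> SurvivalResult:
    """The breeding-ratio analysis of the heterozygous-female cross.

    ``counts`` is a :class:`GenotypeCounts` with classes
    ``(het_female, wt_female, male)`` or a plain length-3 sequence in that
    order.  Reproduces the three goodness-of-fit tests — heterozygous vs
    wild-type females against 1:1, males vs wild-type females against the
    2:1 expected if all males survived, and against 1:1 — plus the percent
    deficiency of heterozygous females.
    """
    if not isinstance(counts, GenotypeCounts):
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (3,):
            raise ValueError("counts must be (het_female, wt_female, male)")
        counts = GenotypeCounts(
            labels=("het_female", "wt_female", "male"), observed=arr
        )
    het_f, wt_f, males = counts.observed
    if min(het_f, wt_f, males) <= 0:
        raise ValueError("every class must have a positive count")
    return SurvivalResult(
        counts=counts,
        het_vs_wt_females_1to1=chi_square_gof([het_f, wt_f], [1, 1]),
        males_vs_wt_females_2to1=chi_square_gof([males, wt_f], [2, 1]),
        males_vs_wt_females_1to1=chi_square_gof([males, wt_f], [1, 1]),
        het_deficiency_percent=deficiency_percent(het_f, wt_f),
    )
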