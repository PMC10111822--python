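"""Synthetic pooled screens and patient cohorts with planted ground truth.

The screen generator emulates a pooled shRNA library taken through a
selective 3D outgrowth culture: day-0 hairpin proportions are drawn from a
symmetric Dirichlet (library representation skew), sequenced by multinomial
sampling; outgrowth multiplies each hairpin's cell clone by 2**e_g for its
gene's planted log2 effect after a binomial bottleneck of cells, and day 14
is sequenced the same way.  Library presets mirror a 903-gene kinome pool
and a 1526-gene cell-polarity pool with 2-4 hairpins per gene, 1.5e6 cells
at a multiplicity of infection < 0.5 (single integration per cell assumed).

The cohort generator emulates a breast-cancer tissue-microarray series:
receptor subtypes at the frequencies of the study cohort (ER+/HER2- 320,
ER+/HER2+ 27, ER-/HER2+ 29, ER-/HER2- 77), COMMD3 IHC categories per
subtype, duplicate cores whose intensity x area scores invert the category
bins, and exponential (optionally Weibull) survival calibrated by per-arm
10-year survival with administrative censoring at 20 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ihc import DEFAULT_IHC_BINS
from .screen import GeneCall, HairpinCounts, ScreenMatrix

__all__ = [
    "ScreenSimConfig",
    "CohortSimConfig",
    "GroundTruth",
    "RecoveryReport",
    "simulate_screen",
    "simulate_cohort",
    "evaluate_recovery",
]

LIBRARY_PRESETS = {"kinome": 903, "polarity": 1526}

SUBTYPE_COUNTS = {"ER+/HER2-": 320, "ER+/HER2+": 27, "ER-/HER2+": 29, "ER-/HER2-": 77}

# per-subtype IHC-category frequencies, taken from the cohort's printed
# category-by-subtype breakdown
CATEGORY_COUNTS_BY_SUBTYPE = {
    "ER+/HER2-": [133, 80, 52, 19, 36],
    "ER+/HER2+": [8, 6, 7, 3, 3],
    "ER-/HER2+": [9, 3, 10, 2, 5],
    "ER-/HER2-": [47, 18, 10, 2, 0],
}

GRADE_COUNTS = {"1": 61, "2": 232, "3": 164}
MITOTIC_COUNTS = {"1": 259, "2": 66, "3": 131}
TUBULE_COUNTS = {"T1/2": 113, "T3": 344}
STAGE_COUNTS = {"I": 28, "II": 104, "III": 14}
HISTOTYPE_COUNTS = {
    "IC (NST)": 273,
    "ILC & variants": 61,
    "mixed ducto-lob": 38,
    "mixed IC + special type": 35,
    "metaplastic": 16,
    "special types": 33,
}
AGE_UNDER50_FRAC = 307 / 439
COHORT_N = 457  # assessable tumours; per-parameter missingness relative to this
MISSING_FRAC = {"age": 1 - 439 / 457, "stage": 1 - 146 / 457, "mitotic": 1 - 456 / 457,
                "histotype": 1 - 456 / 457}
KI67_LOW_FRAC = {"ER+/HER2-": 268 / 297, "ER+/HER2+": 0.5, "ER-/HER2+": 0.5,
                 "ER-/HER2-": 14 / 73}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generative parameters for one pooled-screen simulation.

    ``hairpins_per_gene`` is an inclusive (lo, hi) range (or an int);
    ``planted_suppressors`` maps gene ids to log2 outgrowth effects e_g;
    ``representation_dispersion`` controls day-0 library skew (Dirichlet
    concentration = 1/dispersion; 0 means perfectly even representation);
    ``sequencing_depth`` is reads per timepoint (default 500x the number of
    hairpins); ``bottleneck_survival`` is the fraction of cell clones
    surviving the outgrowth bottleneck.
    """

    seed: int
    n_genes: int = 903
    hairpins_per_gene: int | tuple[int, int] = (2, 4)
    planted_suppressors: Mapping[str, float] = field(default_factory=dict)
    day0_cells: int = 1_500_000
    sequencing_depth: int | None = None
    representation_dispersion: float = 0.1
    bottleneck_survival: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 < self.bottleneck_survival <= 1:
            raise ValidationError(
                f"bottleneck_survival must be in (0,1], got {self.bottleneck_survival}"
            )
        if self.representation_dispersion < 0:
            raise ValidationError("representation_dispersion must be >= 0")
        if self.sequencing_depth is not None and self.sequencing_depth <= 0:
            raise ValidationError("sequencing_depth must be > 0")
        if self.day0_cells <= 0:
            raise ValidationError("day0_cells must be > 0")
        for g, e in self.planted_suppressors.items():
            if not math.isfinite(e):
                raise ValidationError(f"planted effect for {g} must be finite")

    @staticmethod
    def gene_id(i: int) -> str:
        return f"G{i + 1:04d}"

    @classmethod
    def preset(cls, name: str, seed: int, **overrides) -> "ScreenSimConfig":
        if name not in LIBRARY_PRESETS:
            raise ValidationError(f"unknown library preset {name!r}")
        return cls(seed=seed, n_genes=LIBRARY_PRESETS[name], **overrides)

    @classmethod
    def with_planted(
        cls, seed: int, n_genes: int, n_suppressors: int, log2_effect: float, **overrides
    ) -> "ScreenSimConfig":
        """Convenience: plant the first ``n_suppressors`` genes at one effect."""
        planted = {cls.gene_id(i): log2_effect for i in range(n_suppressors)}
        return cls(seed=seed, n_genes=n_genes, planted_suppressors=planted, **overrides)

    @classmethod
    def from_dict(cls, d: Mapping, seed: int | None = None) -> "ScreenSimConfig":
        d = dict(d)
        preset = d.pop("preset", None)
        if preset is not None:
            d.setdefault("n_genes", LIBRARY_PRESETS[preset])
        if seed is not None:
            d["seed"] = seed
        hpg = d.get("hairpins_per_gene")
        if isinstance(hpg, list):
            d["hairpins_per_gene"] = tuple(hpg)
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth emitted alongside a simulated dataset."""

    genes: tuple[str, ...] | None = None
    suppressor_effects: Mapping[str, float] | None = None
    arm_s10: Mapping[str, float] | None = None
    patient_arms: tuple[str, ...] | None = None
    patient_categories: tuple[int, ...] | None = None


def simulate_screen(config: ScreenSimConfig) -> tuple[ScreenMatrix, GroundTruth]:
    """Simulate day-0/day-14 hairpin counts with planted suppressor effects."""
    rng = np.random.default_rng(config.seed)
    genes = [config.gene_id(i) for i in range(config.n_genes)]
    unknown = set(config.planted_suppressors) - set(genes)
    if unknown:
        raise ValidationError(f"planted suppressors not in library: {sorted(unknown)}")

    hpg = config.hairpins_per_gene
    if isinstance(hpg, int):
        n_hp = np.full(config.n_genes, hpg, dtype=int)
    else:
        lo, hi = hpg
        if not 1 <= lo <= hi:
            raise ValidationError(f"invalid hairpins_per_gene range {hpg}")
        n_hp = rng.integers(lo, hi + 1, size=config.n_genes)

    gene_of = np.repeat(np.arange(config.n_genes), n_hp)
    H = gene_of.size
    depth = config.sequencing_depth if config.sequencing_depth is not None else 500 * H

    if config.representation_dispersion == 0:
        p0 = np.full(H, 1.0 / H)
    else:
        p0 = rng.dirichlet(np.full(H, 1.0 / config.representation_dispersion))

    c0 = rng.multinomial(depth, p0)

    cells = rng.multinomial(config.day0_cells, p0)
    if config.bottleneck_survival < 1.0:
        cells = rng.binomial(cells, config.bottleneck_survival)
    log2_eff = np.array(
        [config.planted_suppressors.get(genes[gi], 0.0) for gi in range(config.n_genes)]
    )
    w = cells * np.exp2(log2_eff[gene_of])
    total_w = w.sum()
    if total_w <= 0:
        raise ValidationError("bottleneck extinguished the whole library")
    c14 = rng.multinomial(depth, w / total_w)

    hp_index = np.concatenate([np.arange(k) for k in n_hp])
    records = tuple(
        HairpinCounts(
            hairpin_id=f"{genes[gi]}_h{j + 1}",
            gene_id=genes[gi],
            count_day0=int(a),
            count_day14=int(b),
        )
        for gi, j, a, b in zip(gene_of, hp_index, c0, c14)
    )
    truth = GroundTruth(genes=tuple(genes), suppressor_effects=dict(config.planted_suppressors))
    return ScreenMatrix(records), truth


@dataclass(frozen=True)
class RecoveryReport:
    precision: float | None
    recall: float | None
    tp: int
    fp: int
    fn: int
    tn: int
    tier_confusion: dict[int, dict[str, int]]


def evaluate_recovery(calls: Sequence[GeneCall], truth: GroundTruth) -> RecoveryReport:
    """Precision/recall of the hit calls against planted suppressors.

    ``precision`` is None when nothing was called; ``recall`` is None when
    nothing was planted.  ``tier_confusion[t]`` counts planted and unplanted
    genes whose enriched-hairpin count equals t.
    """
    if truth.genes is None or truth.suppressor_effects is None:
        raise ValidationError("ground truth does not describe a screen")
    call_genes = {c.gene_id for c in calls}
    if call_genes != set(truth.genes):
        raise ValidationError("gene universe of calls does not match ground truth")
    planted = set(truth.suppressor_effects)
    tp = sum(1 for c in calls if c.is_hit and c.gene_id in planted)
    fp = sum(1 for c in calls if c.is_hit and c.gene_id not in planted)
    fn = sum(1 for c in calls if not c.is_hit and c.gene_id in planted)
    tn = len(calls) - tp - fp - fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    confusion: dict[int, dict[str, int]] = {}
    for c in calls:
        d = confusion.setdefault(c.tier, {"planted": 0, "unplanted": 0})
        d["planted" if c.gene_id in planted else "unplanted"] += 1
    return RecoveryReport(precision, recall, tp, fp, fn, tn, confusion)


# ---------------------------------------------------------------------------
# Patient cohort


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters for a synthetic TMA cohort.

    Survival arms are defined by the tumour IHC category: COMMD3-positive
    means category >= ``positive_min_category``.  ``arm_s10`` gives each
    arm's planted 10-year survival probability; event times are Weibull
    (exponential at ``weibull_shape`` = 1) calibrated so S(10) equals the
    planted value.  Censoring is administrative at ``admin_censor_years``
    with an additional uniform early-censoring fraction.
    """

    seed: int
    n_patients: int = COHORT_N
    subtype_freqs: Mapping[str, float] | None = None
    category_dist: Mapping[str, Sequence[float]] | None = None
    arm_s10: Mapping[str, float] = field(
        default_factory=lambda: {"positive": 0.83, "negative": 0.73}
    )
    positive_min_category: int = 1
    admin_censor_years: float = 20.0
    early_censor_frac: float = 0.1
    weibull_shape: float = 1.0
    category_independent: bool = False
    luminal_a_only: bool = False
    forced_arm_sizes: tuple[int, int] | None = None  # (n positive, n negative)
    ihc_bins: tuple[float, ...] = DEFAULT_IHC_BINS

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for arm, s in self.arm_s10.items():
            if not 0 < s < 1:
                raise ValidationError(f"arm_s10[{arm!r}] must be in (0,1), got {s}")
        if not 0 <= self.early_censor_frac <= 1:
            raise ValidationError("early_censor_frac must be in [0,1]")
        if self.weibull_shape <= 0:
            raise ValidationError("weibull_shape must be > 0")
        if self.subtype_freqs is not None:
            tot = sum(self.subtype_freqs.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-6):
                raise ValidationError(f"subtype frequencies must sum to 1, got {tot}")

    @classmethod
    def table2_cohort(cls, seed: int, n_patients: int = COHORT_N, **overrides) -> "CohortSimConfig":
        return cls(seed=seed, n_patients=n_patients, **overrides)

    @classmethod
    def luminal_a_arms(cls, seed: int, n_positive: int, n_negative: int, **over) -> "CohortSimConfig":
        """Two luminal-A-like arms of fixed size (ER+/HER2-, Ki67-low)."""
        return cls(
            seed=seed,
            n_patients=n_positive + n_negative,
            luminal_a_only=True,
            forced_arm_sizes=(n_positive, n_negative),
            **over,
        )

    @classmethod
    def from_dict(cls, d: Mapping, seed: int | None = None) -> "CohortSimConfig":
        d = dict(d)
        preset = d.pop("preset", None)
        if preset is not None and preset != "table2-cohort":
            raise ValidationError(f"unknown cohort preset {preset!r}")
        if seed is not None:
            d["seed"] = seed
        if "forced_arm_sizes" in d and d["forced_arm_sizes"] is not None:
            d["forced_arm_sizes"] = tuple(d["forced_arm_sizes"])
        return cls(**d)


def _draw_level(rng, counts: Mapping[str, int]) -> str:
    labels = list(counts)
    p = np.array([counts[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _core_from_category(rng, cat: int, bins: Sequence[float]) -> tuple[int, float]:
    """Invert the category bins: an (intensity, area) pair scoring inside the bin."""
    if cat == 0:
        return 0, 0.0
    edges = [0.0, *bins]
    lo, hi = edges[cat - 1], edges[cat]
    raw = lo + (hi - lo) * rng.uniform(0.02, 0.98)
    i_min = max(1, math.ceil(raw / 100.0))
    intensity = int(rng.integers(i_min, 4))
    return intensity, raw / intensity


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a core-level cohort table plus planted per-patient truth.

    Returns one row per tumour-core (two cores per tumour) in the cohort
    CSV schema, and the ground truth (arm label and category per patient).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    if config.subtype_freqs is not None:
        sub_counts = {k: float(v) for k, v in config.subtype_freqs.items()}
    else:
        sub_counts = dict(SUBTYPE_COUNTS)
    cat_dist = {
        k: np.asarray(v, dtype=float) / np.sum(v)
        for k, v in (config.category_dist or CATEGORY_COUNTS_BY_SUBTYPE).items()
    }
    pooled = np.sum([CATEGORY_COUNTS_BY_SUBTYPE[k] for k in CATEGORY_COUNTS_BY_SUBTYPE], axis=0)
    pooled = pooled / pooled.sum()

    rows = []
    arms: list[str] = []
    cats: list[int] = []
    for i in range(n):
        tid = f"P{i + 1:05d}"
        if config.luminal_a_only:
            subtype = "ER+/HER2-"
        else:
            subtype = _draw_level(rng, sub_counts)
        er = "pos" if subtype.startswith("ER+") else "neg"
        her2 = "pos" if subtype.endswith("HER2+") else "neg"

        if config.forced_arm_sizes is not None:
            positive = i < config.forced_arm_sizes[0]
            base = cat_dist.get(subtype, pooled)
            if positive:
                p = base.copy()
                p[: config.positive_min_category] = 0.0
                p = p / p.sum()
                cat = int(rng.choice(5, p=p))
            else:
                cat = 0
        elif config.category_independent:
            cat = int(rng.choice(5, p=pooled))
        else:
            cat = int(rng.choice(5, p=cat_dist.get(subtype, pooled)))
        arm = "positive" if cat >= config.positive_min_category else "negative"

        if config.luminal_a_only:
            ki67 = float(rng.uniform(1.0, 19.5))
        else:
            low = rng.random() < KI67_LOW_FRAC.get(subtype, 0.5)
            ki67 = float(rng.uniform(1.0, 19.5)) if low else float(rng.uniform(20.5, 90.0))

        grade = _draw_level(rng, GRADE_COUNTS)
        mitotic = _draw_level(rng, MITOTIC_COUNTS) if rng.random() >= MISSING_FRAC["mitotic"] else ""
        tub = _draw_level(rng, TUBULE_COUNTS)
        tubule = {"T1/2": rng.integers(1, 3), "T3": 3}[tub]
        stage = _draw_level(rng, STAGE_COUNTS) if rng.random() >= MISSING_FRAC["stage"] else ""
        histotype = (
            _draw_level(rng, HISTOTYPE_COUNTS) if rng.random() >= MISSING_FRAC["histotype"] else ""
        )
        if rng.random() >= MISSING_FRAC["age"]:
            age = float(rng.uniform(28, 49.9)) if rng.random() < AGE_UNDER50_FRAC else float(
                rng.uniform(50, 88)
            )
        else:
            age = math.nan

        s10 = config.arm_s10[arm]
        k = config.weibull_shape
        scale = 10.0 / (-math.log(s10)) ** (1.0 / k)
        t_event = scale * rng.weibull(k)
        censor = config.admin_censor_years
        if rng.random() < config.early_censor_frac:
            censor = max(1e-3, rng.uniform(0, config.admin_censor_years))
        surv = min(t_event, censor)
        event = int(t_event <= censor)
        surv = max(surv, 1e-3)

        cat2 = int(rng.integers(0, cat + 1))
        for core_id, core_cat in ((1, cat), (2, cat2)):
            intensity, area = _core_from_category(rng, core_cat, config.ihc_bins)
            rows.append(
                {
                    "tumour_id": tid,
                    "core_id": core_id,
                    "intensity": intensity,
                    "area_pct": round(area, 4),
                    "er_status": er,
                    "her2_status": her2,
                    "ki67_pct": round(ki67, 2),
                    "grade": int(grade),
                    "mitotic_score": int(mitotic) if mitotic else math.nan,
                    "tubule_score": int(tubule),
                    "histotype": histotype,
                    "stage": stage,
                    "age_dx": round(age, 1) if not math.isnan(age) else math.nan,
                    "surv_years": round(surv, 6),
                    "event": event,
                }
            )
        arms.append(arm)
        cats.append(cat)

    truth = GroundTruth(
        arm_s10=dict(config.arm_s10),
        patient_arms=tuple(arms),
        patient_categories=tuple(cats),
    )
    return pd.DataFrame(rows), truth
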