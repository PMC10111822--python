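"""Contingency-table association analysis of tumour IHC categories.

Builds one labelled counts table per clinicopathological parameter
(parameter level x IHC category 0-4), computes row percentages the way a
pathology table prints them (half-up, one decimal), and tests independence
with the Pearson chi-square statistic.  A margins-fixed Monte-Carlo null
(equivalent to shuffling category labels) is available as a finite-sample
check on the asymptotic p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError
from .ihc import DEFAULT_IHC_BINS, aggregate_tumour, categorize_ihc, score_core

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square",
    "montecarlo_pvalue",
    "row_percentages",
    "score_cohort",
    "build_contingency",
    "association_suite",
    "AssociationBlock",
    "PARAMETERS",
    "ParameterRule",
    "CohortAssociationModel",
    "AssociationResults",
]

IHC_CATEGORIES: tuple[int, ...] = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of tumours by parameter level (rows) x IHC category (columns)."""

    parameter_name: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), non-negative ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"{self.parameter_name}: counts shape {arr.shape} does not match labels"
            )
        if (arr < 0).any():
            raise ValidationError(f"{self.parameter_name}: negative count in table")
        object.__setattr__(self, "counts", arr)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    small_expected_warning: bool


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def row_percentages(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-row percentage breakdown.

    Returns ``(rounded, exact)`` where ``rounded`` is half-up to one decimal
    (display convention) and ``exact`` is the unrounded value.
    """
    totals = table.row_totals
    for label, t in zip(table.row_labels, totals):
        if t == 0:
            raise ValidationError(f"{table.parameter_name}: row {label!r} has zero total")
    exact = 100.0 * table.counts / totals[:, None]
    rounded = np.vectorize(_round_half_up)(exact)
    return rounded, exact


def _prune(table: ContingencyTable) -> ContingencyTable:
    keep_r = table.counts.sum(axis=1) > 0
    keep_c = table.counts.sum(axis=0) > 0
    return ContingencyTable(
        table.parameter_name,
        tuple(l for l, k in zip(table.row_labels, keep_r) if k),
        tuple(l for l, k in zip(table.col_labels, keep_c) if k),
        table.counts[np.ix_(keep_r, keep_c)],
    )


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction).

    All-zero rows/columns are dropped before testing.  The p-value is the
    upper tail of the chi-square distribution, Q(df/2, chi2/2).  When more
    than 20% of expected counts fall below 5 the asymptotic p is unreliable
    and ``small_expected_warning`` is set.
    """
    t = _prune(table)
    obs = t.counts.astype(float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError(
            f"{table.parameter_name}: need at least a 2x2 table after pruning, got {obs.shape}"
        )
    n = obs.sum()
    expected = np.outer(t.row_totals, t.col_totals) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(special.chdtrc(dof, chi2))  # regularized upper incomplete gamma
    warn = bool((expected < 5).mean() > 0.20)
    return ChiSquareResult(chi2, dof, p, expected, warn)


def montecarlo_pvalue(
    table: ContingencyTable,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo p-value under the margins-fixed null.

    Samples ``n_shuffles`` tables with the observed margins (Patefield
    algorithm), which is the distribution obtained by shuffling category
    labels against parameter levels.  Returns ``(p, mc_standard_error)``
    with the usual add-one estimator.
    """
    t = _prune(table)
    obs = chi_square(t).statistic
    n = t.grand_total
    expected = np.outer(t.row_totals, t.col_totals) / n
    sampler = stats.random_table(t.row_totals, t.col_totals)
    sim = sampler.rvs(n_shuffles, random_state=rng)
    chi2_sim = ((sim - expected) ** 2 / expected).sum(axis=(-2, -1))
    hits = int((chi2_sim >= obs - 1e-9).sum())
    p = (hits + 1) / (n_shuffles + 1)
    se = float(np.sqrt(p * (1 - p) / n_shuffles))
    return float(p), se


# ---------------------------------------------------------------------------
# Cohort scoring and parameter definitions


def score_cohort(cores: pd.DataFrame, bins: Sequence[float] = DEFAULT_IHC_BINS) -> pd.DataFrame:
    """Collapse a core-level table (one row per tumour-core) to tumour level.

    Each core is scored as intensity x area, binned, and the tumour takes the
    maximum category over its cores.  Clinical covariates are taken from the
    first core row of each tumour; a ``ki67_low`` flag (staining in <= 20% of
    tumour cells) is derived when ``ki67_pct`` is present.
    """
    required = {"tumour_id", "intensity", "area_pct"}
    missing = required - set(cores.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if len(cores) == 0:
        raise ValidationError("empty cohort table")

    raw = [score_core(int(i), float(a)) for i, a in zip(cores["intensity"], cores["area_pct"])]
    cats = [categorize_ihc(s, bins) for s in raw]
    work = cores.assign(_raw=raw, _cat=cats)

    clinical = [
        c
        for c in cores.columns
        if c not in {"core_id", "intensity", "area_pct"}
    ]
    rows = []
    for tid, grp in work.groupby("tumour_id", sort=True):
        rec = {c: grp.iloc[0][c] for c in clinical}
        rec["tumour_id"] = tid
        rec["raw_score"] = float(grp["_raw"].max())
        rec["category"] = aggregate_tumour(grp["_cat"].tolist())
        rows.append(rec)
    out = pd.DataFrame(rows)
    if "ki67_pct" in out.columns:
        out["ki67_low"] = out["ki67_pct"].astype(float) <= 20.0
    return out


def _pos(v) -> bool | None:
    if pd.isna(v):
        return None
    s = str(v).strip().lower()
    if s in {"pos", "positive", "+", "1", "true"}:
        return True
    if s in {"neg", "negative", "-", "0", "false"}:
        return False
    raise ValidationError(f"unrecognised receptor status {v!r}")


@dataclass(frozen=True)
class ParameterRule:
    """How to assign a tumour to a level of one clinicopathological parameter.

    ``assign`` returns the level label, or ``None`` when the tumour is not
    assessable for this parameter (missing data, or outside the stratum the
    block is restricted to) — such tumours are dropped from the block.
    """

    name: str
    label: str
    assign: Callable[[pd.Series], str | None]
    level_order: tuple[str, ...] | None = None


def _age_rule(row: pd.Series) -> str | None:
    if pd.isna(row.get("age_dx")):
        return None
    return "< 50 years" if float(row["age_dx"]) < 50 else ">= 50 years"


def _stage_rule(row: pd.Series) -> str | None:
    v = row.get("stage")
    if pd.isna(v) or str(v).strip() == "":
        return None
    s = str(v).strip().upper()
    return s if s in {"I", "II", "III"} else None


def _ordinal_rule(col: str):
    def rule(row: pd.Series) -> str | None:
        v = row.get(col)
        if pd.isna(v):
            return None
        return str(int(v))

    return rule


def _tubule_rule(row: pd.Series) -> str | None:
    v = row.get("tubule_score")
    if pd.isna(v):
        return None
    return "T1/2" if int(v) in (1, 2) else "T3"


def _erher2_rule(er_positive: bool):
    def rule(row: pd.Series) -> str | None:
        er, her2 = _pos(row.get("er_status")), _pos(row.get("her2_status"))
        if er is None or her2 is None or er is not er_positive:
            return None
        e = "ER+" if er else "ER-"
        h = "HER2+" if her2 else "HER2-"
        return f"{e}/{h}"

    return rule


def _histotype_rule(row: pd.Series) -> str | None:
    v = row.get("histotype")
    if pd.isna(v) or str(v).strip() == "":
        return None
    return str(v)


def _prognostic_rule(row: pd.Series) -> str | None:
    er, her2 = _pos(row.get("er_status")), _pos(row.get("her2_status"))
    ki67 = row.get("ki67_pct")
    if er is None or her2 is None or pd.isna(ki67):
        return None
    low = float(ki67) <= 20.0
    if her2:
        return "HER2+"
    if er:
        return "ER+ (Ki67-low)" if low else "ER+ (Ki67-high)"
    # triple negative; basal-like proxied by high proliferative index
    return "TN (non-basal)" if low else "TN (basal-like)"


PARAMETERS: dict[str, ParameterRule] = {
    "age": ParameterRule("age", "Age at diagnosis", _age_rule, ("< 50 years", ">= 50 years")),
    "stage": ParameterRule("stage", "Stage", _stage_rule, ("I", "II", "III")),
    "grade": ParameterRule("grade", "Grade", _ordinal_rule("grade"), ("1", "2", "3")),
    "mitotic": ParameterRule(
        "mitotic", "Mitotic score", _ordinal_rule("mitotic_score"), ("1", "2", "3")
    ),
    "tubule": ParameterRule("tubule", "Tubule score", _tubule_rule, ("T1/2", "T3")),
    "erher2_erneg": ParameterRule(
        "erher2_erneg", "ER/HER2 subtype (ER-)", _erher2_rule(False), ("ER-/HER2-", "ER-/HER2+")
    ),
    "erher2_erpos": ParameterRule(
        "erher2_erpos", "ER/HER2 subtype (ER+)", _erher2_rule(True), ("ER+/HER2-", "ER+/HER2+")
    ),
    "histotype": ParameterRule("histotype", "Histological type", _histotype_rule, None),
    "prognostic": ParameterRule(
        "prognostic",
        "Prognostic subgroups",
        _prognostic_rule,
        ("HER2+", "ER+ (Ki67-low)", "ER+ (Ki67-high)", "TN (basal-like)", "TN (non-basal)"),
    ),
}


def build_contingency(
    tumours: pd.DataFrame,
    parameter: str | ParameterRule,
    category_col: str = "category",
) -> ContingencyTable:
    """Cross-tabulate tumours: parameter level x IHC category 0-4.

    Tumours whose level is unassessable are dropped (their number is noted on
    the logger); levels with no tumours are omitted.
    """
    rule = PARAMETERS[parameter] if isinstance(parameter, str) else parameter
    levels: list[str] = []
    assigned: list[tuple[str, int]] = []
    n_dropped = 0
    for _, row in tumours.iterrows():
        lvl = rule.assign(row)
        if lvl is None:
            n_dropped += 1
            continue
        assigned.append((lvl, int(row[category_col])))
        if lvl not in levels:
            levels.append(lvl)
    if not assigned:
        raise ValidationError(f"{rule.name}: no assessable tumours")
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "%s: dropped %d tumours with missing level", rule.name, n_dropped
        )
    if rule.level_order is not None:
        order = [l for l in rule.level_order if l in levels]
        order += sorted(set(levels) - set(order))
    else:
        order = sorted(levels)
    idx = {l: i for i, l in enumerate(order)}
    counts = np.zeros((len(order), len(IHC_CATEGORIES)), dtype=int)
    for lvl, cat in assigned:
        counts[idx[lvl], cat] += 1
    return ContingencyTable(
        rule.name, tuple(order), tuple(str(c) for c in IHC_CATEGORIES), counts
    )


@dataclass
class AssociationBlock:
    """One parameter's contingency table, percentages and test result."""

    parameter: str
    table: ContingencyTable | None = None
    percentages: np.ndarray | None = None
    chi2: ChiSquareResult | None = None
    error: str | None = None


def association_suite(
    tumours: pd.DataFrame,
    parameters: Iterable[str | ParameterRule],
    category_col: str = "category",
) -> list[AssociationBlock]:
    """Run ``build_contingency`` + percentages + chi-square per parameter.

    Errors in one block are recorded on the block and do not abort the rest.
    """
    params = list(parameters)
    if not params:
        raise ValidationError("parameter list is empty")
    blocks: list[AssociationBlock] = []
    for p in params:
        name = p if isinstance(p, str) else p.name
        block = AssociationBlock(parameter=name)
        try:
            block.table = build_contingency(tumours, p, category_col)
            block.percentages = row_percentages(block.table)[0]
            block.chi2 = chi_square(block.table)
        except ValidationError as exc:
            block.error = str(exc)
        blocks.append(block)
    return blocks


class CohortAssociationModel:
    """Association of tumour IHC category with clinicopathological parameters.

    Built either from a core-level table (``from_cores``; cores are scored
    and aggregated first) or from an already-scored tumour-level table with a
    ``category`` column.
    """

    def __init__(self, tumours: pd.DataFrame):
        if "category" not in tumours.columns:
            raise ValidationError("tumour table must carry a 'category' column")
        self.tumours = tumours

    @classmethod
    def from_cores(
        cls, cores: pd.DataFrame, bins: Sequence[float] = DEFAULT_IHC_BINS
    ) -> "CohortAssociationModel":
        return cls(score_cohort(cores, bins))

    def fit(self, parameters: Iterable[str | ParameterRule] | None = None) -> "AssociationResults":
        params = list(parameters) if parameters is not None else list(PARAMETERS)
        return AssociationResults(self, association_suite(self.tumours, params))


class AssociationResults:
    def __init__(self, model: CohortAssociationModel, blocks: list[AssociationBlock]):
        self.model = model
        self.blocks = blocks

    def block(self, name: str) -> AssociationBlock:
        for b in self.blocks:
            if b.parameter == name:
                return b
        raise KeyError(name)

    def summary(self) -> str:
        lines = ["IHC-category association results", "=" * 60]
        for b in self.blocks:
            if b.error is not None:
                lines.append(f"[{b.parameter}] ERROR: {b.error}")
                continue
            t, c = b.table, b.chi2
            lines.append(
                f"[{b.parameter}] N={t.grand_total}  chi2={c.statistic:.4f} "
                f"df={c.df}  p={c.p_value:.3g}"
                + ("  (small expected counts)" if c.small_expected_warning else "")
            )
            for i, lbl in enumerate(t.row_labels):
                cells = "  ".join(
                    f"{n:>4d} ({p:5.1f}%)" for n, p in zip(t.counts[i], b.percentages[i])
                )
                lines.append(f"    {lbl:<18} {cells}")
        return "\n".join(lines)
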