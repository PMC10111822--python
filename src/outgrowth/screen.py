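"""Pooled shRNA outgrowth-screen enrichment scoring and gene-level hit calling.

A pooled screen compares the abundance of each short-hairpin construct before
(day 0) and after (day 14) a selective 3D outgrowth culture.  Hairpins whose
target gene suppresses outgrowth become over-represented.  The per-hairpin
statistic is the enrichment ratio

    R_h = (c_h^14 / T^14) / (c_h^0 / T^0)

i.e. the relative abundance at day 14 divided by the relative abundance at
day 0, where T^t is the total read count over *all* hairpins at timepoint t.
A gene is called a hit when at least ``min_enriched`` (default 2) of its
hairpins exceed a fold threshold (default: ratio strictly greater than 2).
Genes are then tiered by how many of their hairpins cleared the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "HairpinCounts",
    "ScreenMatrix",
    "EnrichmentRecord",
    "GeneCall",
    "compute_enrichment",
    "call_gene_hits",
    "tier_genes",
    "ScreenEnrichmentModel",
    "ScreenResults",
]

#: hairpins with fewer day-0 reads than this are flagged low-confidence
DEFAULT_MIN_DAY0_COUNT = 10
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_MIN_ENRICHED = 2


@dataclass(frozen=True)
class HairpinCounts:
    """Read counts for one hairpin at the two screen timepoints."""

    hairpin_id: str
    gene_id: str
    count_day0: int
    count_day14: int

    def __post_init__(self) -> None:
        for name in ("count_day0", "count_day14"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(
                    f"hairpin {self.hairpin_id!r}: {name} must be an integer, got {v!r}"
                )
            if v < 0:
                raise ValidationError(
                    f"hairpin {self.hairpin_id!r}: {name} must be >= 0, got {v}"
                )


@dataclass(frozen=True)
class ScreenMatrix:
    """All hairpins of one screen plus the timepoint column totals."""

    records: tuple[HairpinCounts, ...]
    total_day0: int = field(init=False)
    total_day14: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("no hairpins: a screen must contain at least one record")
        ids = [r.hairpin_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(h for h in ids if ids.count(h) > 1)
            raise ValidationError(f"duplicate hairpin_id {dup!r} in screen")
        object.__setattr__(self, "total_day0", int(sum(r.count_day0 for r in self.records)))
        object.__setattr__(self, "total_day14", int(sum(r.count_day14 for r in self.records)))
        if self.total_day0 <= 0:
            raise ValidationError("total day-0 count must be positive")
        if self.total_day14 <= 0:
            raise ValidationError("total day-14 count must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> set[str]:
        return {r.gene_id for r in self.records}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScreenMatrix":
        required = ["hairpin_id", "gene_id", "count_day0", "count_day14"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {', '.join(missing)}")
        recs = tuple(
            HairpinCounts(str(r.hairpin_id), str(r.gene_id), int(r.count_day0), int(r.count_day14))
            for r in df.itertuples(index=False)
        )
        return cls(recs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hairpin_id": [r.hairpin_id for r in self.records],
                "gene_id": [r.gene_id for r in self.records],
                "count_day0": [r.count_day0 for r in self.records],
                "count_day14": [r.count_day14 for r in self.records],
            }
        )


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-hairpin relative abundances and enrichment ratio.

    ``ratio`` is ``+inf`` when the hairpin is absent at day 0 but present at
    day 14, and ``nan`` when absent at both timepoints (never counted as
    enriched).  ``low_confidence`` marks hairpins whose day-0 representation
    is too thin (below ``min_day0_count`` reads) for the ratio to be stable.
    """

    hairpin_id: str
    gene_id: str
    rel_day0: float
    rel_day14: float
    ratio: float
    log2_ratio: float
    low_confidence: bool


@dataclass(frozen=True)
class GeneCall:
    """Hit decision for one gene."""

    gene_id: str
    n_hairpins_total: int
    n_enriched: int
    is_hit: bool
    tier: int
    insufficient_hairpins: bool


def compute_enrichment(
    screen: ScreenMatrix,
    pseudocount: float = 0.0,
    min_day0_count: int = DEFAULT_MIN_DAY0_COUNT,
) -> list[EnrichmentRecord]:
    """Score every hairpin of a screen.

    With ``pseudocount`` p the relative abundance at timepoint t is
    ``(c_h^t + p) / (T^t + p * n_hairpins)`` so abundances still sum to one.
    The default p = 0 reproduces the plain ratio formula exactly.
    """
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    n = len(screen)
    c0 = np.array([r.count_day0 for r in screen.records], dtype=float)
    c14 = np.array([r.count_day14 for r in screen.records], dtype=float)
    rel0 = (c0 + pseudocount) / (screen.total_day0 + pseudocount * n)
    rel14 = (c14 + pseudocount) / (screen.total_day14 + pseudocount * n)

    out: list[EnrichmentRecord] = []
    for rec, r0, r14 in zip(screen.records, rel0, rel14):
        if r0 > 0:
            ratio = r14 / r0
        elif r14 > 0:
            ratio = math.inf
        else:
            ratio = math.nan
        if ratio > 0:
            log2_ratio = math.log2(ratio) if math.isfinite(ratio) else math.inf
        elif ratio == 0:
            log2_ratio = -math.inf
        else:
            log2_ratio = math.nan
        low_conf = rec.count_day0 < min_day0_count
        out.append(
            EnrichmentRecord(
                hairpin_id=rec.hairpin_id,
                gene_id=rec.gene_id,
                rel_day0=float(r0),
                rel_day14=float(r14),
                ratio=float(ratio),
                log2_ratio=float(log2_ratio),
                low_confidence=bool(low_conf),
            )
        )
    return out


def call_gene_hits(
    records: Iterable[EnrichmentRecord],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_enriched: int = DEFAULT_MIN_ENRICHED,
    exclude_low_confidence: bool = False,
    library: Mapping[str, int] | Iterable[str] | None = None,
) -> list[GeneCall]:
    """Call hits: a gene with ``min_enriched`` or more hairpins whose ratio is
    strictly greater than ``fold_threshold``.

    ``library``, when given, is the set of annotated genes (optionally mapped
    to their library hairpin counts); records for genes outside it raise
    :class:`ValidationError`.  Genes carrying a single hairpin can never
    satisfy a two-hairpin rule and are flagged ``insufficient_hairpins``.
    """
    if fold_threshold <= 0:
        raise ValidationError(f"fold_threshold must be > 0, got {fold_threshold}")
    if min_enriched < 1:
        raise ValidationError(f"min_enriched must be >= 1, got {min_enriched}")

    known: set[str] | None = None
    if library is not None:
        known = set(library)

    per_gene: dict[str, list[EnrichmentRecord]] = {}
    for rec in records:
        if known is not None and rec.gene_id not in known:
            raise ValidationError(f"gene {rec.gene_id!r} not present in library annotation")
        per_gene.setdefault(rec.gene_id, []).append(rec)

    calls: list[GeneCall] = []
    for gene in sorted(per_gene):
        recs = per_gene[gene]
        usable = [r for r in recs if not (exclude_low_confidence and r.low_confidence)]
        n_enr = sum(1 for r in usable if r.ratio > fold_threshold)
        n_total = len(recs)
        insufficient = n_total < 2
        is_hit = (n_enr >= min_enriched) and not (insufficient and min_enriched >= 2)
        calls.append(
            GeneCall(
                gene_id=gene,
                n_hairpins_total=n_total,
                n_enriched=n_enr,
                is_hit=is_hit,
                tier=n_enr,
                insufficient_hairpins=insufficient,
            )
        )
    return calls


def tier_genes(
    calls: Sequence[GeneCall], min_enriched: int = DEFAULT_MIN_ENRICHED
) -> dict[int, list[str]]:
    """Group genes by enriched-hairpin count, highest tier first.

    Only genes reaching ``min_enriched`` appear; genes are alphabetical
    within a tier and empty tiers are omitted.
    """
    if len(calls) == 0:
        raise ValidationError("tier_genes requires at least one gene call")
    tiers: dict[int, list[str]] = {}
    for c in calls:
        if c.n_enriched >= min_enriched:
            tiers.setdefault(c.n_enriched, []).append(c.gene_id)
    return {t: sorted(tiers[t]) for t in sorted(tiers, reverse=True)}


class ScreenEnrichmentModel:
    """Enrichment analysis of one pooled screen, statsmodels-style.

    Parameters
    ----------
    screen
        A :class:`ScreenMatrix` (use :meth:`from_dataframe` for tabular input).
    pseudocount
        Added to every count before forming relative abundances; default 0.
    min_day0_count
        Day-0 read floor below which a hairpin is flagged low-confidence.
    """

    def __init__(
        self,
        screen: ScreenMatrix,
        pseudocount: float = 0.0,
        min_day0_count: int = DEFAULT_MIN_DAY0_COUNT,
    ):
        self.screen = screen
        self.pseudocount = pseudocount
        self.min_day0_count = min_day0_count

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ScreenEnrichmentModel":
        return cls(ScreenMatrix.from_dataframe(df), **kwargs)

    def fit(
        self,
        fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
        min_enriched: int = DEFAULT_MIN_ENRICHED,
        exclude_low_confidence: bool = False,
    ) -> "ScreenResults":
        records = compute_enrichment(self.screen, self.pseudocount, self.min_day0_count)
        calls = call_gene_hits(
            records,
            fold_threshold=fold_threshold,
            min_enriched=min_enriched,
            exclude_low_confidence=exclude_low_confidence,
        )
        return ScreenResults(self, records, calls, fold_threshold, min_enriched)


class ScreenResults:
    """Fitted screen results: per-hairpin ratios, gene calls and tiers."""

    def __init__(
        self,
        model: ScreenEnrichmentModel,
        records: list[EnrichmentRecord],
        calls: list[GeneCall],
        fold_threshold: float,
        min_enriched: int,
    ):
        self.model = model
        self.records = records
        self.calls = calls
        self.fold_threshold = fold_threshold
        self.min_enriched = min_enriched

    @property
    def enrichment(self) -> pd.DataFrame:
        """One row per hairpin, sorted by descending ratio then gene symbol."""
        df = pd.DataFrame([r.__dict__ for r in self.records])
        return df.sort_values(
            ["ratio", "gene_id", "hairpin_id"], ascending=[False, True, True]
        ).reset_index(drop=True)

    @property
    def gene_calls(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.calls])

    @property
    def hits(self) -> list[str]:
        return sorted(c.gene_id for c in self.calls if c.is_hit)

    def tiers(self) -> dict[int, list[str]]:
        return tier_genes(self.calls, self.min_enriched)

    def summary(self) -> str:
        n_hp = len(self.records)
        n_genes = len(self.calls)
        lines = [
            "Pooled-screen enrichment results",
            "=" * 40,
            f"hairpins scored      {n_hp}",
            f"genes                {n_genes}",
            f"fold threshold       > {self.fold_threshold:g}",
            f"min enriched hairpins{self.min_enriched:>3}",
            f"genes called hit     {len(self.hits)}",
            "",
            "tier (n enriched hairpins): genes",
        ]
        for tier, genes in self.tiers().items():
            lines.append(f"  {tier}: {', '.join(genes)}")
        return "\n".join(lines)
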