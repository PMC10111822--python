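"""Immunohistochemistry (IHC) scoring for tissue-microarray cores.

Each tumour is sampled in duplicate cores; each core receives a staining
intensity I in 0..3 and a stained-area percentage A in 0..100.  The raw core
score is the H-score-style product s = I x A (0..300), binned into five
ordinal categories (0 = negative through 4 = strongest), and a tumour's
category is the maximum over its assessable cores.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "DEFAULT_IHC_BINS",
    "score_core",
    "categorize_ihc",
    "aggregate_tumour",
]

#: upper edges of the positive bins: (0,50] -> 1, (50,100] -> 2,
#: (100,200] -> 3, (200,300] -> 4; a raw score of exactly 0 is category 0.
DEFAULT_IHC_BINS: tuple[float, ...] = (50.0, 100.0, 200.0, 300.0)


def score_core(intensity: int, area_pct: float) -> float:
    """Raw core score = intensity x stained area (range 0-300)."""
    if not 0 <= intensity <= 3:
        raise ValidationError(f"intensity must be in 0..3, got {intensity}")
    if not 0.0 <= area_pct <= 100.0:
        raise ValidationError(f"area_pct must be in 0..100, got {area_pct}")
    return float(intensity) * float(area_pct)


def categorize_ihc(raw: float, bins: Sequence[float] = DEFAULT_IHC_BINS) -> int:
    """Map a raw score to an ordinal category.

    Category 0 iff ``raw == 0``; otherwise 1 + index of the half-open bin
    ``(edge_{k-1}, edge_k]`` containing ``raw``.  ``bins`` lists the upper
    edges, strictly increasing, ending at the score maximum (300 by default).
    """
    edges = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValidationError(f"bin edges must be positive and strictly increasing: {edges}")
    if not 0.0 <= raw <= edges[-1]:
        raise ValidationError(f"raw score {raw} outside [0, {edges[-1]}]")
    if raw == 0:
        return 0
    return bisect_left(edges, raw) + 1


def aggregate_tumour(core_categories: Sequence[int]) -> int:
    """Tumour category = maximum category over its cores."""
    cats = list(core_categories)
    if not cats:
        raise ValidationError("no assessable cores for tumour")
    for c in cats:
        if not 0 <= int(c) <= 4:
            raise ValidationError(f"core category must be in 0..4, got {c}")
    return int(max(cats))
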