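"""Packaged fixtures: the published TMA association table as labelled counts."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..association import ContingencyTable
from ..errors import FixtureError

__all__ = ["load_table3_fixture", "table3_printed_p", "TABLE3_BLOCKS"]

#: block keys in printed order; the ER/HER2 parameter is printed as two
#: separately totalled strata, so 8 parameters yield 9 tables
TABLE3_BLOCKS = (
    "age",
    "stage",
    "grade",
    "mitotic",
    "tubule",
    "erher2_erneg",
    "erher2_erpos",
    "histotype",
    "prognostic",
)

_CAT_COLS = ["cat0", "cat1", "cat2", "cat3", "cat4"]


def _read_fixture() -> pd.DataFrame:
    ref = resources.files(__package__) / "tma_table3.tsv"
    try:
        with ref.open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh, sep="\t", comment="#")
    except FileNotFoundError as exc:  # pragma: no cover
        raise FixtureError("packaged fixture tma_table3.tsv is missing") from exc


def load_table3_fixture() -> dict[str, ContingencyTable]:
    """Load the published association table as :class:`ContingencyTable` objects.

    Each block's column sums are checked against the printed total row; a
    mismatch means the transcription was corrupted and raises
    :class:`FixtureError`.
    """
    df = _read_fixture()
    tables: dict[str, ContingencyTable] = {}
    for block in TABLE3_BLOCKS:
        sub = df[df["block"] == block]
        if sub.empty:
            raise FixtureError(f"fixture block {block!r} missing")
        body = sub[sub["level"] != "(total)"]
        total = sub[sub["level"] == "(total)"]
        if len(total) != 1:
            raise FixtureError(f"fixture block {block!r} must have exactly one total row")
        counts = body[_CAT_COLS].to_numpy(dtype=int)
        printed_totals = total[_CAT_COLS].to_numpy(dtype=int)[0]
        if not np.array_equal(counts.sum(axis=0), printed_totals):
            raise FixtureError(
                f"fixture block {block!r}: column sums {counts.sum(axis=0).tolist()} "
                f"do not match printed totals {printed_totals.tolist()}"
            )
        tables[block] = ContingencyTable(
            parameter_name=str(body["parameter"].iloc[0]),
            row_labels=tuple(body["level"].astype(str)),
            col_labels=("0", "1", "2", "3", "4"),
            counts=counts,
        )
    return tables


def table3_printed_p() -> dict[str, str]:
    """The p-value string printed for each block ("ns" = not significant)."""
    df = _read_fixture()
    return {
        block: str(df.loc[df["block"] == block, "printed_p"].iloc[0])
        for block in TABLE3_BLOCKS
    }
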