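"""Readers and writers for the pipeline's tab-separated dialects.

All tables are UTF-8, tab-delimited, ``.`` decimal separator, no quoting;
``inf``/``nan`` literals serialize the sentinel values.  Reals are written
with 12 significant digits so write-then-read round-trips are lossless to
that precision; integers round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import ParseError, ValidationError
from .screen import HairpinCounts, ScreenMatrix

__all__ = [
    "read_screen_counts",
    "read_cohort_table",
    "read_survival_table",
    "read_measurements_table",
    "write_table",
    "write_results",
]

log = logging.getLogger(__name__)

SCREEN_HEADER = ["hairpin_id", "gene_id", "count_day0", "count_day14"]
FLOAT_FORMAT = "%.12g"


def read_screen_counts(path: str | Path) -> ScreenMatrix:
    """Parse a hairpin count table (see ``SCREEN_HEADER``) into a ScreenMatrix.

    Raises :class:`ParseError` with the offending line number for missing
    columns, non-integer or negative counts, and duplicate hairpin ids.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[: len(SCREEN_HEADER)] != SCREEN_HEADER:
        raise ParseError(
            f"{path}:1: expected header {'	'.join(SCREEN_HEADER)!r}, got {lines[0]!r}"
        )
    records: list[HairpinCounts] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        hid, gene, c0s, c14s = fields[:4]
        try:
            c0, c14 = int(c0s), int(c14s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: counts must be integers, got {c0s!r}/{c14s!r}")
        if c0 < 0 or c14 < 0:
            raise ParseError(f"{path}:{lineno}: negative count for hairpin {hid!r}")
        if hid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate hairpin_id {hid!r}")
        seen.add(hid)
        records.append(HairpinCounts(hid, gene, c0, c14))
    if not records:
        raise ParseError(f"{path}: no hairpin rows")
    screen = ScreenMatrix(tuple(records))
    log.info(
        "%s: %d hairpins, T0=%d, T14=%d", path.name, len(screen), screen.total_day0,
        screen.total_day14,
    )
    return screen


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a core-level cohort table (CSV or TSV by extension).

    Rows whose intensity/area cannot be typed are skipped (a summary count is
    logged).  Adds a ``ki67_low`` flag: Ki67 staining in <= 20% of tumour
    cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise ParseError(f"{path}: empty cohort table")
    n0 = len(df)
    for col in ("intensity", "area_pct"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["intensity", "area_pct"]].isna().any(axis=1) if {
        "intensity",
        "area_pct",
    } <= set(df.columns) else pd.Series(False, index=df.index)
    if bad.any():
        log.warning("%s: skipped %d unparseable rows", path.name, int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ParseError(f"{path}: no parseable rows")
    if "ki67_pct" in df.columns:
        df = df.assign(ki67_low=pd.to_numeric(df["ki67_pct"], errors="coerce") <= 20.0)
    return df.reset_index(drop=True)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table with columns time, event (0/1), group."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: empty survival table")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = df["event"].astype(int).astype(bool)
    if (df["time"] <= 0).any():
        raise ValidationError(f"{path}: survival times must be > 0")
    return df


def read_measurements_table(path: str | Path) -> pd.DataFrame:
    """Read caliper measurements: animal_id, day, b_mm, s_mm."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = {"animal_id", "day", "b_mm", "s_mm"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write one TSV with the package's dialect (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
        na_rep="nan",
        lineterminator="\n",
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write each table as ``<name>.tsv`` + ``<name>.json`` plus a manifest.

    The manifest records the run configuration, its hash, the seed and
    library versions; reruns with identical inputs produce byte-identical
    table files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc
    manifest: dict = {"files": [], "seed": seed, "versions": _versions()}
    if config is not None:
        cfg = json.loads(json.dumps(config, default=_jsonable, sort_keys=True))
        manifest["config"] = cfg
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    for name in sorted(tables):
        df = tables[name]
        tsv = out / f"{name}.tsv"
        write_table(df, tsv)
        js = out / f"{name}.json"
        with js.open("w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, default=_jsonable, indent=1)
            fh.write("\n")
        manifest["files"] += [tsv.name, js.name]
    with (out / "run_manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)
        fh.write("\n")
    return manifest


def _versions() -> dict[str, str]:
    import scipy

    return {
        "outgrowth": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
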