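"""File formats, run configuration and logging for the labeling pipeline.

The on-disk isotopologue dialect is a tidy TSV with one row per isotopologue
per sample::

    metabolite  i  c  condition  biological_replicate  technical_replicate  time_min  ion_count

Every (metabolite, condition, replicates, time) group must form a complete
``i = 0..c`` block with non-negative counts.  Floats are written with 17
significant digits so write -> read round-trips are bit exact; files are
UTF-8 with Unix line endings and "." decimals.  A wide exporter (rows
"metabolite + i", columns time x replicate) mirrors the layout used in
supplementary isotopologue tables for human inspection, and a CDT-style
tab-delimited export (GID, NAME, value columns) feeds tree-view heatmap
tools.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TableFormatError",
    "RunConfig",
    "ISOTOPOLOGUE_COLUMNS",
    "read_isotopologue_table",
    "write_isotopologue_table",
    "write_wide_table",
    "write_heatmap_export",
    "read_heatmap_export",
    "load_run_config",
    "setup_logging",
]

log = logging.getLogger("picoflux")

ISOTOPOLOGUE_COLUMNS = [
    "metabolite",
    "i",
    "c",
    "condition",
    "biological_replicate",
    "technical_replicate",
    "time_min",
    "ion_count",
]

_GROUP_COLS = [
    "metabolite",
    "condition",
    "biological_replicate",
    "technical_replicate",
    "time_min",
]


class TableFormatError(ValueError):
    """A file violates the isotopologue table dialect; message carries row numbers."""


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Log to stderr (and optionally a file); idempotent."""
    root = logging.getLogger("picoflux")
    root.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(h)
    if logfile is not None and not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == Path(logfile).resolve()
        for h in root.handlers
    ):
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


@dataclasses.dataclass
class RunConfig:
    """Pipeline run options, loadable from a YAML file."""

    input_path: str | None = None
    output_dir: str = "picoflux_out"
    na_correction: bool = False
    p_na: float = 0.0107
    baseline_mode: str = "observed_t0"  # or "zero"
    seed: int = 0
    limitation_factor: float = 3.0
    noise_cv: float = 0.05
    cell_density: float = 4.5e7


def load_run_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML / flat key-value file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise TableFormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def _fmt(x: float) -> str:
    # 17 significant digits: enough for exact float64 round-trip.
    return format(float(x), ".17g")


def write_isotopologue_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy isotopologue table in the package dialect."""
    missing = [c for c in ISOTOPOLOGUE_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"missing columns: {missing}")
    out = table[ISOTOPOLOGUE_COLUMNS].copy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ISOTOPOLOGUE_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.metabolite),
                        str(int(row.i)),
                        str(int(row.c)),
                        str(row.condition),
                        str(row.biological_replicate),
                        str(row.technical_replicate),
                        _fmt(row.time_min),
                        _fmt(row.ion_count),
                    ]
                )
                + "\n"
            )


def read_isotopologue_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy isotopologue table.

    Raises :class:`TableFormatError` (with 1-based data row numbers) on
    missing columns, ``i > c``, negative counts, duplicate keys, or
    incomplete ``i = 0..c`` blocks; an empty file raises "no records".
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"metabolite": str, "condition": str},
            float_precision="round_trip",  # bit-exact read-back of 17-digit floats
        )
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: no records") from None
    missing = [c for c in ISOTOPOLOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TableFormatError(f"{path}: no records")
    df = df[ISOTOPOLOGUE_COLUMNS]
    rownum = np.arange(1, len(df) + 1)

    bad = df["i"] > df["c"]
    if bad.any():
        rows = rownum[bad.to_numpy()][:5].tolist()
        raise TableFormatError(f"{path}: i > c at data row(s) {rows}")
    if (df["i"] < 0).any() or (df["c"] < 1).any():
        raise TableFormatError(f"{path}: negative i or c < 1")
    neg = df["ion_count"] < 0
    if neg.any():
        rows = rownum[neg.to_numpy()][:5].tolist()
        raise TableFormatError(f"{path}: negative ion_count at data row(s) {rows}")
    dup = df.duplicated(subset=_GROUP_COLS + ["i"], keep=False)
    if dup.any():
        rows = rownum[dup.to_numpy()][:5].tolist()
        raise TableFormatError(f"{path}: duplicate isotopologue keys at data row(s) {rows}")
    for key, grp in df.groupby(_GROUP_COLS, sort=False):
        c = int(grp["c"].iloc[0])
        if (grp["c"] != c).any():
            raise TableFormatError(f"{path}: inconsistent carbon count for {key}")
        got = sorted(grp["i"].tolist())
        if got != list(range(c + 1)):
            first = rownum[grp.index[0]]
            raise TableFormatError(
                f"{path}: incomplete isotopologue block for {key} starting at data "
                f"row {first}: have i = {got}, need 0..{c}"
            )
    return df.reset_index(drop=True)


def write_wide_table(table: pd.DataFrame, path: str | Path) -> None:
    """Export the wide, human-facing layout: rows "metabolite + i",
    columns condition/time/replicate (mirrors supplementary-table style)."""
    wide = table.copy()
    wide["isotopologue"] = wide["metabolite"] + " + " + wide["i"].astype(int).astype(str)
    wide["sample"] = (
        wide["condition"].astype(str)
        + "_t"
        + wide["time_min"].astype(float).map("{:g}".format)
        + "_b"
        + wide["biological_replicate"].astype(str)
        + "_r"
        + wide["technical_replicate"].astype(str)
    )
    pivot = wide.pivot_table(
        index="isotopologue", columns="sample", values="ion_count", sort=True
    )
    pivot.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


def write_heatmap_export(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as a CDT-style tab file (GID, NAME, value columns).

    Row order is preserved (no clustering is performed); missing values are
    emitted as empty fields per CDT convention.  Non-numeric cells are an
    error, as is a ragged frame.
    """
    if matrix.empty:
        raise TableFormatError("empty matrix")
    values = matrix.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"non-numeric cell in heatmap matrix: {exc}") from None
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GID\tNAME\t" + "\t".join(str(col) for col in matrix.columns) + "\n")
        for n, (name, row) in enumerate(zip(matrix.index, values), start=1):
            cells = ["" if np.isnan(v) else _fmt(v) for v in row]
            fh.write(f"ROW{n}X\t{name}\t" + "\t".join(cells) + "\n")


def read_heatmap_export(path: str | Path) -> pd.DataFrame:
    """Read back a CDT-style export written by :func:`write_heatmap_export`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["GID", "NAME"]:
        raise TableFormatError(f"{path}: not a CDT-style export (expected GID, NAME)")
    out = df.drop(columns=["GID"]).set_index("NAME")
    out.index.name = None
    return out.astype(float)
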