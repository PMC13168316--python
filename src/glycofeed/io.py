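"""Delimited-text interchange for time courses, glycoform tables and results.

Long (tidy) CSV is the canonical interchange format; wide glycoform tables
are accepted on input. All floating-point output is written with 6
significant digits for diffability. Schema violations raise
:class:`SchemaError` naming the file and the offending column or value.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .glycoforms import (
    GLYCATION_SITES,
    GlycationProfile,
    GlycoformTable,
    normalize_abundances,
    parse_glycoform,
)
from .kinetics import CultureTimeCourse, FeedEvent

FLOAT_FORMAT = "%.6g"

TIMECOURSE_COLUMNS = [
    "replicate", "strategy", "day", "vcd_1e6_per_ml", "viability_pct",
    "diameter_um", "glucose_g_l", "lactate_mm", "titer_mg_l", "ph",
]
FEED_COLUMNS = ["replicate", "strategy", "day", "feed_pct_vv",
                "glucose_added_g_l", "gal_plus"]
GLYCO_LONG_COLUMNS = ["sample_id", "strategy", "phase", "replicate",
                      "glycoform", "abundance_percent"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _read_delim(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# -- time courses -----------------------------------------------------------

def write_time_courses(
    courses: list[CultureTimeCourse], path: str | Path,
    feed_path: str | Path | None = None,
) -> None:
    frame = pd.concat([c.to_frame() for c in courses], ignore_index=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if feed_path is not None:
        rows = []
        for c in courses:
            for e in c.feed_events:
                rows.append({"replicate": c.replicate, "strategy": c.strategy,
                             "day": e.day, "feed_pct_vv": e.feed_pct_vv,
                             "glucose_added_g_l": e.glucose_added_g_l,
                             "gal_plus": e.gal_plus})
        pd.DataFrame(rows, columns=FEED_COLUMNS).to_csv(
            feed_path, index=False, float_format=FLOAT_FORMAT)


def read_time_courses(
    path: str | Path, feed_path: str | Path | None = None
) -> list[CultureTimeCourse]:
    """Read per-replicate daily time courses (and optionally feed events)."""
    df = _read_delim(path)
    _require(df, ["replicate", "strategy", "day", "vcd_1e6_per_ml"], path)
    feeds = None
    if feed_path is not None:
        feeds = _read_delim(feed_path)
        _require(feeds, ["strategy", "day", "feed_pct_vv"], feed_path)
    out = []
    for (strategy, replicate), grp in df.groupby(["strategy", "replicate"], sort=True):
        grp = grp.sort_values("day")
        events: list[FeedEvent] = []
        if feeds is not None:
            sel = feeds[feeds["strategy"] == strategy]
            if "replicate" in sel.columns:
                sel = sel[sel["replicate"] == replicate]
            for _, row in sel.iterrows():
                events.append(FeedEvent(
                    float(row["day"]), float(row["feed_pct_vv"]),
                    float(row.get("glucose_added_g_l",
                                  row.get("glucose_target_g_l", 0.0))),
                    bool(row.get("gal_plus", False))))
        def col(name):
            return grp[name].to_numpy(float) if name in grp.columns else None
        out.append(CultureTimeCourse(
            t=grp["day"].to_numpy(float), vcd=grp["vcd_1e6_per_ml"].to_numpy(float),
            viability=col("viability_pct"), diameter=col("diameter_um"),
            glucose=col("glucose_g_l"), lactate=col("lactate_mm"),
            titer=col("titer_mg_l"), ph=col("ph"),
            feed_events=events, replicate=str(replicate), strategy=str(strategy)))
    return out


# -- glycoform tables -------------------------------------------------------

def write_glycoform_table(table: GlycoformTable, path: str | Path) -> None:
    """Write in the canonical long format."""
    rows = table.abundances.stack().rename("abundance_percent").reset_index()
    rows.columns = ["sample_id", "glycoform", "abundance_percent"]
    meta = table.metadata.reset_index(names="sample_id")
    out = rows.merge(meta, on="sample_id", how="left")
    out = out[["sample_id", "strategy", "phase", "replicate",
               "glycoform", "abundance_percent"]]
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_glycoform_table(path: str | Path) -> GlycoformTable:
    """Read a glycoform table, auto-detecting long vs wide layout.

    Long layout: sample_id, strategy, phase, replicate, glycoform,
    abundance_percent. Wide layout: a sample_id column (plus optional
    metadata columns) and one column per glycoform label.
    """
    df = _read_delim(path)
    if "glycoform" in df.columns and "abundance_percent" in df.columns:
        _require(df, ["sample_id", "glycoform", "abundance_percent"], path)
        dup = df.duplicated(["sample_id", "glycoform"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise SchemaError(
                f"{path}: duplicate entry for sample {row['sample_id']!r}, "
                f"glycoform {row['glycoform']!r}")
        wide = df.pivot(index="sample_id", columns="glycoform",
                        values="abundance_percent")
        # a glycoform absent from a sample's rows was not observed there
        wide = wide.fillna(0.0)
        meta_cols = [c for c in ("strategy", "phase", "replicate") if c in df.columns]
        meta = (df[["sample_id"] + meta_cols].drop_duplicates("sample_id")
                .set_index("sample_id"))
        for c in ("strategy", "phase", "replicate"):
            if c not in meta.columns:
                meta[c] = pd.NA
    else:
        _require(df, ["sample_id"], path)
        df = df.set_index("sample_id")
        meta_cols = [c for c in ("strategy", "phase", "replicate") if c in df.columns]
        meta = df[meta_cols].copy()
        for c in ("strategy", "phase", "replicate"):
            if c not in meta.columns:
                meta[c] = pd.NA
        wide = df.drop(columns=meta_cols)
        for c in wide.columns:
            try:
                parse_glycoform(c)
            except ValueError as exc:
                raise SchemaError(f"{path}: column {c!r}: {exc}") from exc
    try:
        return normalize_abundances(wide, meta.loc[wide.index])
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- glycation profiles -----------------------------------------------------

def write_glycation_profile(profile: GlycationProfile, path: str | Path) -> None:
    profile.fractions.reset_index(names="sample_id").to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_glycation_profile(path: str | Path) -> GlycationProfile:
    df = _read_delim(path)
    cols = [f"hexoses_{i}" for i in range(GLYCATION_SITES + 1)]
    _require(df, ["sample_id"] + cols, path)
    try:
        return GlycationProfile(df.set_index("sample_id")[cols])
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- result tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table with the package's fixed float precision."""
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
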