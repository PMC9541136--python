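"""Occurrence-table IO and the auditable cleaning log.

Reading is column-mapped (Darwin Core term defaults) and never silently
drops a row: malformed rows are counted and reported. Cleaning is an ordered
pipeline of named rules; the resulting :class:`ProvenanceLog` satisfies the
conservation identity ``input = output + sum(removed)`` by construction and
is what the pre-bias-assessment questions embed as evidence of data handling.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import RECORD_COLUMNS

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "ParseReport",
    "CleaningRule",
    "ProvenanceLog",
    "read_occurrences",
    "write_occurrences",
    "clean_records",
    "BUILTIN_RULES",
    "write_table",
    "read_table",
]

#: Darwin Core terms mapped onto the canonical short column names.
DEFAULT_COLUMN_MAP = {
    "taxon": "scientificName",
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
    "year": "year",
    "count": "individualCount",
    "coord_uncertainty_m": "coordinateUncertaintyInMeters",
    "source": "datasetKey",
}

_REQUIRED = ("taxon", "lon", "lat", "year")


@dataclass(frozen=True)
class ParseReport:
    rows_read: int
    rows_malformed: int
    malformed_reasons: dict[str, int]


def read_occurrences(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a delimited occurrence file into the canonical table.

    ``column_map`` maps canonical names (taxon/lon/lat/year/...) to the file's
    header names; unmapped optional columns are filled with NA. Rows whose
    required fields are missing or non-numeric are excluded from the returned
    table but tallied in the parse report — nothing disappears silently.
    Coordinates out of physical range are retained here (a cleaning rule
    handles them) so that reading and cleaning stay separately auditable.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True, comment="#")
    missing = [cmap[k] for k in _REQUIRED if cmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"input file lacks required column(s): {missing}")

    out = pd.DataFrame(index=raw.index)
    out["taxon"] = raw[cmap["taxon"]]
    for key in ("lon", "lat"):
        out[key] = pd.to_numeric(raw[cmap[key]], errors="coerce")
    out["year"] = pd.to_numeric(raw[cmap["year"]], errors="coerce")
    for key in ("count", "coord_uncertainty_m"):
        col = cmap[key]
        out[key] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan
    src = cmap["source"]
    out["source"] = raw[src] if src in raw.columns else pd.NA

    reasons: dict[str, int] = {}
    bad_coord = out["lon"].isna() | out["lat"].isna()
    bad_year = ~bad_coord & out["year"].isna()
    bad_taxon = ~bad_coord & ~bad_year & (out["taxon"].isna() | (out["taxon"].str.strip() == ""))
    if bad_coord.any():
        reasons["missing coordinate"] = int(bad_coord.sum())
    if bad_year.any():
        reasons["missing or non-numeric year"] = int(bad_year.sum())
    if bad_taxon.any():
        reasons["missing taxon"] = int(bad_taxon.sum())
    ok = ~(bad_coord | bad_year | bad_taxon)
    df = out.loc[ok].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    report = ParseReport(rows_read=len(raw), rows_malformed=int((~ok).sum()), malformed_reasons=reasons)
    return df[list(RECORD_COLUMNS)], report


def write_occurrences(df: pd.DataFrame, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write the canonical table back out with Darwin Core headers."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = df[list(RECORD_COLUMNS)].rename(columns=cmap)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class CleaningRule:
    """A named, parameterised row filter applied in declared order."""

    name: str
    params: dict = field(default_factory=dict)

    def describe(self) -> str:
        spec = BUILTIN_RULES.get(self.name)
        desc = spec[1] if spec else "unknown rule"
        if self.params:
            desc += " (" + ", ".join(f"{k}={v}" for k, v in sorted(self.params.items())) + ")"
        return desc


def _keep_with_coords(df: pd.DataFrame, **_) -> pd.Series:
    return df["lon"].notna() & df["lat"].notna()


def _keep_with_year(df: pd.DataFrame, **_) -> pd.Series:
    return df["year"].notna()


def _keep_in_range(df: pd.DataFrame, **_) -> pd.Series:
    return df["lon"].between(-180, 180) & df["lat"].between(-90, 90)


def _keep_first_unique(df: pd.DataFrame, **_) -> pd.Series:
    return ~df.duplicated(subset=["taxon", "lon", "lat", "year"], keep="first")


def _keep_precise(df: pd.DataFrame, threshold_m: float = 10000.0, **_) -> pd.Series:
    unc = df["coord_uncertainty_m"]
    return unc.isna() | (unc <= threshold_m)


#: name -> (keep-mask function, human description)
BUILTIN_RULES: dict[str, tuple[Callable[..., pd.Series], str]] = {
    "drop-missing-coordinates": (_keep_with_coords, "drop rows without both coordinates"),
    "drop-missing-year": (_keep_with_year, "drop rows without a year"),
    "drop-out-of-range-coordinates": (_keep_in_range, "drop rows with coordinates outside WGS84 bounds"),
    "drop-exact-duplicates": (_keep_first_unique, "drop exact duplicates on (taxon, lon, lat, year)"),
    "drop-coarse-coordinates": (_keep_precise, "drop rows with coordinate uncertainty above threshold_m"),
}


@dataclass
class ProvenanceLog:
    """Ordered record of what each cleaning rule removed.

    ``input_count == output_count + sum(removed)`` always holds; re-running
    the same rules on the same input reproduces the log exactly (timestamp
    aside).
    """

    input_count: int
    steps: list[dict]  # {"rule", "description", "removed"} in application order
    output_count: int
    sources: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        removed = sum(s["removed"] for s in self.steps)
        if self.input_count != self.output_count + removed:
            raise ValueError("provenance log violates conservation")
        if any(s["removed"] < 0 for s in self.steps):
            raise ValueError("negative removal count")
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "steps": [dict(s) for s in self.steps],
            "output_count": self.output_count,
            "sources": list(self.sources),
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProvenanceLog":
        return cls(
            input_count=int(d["input_count"]),
            steps=[dict(s) for s in d["steps"]],
            output_count=int(d["output_count"]),
            sources=list(d.get("sources", [])),
            timestamp=str(d.get("timestamp", "")),
        )


def clean_records(
    records: pd.DataFrame,
    rules: Sequence[CleaningRule | str],
    sources: Sequence[str] = (),
    timestamp: str = "",
) -> tuple[pd.DataFrame, ProvenanceLog]:
    """Apply cleaning rules in order, logging removals per rule."""
    resolved: list[CleaningRule] = []
    for r in rules:
        rule = CleaningRule(r) if isinstance(r, str) else r
        if rule.name not in BUILTIN_RULES:
            raise ValueError(f"unknown cleaning rule: {rule.name!r}")
        resolved.append(rule)
    seen = [r.name for r in resolved]
    if len(set(seen)) != len(seen):
        raise ValueError("cleaning rule names must be unique within a pipeline")

    df = records.reset_index(drop=True)
    input_count = len(df)
    steps = []
    for rule in resolved:
        fn, _ = BUILTIN_RULES[rule.name]
        keep = fn(df, **rule.params)
        removed = int((~keep).sum())
        steps.append({"rule": rule.name, "description": rule.describe(), "removed": removed})
        df = df.loc[keep].reset_index(drop=True)
    log = ProvenanceLog(
        input_count=input_count,
        steps=steps,
        output_count=len(df),
        sources=list(sources),
        timestamp=timestamp,
    )
    return df, log


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    """Write a tidy CSV artifact with a one-line ``#`` metadata header.

    The header carries tool version, config hash and seed so every artifact
    is self-describing; readers skip it via ``comment='#'``.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV artifact, skipping ``#`` metadata lines."""
    return pd.read_csv(path, comment="#")
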