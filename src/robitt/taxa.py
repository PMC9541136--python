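"""Taxonomic and environmental coverage heuristics.

Taxonomic screening asks how much of the declared target taxon list is
actually recorded in each period, how evenly records are spread across taxa
(Pielou-type evenness, H'/ln S on record shares), and how much the recorded
taxon set turns over between periods (Jaccard).  Environmental screening
summarises covariates at the grid-cell level: the domain's cells are binned
into a joint environmental lattice and each period's coverage is the
fraction of *realized* bins (bins actually occupied by some domain cell)
that hold at least one record — unrealizable covariate combinations never
count as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GridSpec, PeriodSpec, jaccard

__all__ = [
    "TaxonCoverage",
    "EnvCoverage",
    "taxon_coverage",
    "taxon_sampling_turnover",
    "env_coverage",
    "pielou_evenness",
]


def pielou_evenness(counts) -> float | None:
    """H'/ln S over record shares; None when fewer than 2 taxa recorded."""
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if len(c) < 2:
        return None
    p = c / c.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(len(c)))


@dataclass(frozen=True)
class TaxonCoverage:
    """Per-period taxonomic coverage evidence.

    summary: period, n_taxa_recorded, fraction_target (recorded∩target /
    target), evenness; shares: per-period record share of each recorded
    taxon (summing to 1 within a period); off_target: counts of records whose
    taxon is not on the target list (reported, never silently dropped).
    """

    summary: pd.DataFrame
    shares: pd.DataFrame
    off_target: pd.DataFrame


def taxon_coverage(
    records: pd.DataFrame, taxa, periods: PeriodSpec
) -> TaxonCoverage:
    target = set(taxa)
    if not target:
        raise ValueError("target taxon list must be non-empty")
    idx = periods.indices(records["year"].to_numpy()) if len(records) else np.array([], int)
    df = records.assign(period_idx=idx)

    rows, share_rows, off_rows = [], [], []
    for p in range(1, periods.n_periods + 1):
        label = periods.label(p)
        sub = df[df["period_idx"] == p]
        counts = sub.groupby("taxon").size().sort_index()
        recorded = set(counts.index)
        fraction = len(recorded & target) / len(target)
        rows.append(
            {
                "period": label,
                "n_records": int(len(sub)),
                "n_taxa_recorded": int(len(recorded)),
                "fraction_target": fraction,
                "evenness": pielou_evenness(counts.to_numpy()),
            }
        )
        total = counts.sum()
        for taxon, c in counts.items():
            share_rows.append({"period": label, "taxon": taxon, "share": c / total})
        off_rows.append(
            {"period": label, "n_off_target": int(sub[~sub["taxon"].isin(target)].shape[0])}
        )
    return TaxonCoverage(
        summary=pd.DataFrame(rows),
        shares=pd.DataFrame(share_rows, columns=["period", "taxon", "share"]),
        off_target=pd.DataFrame(off_rows),
    )


def taxon_sampling_turnover(
    records: pd.DataFrame, periods: PeriodSpec, period_a: str, period_b: str
) -> float | None:
    """Jaccard similarity of recorded taxon sets between two periods."""
    labels = {periods.label(i): i for i in range(1, periods.n_periods + 1)}
    for p in (period_a, period_b):
        if p not in labels:
            raise ValueError(f"unknown period {p!r}")
    idx = periods.indices(records["year"].to_numpy()) if len(records) else np.array([], int)
    a = set(records.loc[idx == labels[period_a], "taxon"])
    b = set(records.loc[idx == labels[period_b], "taxon"])
    return jaccard(a, b)


@dataclass(frozen=True)
class EnvCoverage:
    """Per-period environmental-space coverage.

    summary: period, n_bins_occupied, fraction (of the domain's realized
    joint-bin set), n_unassessable (records in cells without covariates).
    The reference bin set is fixed across periods.
    """

    summary: pd.DataFrame
    n_reference_bins: int
    bins_per_axis: int
    axes: tuple[str, ...]
    scheme: str = "equal_width"


def _joint_bins(values: pd.DataFrame, edges: dict[str, np.ndarray], bins: int) -> list[tuple]:
    keys = []
    per_axis = {}
    for ax, e in edges.items():
        v = values[ax].to_numpy(float)
        # right-inclusive top edge so the axis maximum stays in the last bin
        b = np.clip(np.searchsorted(e, v, side="right") - 1, 0, bins - 1)
        per_axis[ax] = b
    for i in range(len(values)):
        keys.append(tuple(int(per_axis[ax][i]) for ax in edges))
    return keys


def env_coverage(
    records: pd.DataFrame,
    cell_env_table: pd.DataFrame,
    grid: GridSpec,
    periods: PeriodSpec,
    bins_per_axis: int = 5,
    scheme: str = "equal_width",
) -> EnvCoverage:
    """Fraction of the domain's realized environmental bins sampled per period.

    ``cell_env_table`` supplies one covariate vector per grid cell (columns
    col, row, then one column per axis). Binning is equal-width per axis over
    the domain's range by default; ``scheme="quantile"`` uses per-axis
    quantile edges instead.
    """
    if bins_per_axis < 2:
        raise ValueError("bins_per_axis must be >= 2")
    axes = tuple(c for c in cell_env_table.columns if c not in ("col", "row"))
    if not axes:
        raise ValueError("cell_env_table has no covariate columns")

    edges: dict[str, np.ndarray] = {}
    for ax in axes:
        v = cell_env_table[ax].to_numpy(float)
        if scheme == "equal_width":
            edges[ax] = np.linspace(v.min(), v.max(), bins_per_axis + 1)
        elif scheme == "quantile":
            edges[ax] = np.quantile(v, np.linspace(0, 1, bins_per_axis + 1))
        else:
            raise ValueError(f"unknown binning scheme {scheme!r}")

    table = cell_env_table.copy()
    table["joint_bin"] = _joint_bins(table, edges, bins_per_axis)
    reference = set(table["joint_bin"])
    cell_bin = {(int(c), int(r)): b for c, r, b in zip(table["col"], table["row"], table["joint_bin"])}

    col, row = grid.cells(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    idx = periods.indices(records["year"].to_numpy()) if len(records) else np.array([], int)

    rows = []
    for p in range(1, periods.n_periods + 1):
        mask = idx == p
        occupied = set()
        unassessable = 0
        for c, r in zip(col[mask], row[mask]):
            b = cell_bin.get((int(c), int(r)))
            if b is None:
                unassessable += 1
            else:
                occupied.add(b)
        rows.append(
            {
                "period": periods.label(p),
                "n_bins_occupied": len(occupied),
                "fraction": len(occupied) / len(reference),
                "n_unassessable": unassessable,
            }
        )
    return EnvCoverage(
        summary=pd.DataFrame(rows),
        n_reference_bins=len(reference),
        bins_per_axis=bins_per_axis,
        axes=axes,
        scheme=scheme,
    )
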