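"""Descriptive summaries: viability bins, index correlations, era trends.

Complements the screening pipeline with the reporting views a trial analyst
expects: decade binning of genotype mean viability, Pearson correlations of
the susceptibility index with viability under each condition, per-breeding-era
index summaries, and grouped descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pollenheat.trial_data import TrialPanel

#: Default decade bins, inclusive percent ranges, high to low.
DEFAULT_BINS: tuple[tuple[int, int, str], ...] = (
    (100, 100, "100"),
    (90, 99, "90-99"),
    (80, 89, "80-89"),
    (70, 79, "70-79"),
    (60, 69, "60-69"),
    (0, 59, "<60"),
)

#: Default breeding-era cut years: release before 1965 -> pre-green-revolution,
#: 1965-2000 -> post-green-revolution, 2001 onward -> modern.
DEFAULT_ERA_CUTS: tuple[int, int] = (1965, 2001)

ERAS = ("pre_green_revolution", "post_green_revolution", "modern")


@dataclass(frozen=True)
class EraRule:
    """Release-year cut points mapping year -> breeding era."""

    post_start: int = DEFAULT_ERA_CUTS[0]
    modern_start: int = DEFAULT_ERA_CUTS[1]

    def __post_init__(self) -> None:
        if self.post_start >= self.modern_start:
            raise ValueError("era cut years must be increasing")


def _check_bins(bins: tuple[tuple[int, int, str], ...]) -> None:
    spans = sorted((lo, hi) for lo, hi, _ in bins)
    covered = 0
    for lo, hi in spans:
        if lo != covered:
            raise ValueError(f"bins must be non-overlapping and exhaustive over [0,100]; gap at {covered}")
        covered = hi + 1
    if covered != 101:
        raise ValueError("bins must cover [0, 100]")


def viability_bins(
    means: pd.DataFrame,
    condition: str,
    season: str | None = None,
    bins: tuple[tuple[int, int, str], ...] = DEFAULT_BINS,
    round_to_int: bool = True,
) -> pd.DataFrame:
    """Count genotypes per viability bin for one condition (and season).

    Genotype means are rounded to the nearest integer percent before binning
    by default, matching integer-labelled decade bins; pass
    ``round_to_int=False`` to bin raw means (a value belongs to the bin whose
    inclusive integer range contains its floor).  Counts sum to the number of
    genotypes with data.  Seasons average when ``season`` is None.
    """
    _check_bins(bins)
    sub = means[means["treatment"] == condition]
    if season is not None:
        sub = sub[sub["season"] == season]
    if sub.empty:
        raise ValueError(f"no means for condition {condition!r}, season {season!r}")
    per_geno = sub.groupby("genotype")["mean_viability"].mean()
    values = per_geno.to_numpy(float)
    if round_to_int:
        values = np.rint(values)
    rows = []
    for lo, hi, label in bins:
        in_bin = (values >= lo) & (values <= hi) if round_to_int else (
            (np.floor(values) >= lo) & (np.floor(values) <= hi)
        )
        rows.append({"bin_low": lo, "bin_high": hi, "label": label, "count": int(in_bin.sum())})
    out = pd.DataFrame(rows, columns=["bin_low", "bin_high", "label", "count"])
    assert out["count"].sum() == len(values)
    return out


def hsi_correlations(
    results: pd.DataFrame, pairs: tuple[str, ...] = ("normal", "stress")
) -> pd.DataFrame:
    """Pearson correlation of the susceptibility index with viability.

    Pairs (hsi, x_normal) and (hsi, x_stress) are taken from the screening
    table, aligned by genotype and season; ``pairs`` selects which conditions
    to correlate against.  Two-sided p-values come from the t transform of r.
    Zero variance in either variable of a requested pair is an error.
    """
    if len(results) < 3:
        raise ValueError("need >= 3 paired observations for a correlation")
    rows = []
    for col, pair in ((f"x_{c}", f"hsi_vs_{c}_viability") for c in pairs):
        x = results[col].to_numpy(float)
        y = results["hsi"].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in {pair}; correlation undefined")
        r, p = stats.pearsonr(x, y)
        rows.append({"pair": pair, "r": float(r), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows, columns=["pair", "r", "p", "n"])


def era_from_year(release_year: int | None, rule: EraRule = EraRule()) -> str | None:
    """Breeding era for a release year; None stays unassigned (advanced lines)."""
    if release_year is None or pd.isna(release_year):
        return None
    year = int(release_year)
    if year < rule.post_start:
        return "pre_green_revolution"
    if year < rule.modern_start:
        return "post_green_revolution"
    return "modern"


def era_trend(
    results: pd.DataFrame,
    registry: pd.DataFrame,
    rule: EraRule = EraRule(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-era susceptibility summaries over season-averaged index values.

    Each genotype contributes its mean hsi across the seasons present in
    ``results``.  Eras come from the registry's ``era`` column where given,
    otherwise from ``release_year`` via ``rule``; genotypes without either are
    listed as unassigned.

    Returns ``(summary, values, unassigned)`` where ``summary`` has columns
    ``era, n, mean_hsi, median_hsi, q1, q3`` (one row per era, n = 0 when
    empty), ``values`` is the per-genotype ``era, genotype, hsi`` table for
    violin plotting, and ``unassigned`` lists genotypes without an era.
    """
    per_geno = results.groupby("genotype", as_index=False).agg(hsi=("hsi", "mean"))
    reg = registry.copy()
    if "era" not in reg.columns:
        reg["era"] = pd.NA
    derived = reg["release_year"].map(lambda y: era_from_year(y, rule))
    reg["era"] = reg["era"].where(reg["era"].notna() & (reg["era"] != ""), derived)
    merged = per_geno.merge(reg[["genotype", "era"]], on="genotype", how="left")
    unassigned = sorted(merged.loc[merged["era"].isna(), "genotype"])
    values = (
        merged.dropna(subset=["era"])
        .loc[:, ["era", "genotype", "hsi"]]
        .sort_values(["era", "genotype"], kind="mergesort")
        .reset_index(drop=True)
    )
    rows = []
    for era in ERAS:
        vals = values.loc[values["era"] == era, "hsi"].to_numpy(float)
        if vals.size:
            rows.append(
                {
                    "era": era,
                    "n": vals.size,
                    "mean_hsi": float(vals.mean()),
                    "median_hsi": float(np.median(vals)),
                    "q1": float(np.quantile(vals, 0.25)),
                    "q3": float(np.quantile(vals, 0.75)),
                }
            )
        else:
            rows.append(
                {"era": era, "n": 0, "mean_hsi": np.nan, "median_hsi": np.nan, "q1": np.nan, "q3": np.nan}
            )
    summary = pd.DataFrame(rows, columns=["era", "n", "mean_hsi", "median_hsi", "q1", "q3"])
    return summary, values, unassigned


def descriptive_stats(
    panel: TrialPanel, grouping: list[str] = ["season", "treatment"]
) -> pd.DataFrame:
    """Mean, sample SD (n-1), min, max and n of viability per group.

    SD is reported absent (NaN) for singleton groups.
    """
    grouped = panel.records.groupby(grouping, as_index=False)["viability"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), min="min", max="max", n="size"
    )
    return grouped
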