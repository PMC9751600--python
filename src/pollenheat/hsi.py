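"""Pollen-viability heat susceptibility index (HSI) and tolerance screening.

For genotype g in a given season, with replicate-mean viabilities X_stress and
X_normal and panel grand means X̄_stress, X̄_normal (unweighted over genotypes
with both treatments observed),

    HSI_g = (1 - X_stress,g / X_normal,g) / (1 - X̄_stress / X̄_normal)

i.e. the genotype's relative viability reduction divided by the panel-mean
relative reduction (the Fischer-Maurer susceptibility index applied to pollen
viability).  HSI < 1 means below-average susceptibility.  Genotypes are
classified tolerant (HSI < 0.5), moderately tolerant (0.5 <= HSI < 1) or
susceptible (HSI >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pollenheat.trial_data import TrialPanel, genotype_means

#: Classification thresholds.
TOLERANT_CUT = 0.5
SUSCEPTIBLE_CUT = 1.0

#: Ordered class labels.
CLASSES = ("tolerant", "moderately_tolerant", "susceptible")

#: Column order of the per-genotype result table.
HSI_COLUMNS = [
    "genotype",
    "season",
    "x_normal",
    "x_stress",
    "reduction",
    "mean_reduction",
    "hsi",
    "class",
]


class HsiError(ValueError):
    """The index is undefined for the given inputs."""


@dataclass(frozen=True)
class PanelReduction:
    """Panel-level mean relative reduction for one season.

    ``mean_reduction`` is D̄ = 1 - X̄_stress / X̄_normal, the denominator of
    the susceptibility index; grand means are unweighted means over genotype
    cell means, restricted to genotypes observed under both treatments.
    """

    season: str
    grand_mean_stress: float
    grand_mean_normal: float
    mean_reduction: float
    n_genotypes: int


def _paired_means(means: pd.DataFrame, season: str) -> pd.DataFrame:
    """Wide table of (x_normal, x_stress) per genotype for one season,
    keeping only genotypes with both treatment means present."""
    sub = means[means["season"] == season]
    wide = sub.pivot_table(
        index="genotype", columns="treatment", values="mean_viability", aggfunc="first"
    )
    for col in ("normal", "stress"):
        if col not in wide.columns:
            wide[col] = np.nan
    return wide.dropna(subset=["normal", "stress"]).rename(
        columns={"normal": "x_normal", "stress": "x_stress"}
    )


def panel_reduction(means: pd.DataFrame, season: str) -> PanelReduction:
    """Panel-mean relative reduction D̄ for one season.

    Parameters
    ----------
    means
        Genotype-mean table from :func:`pollenheat.trial_data.genotype_means`.
    season
        Season label to restrict to.
    """
    wide = _paired_means(means, season)
    if wide.empty:
        raise HsiError(
            f"season {season!r}: no genotype has means under both treatments"
        )
    gm_normal = float(wide["x_normal"].mean())
    gm_stress = float(wide["x_stress"].mean())
    if gm_normal <= 0:
        raise HsiError(f"season {season!r}: grand normal mean is {gm_normal}; index undefined")
    d_bar = 1.0 - gm_stress / gm_normal
    if d_bar == 0:
        raise HsiError(
            f"season {season!r}: no panel-level stress response (mean reduction = 0); "
            "index undefined"
        )
    return PanelReduction(
        season=season,
        grand_mean_stress=gm_stress,
        grand_mean_normal=gm_normal,
        mean_reduction=d_bar,
        n_genotypes=len(wide),
    )


def compute_hsi(x_stress: float, x_normal: float, panel: PanelReduction) -> float:
    """Susceptibility index for one genotype: (1 - x_stress/x_normal) / D̄.

    Negative values (genotype improved under stress while the panel declined)
    are legitimate and returned as-is.
    """
    if x_normal <= 0:
        raise HsiError(
            f"normal-condition mean is {x_normal}; index undefined for this genotype"
        )
    if panel.mean_reduction == 0:
        raise HsiError("panel mean reduction is 0; index undefined")
    return (1.0 - x_stress / x_normal) / panel.mean_reduction


def classify_hsi(
    hsi: float,
    tolerant_cut: float = TOLERANT_CUT,
    susceptible_cut: float = SUSCEPTIBLE_CUT,
) -> str:
    """Map an index value to its tolerance class.

    Half-open intervals make the partition total: tolerant on
    (-inf, tolerant_cut), moderately tolerant on [tolerant_cut,
    susceptible_cut), susceptible on [susceptible_cut, inf).
    """
    if not math.isfinite(hsi):
        raise HsiError(f"non-finite index value {hsi!r}")
    if hsi < tolerant_cut:
        return "tolerant"
    if hsi < susceptible_cut:
        return "moderately_tolerant"
    return "susceptible"


def screen_panel(
    panel: TrialPanel,
    seasons: list[str] | None = None,
    tolerant_cut: float = TOLERANT_CUT,
    susceptible_cut: float = SUSCEPTIBLE_CUT,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Screen every genotype in every season.

    Returns
    -------
    results : DataFrame
        One row per classifiable genotype x season with columns
        ``genotype, season, x_normal, x_stress, reduction, mean_reduction,
        hsi, class`` (full precision; round for reporting).
    counts : DataFrame
        Per-season class counts (``season, class, n``); counts per season sum
        to the number of classifiable genotypes.
    excluded : DataFrame
        Genotype x season combinations for which the index is undefined
        (missing treatment mean or zero normal mean), with a reason.
    """
    means = genotype_means(panel)
    if seasons is None:
        seasons = sorted(means["season"].unique())
    rows: list[dict] = []
    excluded: list[dict] = []
    for season in seasons:
        sub = means[means["season"] == season]
        present = sub.pivot_table(
            index="genotype", columns="treatment", values="mean_viability", aggfunc="first"
        )
        wide = _paired_means(means, season)
        # classifiable genotypes need both means and x_normal > 0
        usable = wide[wide["x_normal"] > 0]
        for gid in present.index:
            if gid not in wide.index:
                excluded.append(
                    {"genotype": gid, "season": season, "reason": "missing treatment mean"}
                )
            elif gid not in usable.index:
                excluded.append(
                    {"genotype": gid, "season": season, "reason": "zero normal mean"}
                )
        if usable.empty:
            continue
        gm_normal = float(usable["x_normal"].mean())
        gm_stress = float(usable["x_stress"].mean())
        if gm_normal <= 0:
            raise HsiError(f"season {season!r}: grand normal mean is {gm_normal}")
        d_bar = 1.0 - gm_stress / gm_normal
        if d_bar == 0:
            raise HsiError(
                f"season {season!r}: no panel-level stress response (mean reduction = 0)"
            )
        pr = PanelReduction(season, gm_stress, gm_normal, d_bar, len(usable))
        for gid, row in usable.iterrows():
            hsi = compute_hsi(row["x_stress"], row["x_normal"], pr)
            rows.append(
                {
                    "genotype": gid,
                    "season": season,
                    "x_normal": row["x_normal"],
                    "x_stress": row["x_stress"],
                    "reduction": 1.0 - row["x_stress"] / row["x_normal"],
                    "mean_reduction": d_bar,
                    "hsi": hsi,
                    "class": classify_hsi(hsi, tolerant_cut, susceptible_cut),
                }
            )
    results = pd.DataFrame(rows, columns=HSI_COLUMNS)
    results = results.sort_values(["season", "genotype"], kind="mergesort").reset_index(
        drop=True
    )
    if results.empty:
        raise HsiError("no classifiable genotype in any requested season")
    counts = (
        results.groupby(["season", "class"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
    # report zero counts for empty classes so the partition is explicit
    full = pd.MultiIndex.from_product(
        [seasons, CLASSES], names=["season", "class"]
    ).to_frame(index=False)
    counts = full.merge(counts, on=["season", "class"], how="left").fillna({"n": 0})
    counts["n"] = counts["n"].astype(int)
    excluded_df = pd.DataFrame(excluded, columns=["genotype", "season", "reason"])
    return results, counts, excluded_df


def stable_tolerant(results: pd.DataFrame, seasons: list[str] | None = None) -> tuple[list[str], pd.DataFrame]:
    """Genotypes classified tolerant in every season.

    Parameters
    ----------
    results
        Screening table from :func:`screen_panel` covering >= 2 seasons.

    Returns
    -------
    stable : list of genotype ids, sorted.
    partial : DataFrame of genotypes classifiable in only a subset of the
        seasons (excluded from the intersection), with the seasons they have.
    """
    if seasons is None:
        seasons = sorted(results["season"].unique())
    if len(seasons) < 2:
        raise HsiError(f"need >= 2 seasons for a cross-season intersection, got {seasons}")
    sub = results[results["season"].isin(seasons)]
    per_geno = sub.groupby("genotype")
    n_seasons = per_geno["season"].nunique()
    partial_ids = n_seasons[n_seasons < len(seasons)].index
    partial = (
        sub[sub["genotype"].isin(partial_ids)]
        .groupby("genotype", as_index=False)
        .agg(seasons_present=("season", lambda s: ",".join(sorted(s))))
    )
    complete = sub[~sub["genotype"].isin(partial_ids)]
    tol = complete[complete["class"] == "tolerant"]
    stable = sorted(
        tol.groupby("genotype")["season"].nunique().pipe(lambda s: s[s == len(seasons)]).index
    )
    return stable, partial
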