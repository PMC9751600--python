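"""Data model, validation and CSV I/O for plot-level trial records.

A trial panel is a long (tidy) table of plot-level observations: one row per
(genotype, season, treatment, replicate) carrying percent pollen viability in
[0, 100].  An optional genotype registry carries release year, breeding era
and pedigree.  All downstream computation consumes the validated
:class:`TrialPanel` produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Fixed header of a panel CSV.
PANEL_COLUMNS = ["genotype", "season", "treatment", "replicate", "viability"]

#: Fixed header of a registry CSV (release_year may be empty for advanced lines).
REGISTRY_COLUMNS = ["genotype", "release_year", "era", "pedigree"]

#: The two admissible treatment levels.
TREATMENTS = ("normal", "stress")


class PanelValidationError(ValueError):
    """A panel or registry failed schema or invariant validation."""


@dataclass
class TrialPanel:
    """A validated collection of plot-level trial records.

    Attributes
    ----------
    records
        Long-format DataFrame with columns ``genotype, season, treatment,
        replicate, viability``; every row validated.
    registry
        Optional genotype registry (``genotype, release_year, era, pedigree``).
    """

    records: pd.DataFrame
    registry: pd.DataFrame | None = field(default=None)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].unique())

    @property
    def seasons(self) -> list[str]:
        return sorted(self.records["season"].unique())

    @property
    def n_genotypes(self) -> int:
        return self.records["genotype"].nunique()

    @property
    def n_seasons(self) -> int:
        return self.records["season"].nunique()

    @property
    def n_treatments(self) -> int:
        return self.records["treatment"].nunique()

    @property
    def n_replicates(self) -> int:
        """Replicate count of the (first) cell; meaningful when balanced."""
        return int(
            self.records.groupby(["genotype", "season", "treatment"], sort=False)
            .size()
            .iloc[0]
        )

    @property
    def balanced(self) -> bool:
        """True iff every genotype x season x treatment cell is present with
        the same replicate count."""
        sizes = self.records.groupby(["genotype", "season", "treatment"]).size()
        n_cells_expected = self.n_genotypes * self.n_seasons * self.n_treatments
        return len(sizes) == n_cells_expected and sizes.nunique() == 1

    def design_summary(self) -> dict:
        return {
            "n_genotypes": self.n_genotypes,
            "n_seasons": self.n_seasons,
            "n_treatments": self.n_treatments,
            "n_replicates": self.n_replicates,
            "n_records": len(self.records),
            "balanced": self.balanced,
        }

    def subset(self, treatment: str | None = None, season: str | None = None) -> "TrialPanel":
        """Restrict to one treatment and/or season, keeping the registry."""
        rec = self.records
        if treatment is not None:
            rec = rec[rec["treatment"] == treatment]
        if season is not None:
            rec = rec[rec["season"] == season]
        if rec.empty:
            raise PanelValidationError(
                f"subset (treatment={treatment!r}, season={season!r}) is empty"
            )
        return TrialPanel(records=rec.reset_index(drop=True), registry=self.registry)


def _normalise_treatment(values: pd.Series) -> pd.Series:
    """Case-insensitive normalisation of treatment labels; anything outside
    {normal, stress} is an error (no silent coercion)."""
    lowered = values.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(TREATMENTS)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise PanelValidationError(
            f"invalid treatment level(s) {sorted(values[bad].unique())} "
            f"at CSV row(s) {rows[:10]}; expected one of {list(TREATMENTS)}"
        )
    return lowered


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw record table against the panel invariants.

    Returns a cleaned copy (treatment normalised, dtypes fixed).  Raises
    :class:`PanelValidationError` naming offending CSV rows (header = row 1).
    """
    missing = [c for c in PANEL_COLUMNS if c not in records.columns]
    if missing:
        raise PanelValidationError(
            f"missing required column(s) {missing}; expected header {PANEL_COLUMNS}"
        )
    rec = records.loc[:, PANEL_COLUMNS].copy().reset_index(drop=True)

    rec["genotype"] = rec["genotype"].astype(str)
    rec["season"] = rec["season"].astype(str)
    rec["treatment"] = _normalise_treatment(rec["treatment"])

    replicate = pd.to_numeric(rec["replicate"], errors="coerce")
    bad_rep = replicate.isna() | (replicate < 1) | (replicate != replicate.round())
    if bad_rep.any():
        rows = (np.flatnonzero(bad_rep.to_numpy()) + 2).tolist()
        raise PanelValidationError(
            f"replicate must be an integer >= 1; bad row(s) {rows[:10]}"
        )
    rec["replicate"] = replicate.astype(int)

    viability = pd.to_numeric(rec["viability"], errors="coerce")
    bad_v = viability.isna() | (viability < 0) | (viability > 100)
    if bad_v.any():
        rows = (np.flatnonzero(bad_v.to_numpy()) + 2).tolist()
        raise PanelValidationError(
            f"viability must be a percent in [0, 100]; bad row(s) {rows[:10]} "
            f"(values {rec.loc[bad_v, 'viability'].head(10).tolist()})"
        )
    rec["viability"] = viability.astype(float)

    dup = rec.duplicated(subset=["genotype", "season", "treatment", "replicate"])
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 2).tolist()
        raise PanelValidationError(
            f"duplicate (genotype, season, treatment, replicate) key(s) at row(s) {rows[:10]}"
        )
    return rec


def validate_registry(registry: pd.DataFrame) -> pd.DataFrame:
    """Validate and clean a genotype registry table."""
    if "genotype" not in registry.columns:
        raise PanelValidationError(
            f"registry missing 'genotype' column; expected header {REGISTRY_COLUMNS}"
        )
    reg = registry.copy().reset_index(drop=True)
    reg["genotype"] = reg["genotype"].astype(str)
    for col in ("release_year", "era", "pedigree"):
        if col not in reg.columns:
            reg[col] = pd.NA
    reg["release_year"] = pd.to_numeric(reg["release_year"], errors="coerce").astype(
        "Int64"
    )
    if reg["genotype"].duplicated().any():
        dups = reg.loc[reg["genotype"].duplicated(), "genotype"].tolist()
        raise PanelValidationError(f"duplicate genotype(s) in registry: {dups[:10]}")
    return reg.loc[:, REGISTRY_COLUMNS]


def make_panel(
    records: pd.DataFrame, registry: pd.DataFrame | None = None
) -> TrialPanel:
    """Build a validated panel from in-memory tables."""
    rec = validate_records(records)
    reg = validate_registry(registry) if registry is not None else None
    return TrialPanel(records=rec, registry=reg)


def read_panel(path: str | Path, registry_path: str | Path | None = None) -> TrialPanel:
    """Read and validate a panel CSV (and optional registry CSV).

    The panel CSV must carry the header ``genotype,season,treatment,
    replicate,viability``.  Every record is validated; descriptive errors name
    the offending CSV row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    records = pd.read_csv(path, dtype={"genotype": str, "season": str})
    registry = None
    if registry_path is not None:
        registry_path = Path(registry_path)
        if not registry_path.exists():
            raise FileNotFoundError(f"registry file not found: {registry_path}")
        registry = pd.read_csv(registry_path, dtype={"genotype": str})
    return make_panel(records, registry)


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read and validate a standalone genotype registry CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"registry file not found: {path}")
    return validate_registry(pd.read_csv(path, dtype={"genotype": str}))


def genotype_means(panel: TrialPanel) -> pd.DataFrame:
    """Mean viability per (genotype, season, treatment) cell.

    One row per cell present in the data, averaging over available replicates;
    the replicate count per cell is reported in ``n``.  These cell means are
    the X values entering the susceptibility index.
    """
    if panel.records.empty:
        raise PanelValidationError("panel is empty")
    out = (
        panel.records.groupby(["genotype", "season", "treatment"], as_index=False)
        .agg(mean_viability=("viability", "mean"), n=("viability", "size"))
        .sort_values(["genotype", "season", "treatment"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def write_panel(panel: TrialPanel, path: str | Path) -> Path:
    """Write panel records as CSV with the documented header, full precision."""
    path = Path(path)
    sorted_rec = panel.records.sort_values(
        ["genotype", "season", "treatment", "replicate"], kind="mergesort"
    )
    sorted_rec.to_csv(path, index=False, columns=PANEL_COLUMNS, float_format="%.17g")
    return path


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as CSV with stable column order."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path
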