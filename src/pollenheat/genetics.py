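"""Variance components and genetic parameters from genotype-trial ANOVA.

In a balanced one-way genotype layout with r observations per genotype the
expected mean squares are E[MS_genotype] = sigma2_e + r*sigma2_g and
E[MS_error] = sigma2_e, giving the method-of-moments estimators

    sigma2_e = MS_error
    sigma2_g = (MS_genotype - MS_error) / r      (clamped at 0)

Phenotypic variance follows either the plot basis sigma2_p = sigma2_g +
sigma2_e (default; the usual convention in PCV/GCV studies following Allard)
or the genotype-mean basis sigma2_g + sigma2_e / r.  Derived parameters, with
X̄ the condition mean:

    PCV% = 100 * sqrt(sigma2_p) / X̄        GCV% = 100 * sqrt(sigma2_g) / X̄
    h2_bs = sigma2_g / sigma2_p             (broad-sense heritability)
    GA = k * sqrt(sigma2_p) * h2_bs         (genetic advance, trait units;
                                             k = 2.06 at 5% selection intensity)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pollenheat.anova import anova_oneway_genotype
from pollenheat.trial_data import TrialPanel

#: Standardized selection differential at 5% selection intensity.
DEFAULT_K = 2.06

GENETICS_COLUMNS = [
    "condition",
    "mean",
    "sigma2_g",
    "sigma2_e",
    "sigma2_p",
    "pcv_pct",
    "gcv_pct",
    "h2_bs_pct",
    "ga",
    "ga_over_mean_pct",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic, error and phenotypic variance (trait-squared units)."""

    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    r: int
    truncated: bool  # sigma2_g clamped at 0 (MS_genotype < MS_error)
    basis: str = "plot"


@dataclass(frozen=True)
class GeneticSummary:
    """Per-condition genetic parameters for the trait."""

    condition: str
    mean: float
    components: VarianceComponents
    pcv_pct: float
    gcv_pct: float
    h2_bs_pct: float
    ga: float
    k: float = DEFAULT_K

    def as_row(self) -> dict:
        return {
            "condition": self.condition,
            "mean": self.mean,
            "sigma2_g": self.components.sigma2_g,
            "sigma2_e": self.components.sigma2_e,
            "sigma2_p": self.components.sigma2_p,
            "pcv_pct": self.pcv_pct,
            "gcv_pct": self.gcv_pct,
            "h2_bs_pct": self.h2_bs_pct,
            "ga": self.ga,
            "ga_over_mean_pct": 100.0 * self.ga / self.mean if self.mean > 0 else float("nan"),
        }


def variance_components(
    ms_genotype: float, ms_error: float, r: int, basis: str = "plot"
) -> VarianceComponents:
    """Method-of-moments variance components from the two mean squares.

    ``r`` is the number of observations per genotype entering MS_genotype
    (replicates, times seasons when pooled).  A negative genotypic estimate is
    clamped to 0 and flagged.
    """
    if r < 2:
        raise ValueError(f"need r >= 2 observations per genotype, got {r}")
    if ms_genotype < 0 or ms_error < 0:
        raise ValueError("mean squares must be non-negative")
    if basis not in ("plot", "mean"):
        raise ValueError(f"basis must be 'plot' or 'mean', got {basis!r}")
    sigma2_e = float(ms_error)
    raw = (ms_genotype - ms_error) / r
    truncated = raw < 0
    sigma2_g = 0.0 if truncated else float(raw)
    sigma2_p = sigma2_g + (sigma2_e if basis == "plot" else sigma2_e / r)
    return VarianceComponents(sigma2_g, sigma2_e, sigma2_p, int(r), truncated, basis)


def pcv_gcv(vc: VarianceComponents, mean: float) -> tuple[float, float]:
    """Phenotypic and genotypic coefficients of variation (percent of mean)."""
    if mean <= 0:
        raise ValueError(f"trait mean must be positive, got {mean}")
    pcv = 100.0 * vc.sigma2_p**0.5 / mean
    gcv = 100.0 * vc.sigma2_g**0.5 / mean
    return pcv, gcv


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability as a percentage, in [0, 100]."""
    if vc.sigma2_p <= 0:
        raise ValueError("phenotypic variance is 0; heritability undefined")
    return 100.0 * vc.sigma2_g / vc.sigma2_p


def genetic_advance(vc: VarianceComponents, k: float = DEFAULT_K) -> float:
    """Expected gain from truncation selection, GA = k * sqrt(sigma2_p) * h2.

    Returned in trait units (percent viability); h2 enters as a fraction.
    """
    if vc.sigma2_p == 0:
        return 0.0
    h2 = vc.sigma2_g / vc.sigma2_p
    return k * vc.sigma2_p**0.5 * h2


def genetics_report(
    panel: TrialPanel,
    condition: str,
    season: str | None = None,
    k: float = DEFAULT_K,
    basis: str = "plot",
) -> GeneticSummary:
    """Full per-condition chain: one-way ANOVA -> components -> parameters.

    Seasons pool by default (pass ``season=`` for a single-season estimate);
    the replicate divisor is then the per-genotype observation count.
    """
    table = anova_oneway_genotype(panel, treatment=condition, season=season)
    ms_g = float(table.loc[table["source"] == "Genotypes", "mean_sq"].iloc[0])
    ms_e = float(table.loc[table["source"] == "Residuals", "mean_sq"].iloc[0])
    r = int(table.attrs["replicates_per_genotype"])
    mean = float(table.attrs["grand_mean"])
    vc = variance_components(ms_g, ms_e, r, basis=basis)
    pcv, gcv = pcv_gcv(vc, mean)
    h2 = heritability(vc)
    ga = genetic_advance(vc, k=k)
    return GeneticSummary(
        condition=condition, mean=mean, components=vc,
        pcv_pct=pcv, gcv_pct=gcv, h2_bs_pct=h2, ga=ga, k=k,
    )


def genetics_table(
    panel: TrialPanel,
    conditions: tuple[str, ...] = ("normal", "stress"),
    season: str | None = None,
    k: float = DEFAULT_K,
    basis: str = "plot",
) -> pd.DataFrame:
    """One summary row per condition, in CSV-ready column order."""
    rows = [
        genetics_report(panel, c, season=season, k=k, basis=basis).as_row()
        for c in conditions
    ]
    return pd.DataFrame(rows, columns=GENETICS_COLUMNS)
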