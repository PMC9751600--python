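"""Balanced fixed-effects factorial ANOVA for replicated genotype trials.

The combined model decomposes plot-level viability as

    y = mu + Treatment + Year + Genotype + Treatment:Genotype + error

with every factor fixed and all remaining variation (blocks, year
interactions) pooled into the residual.  For a balanced G x 2 x S x r design
the sources are orthogonal, so sums of squares add exactly and each F test is
MS_source / MS_residual.  A per-condition one-way genotype ANOVA feeds the
variance-component estimators in :mod:`pollenheat.genetics`.

Only balanced panels are accepted: the expected-mean-square algebra behind
the genetic parameters holds only under balance, and approximating it on
unbalanced data would silently change the estimand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pollenheat.trial_data import TrialPanel

ANOVA_COLUMNS = ["source", "df", "sum_sq", "mean_sq", "f_value", "p_value"]


class UnbalancedDesignError(ValueError):
    """The panel is not balanced; the orthogonal decomposition does not apply."""


def _require_balanced(panel: TrialPanel, keys: list[str]) -> int:
    """Check each cell over `keys` has identical replication; return the count."""
    sizes = panel.records.groupby(keys).size()
    expected_cells = 1
    for k in keys:
        expected_cells *= panel.records[k].nunique()
    if len(sizes) != expected_cells or sizes.nunique() != 1:
        counts = sizes.value_counts()
        modal = counts.idxmax()
        offending = sizes[sizes != modal]
        missing = expected_cells - len(sizes)
        detail = []
        if missing:
            detail.append(f"{missing} empty cell(s)")
        if len(offending):
            detail.append(
                "unequal replication in cells "
                + ", ".join(str(ix) for ix in offending.index[:5].tolist())
            )
        raise UnbalancedDesignError(
            "balanced design required over " + " x ".join(keys) + ": " + "; ".join(detail)
        )
    return int(sizes.iloc[0])


def f_pvalue(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the central F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if not np.isfinite(f):
        return 0.0
    if f < 0:
        raise ValueError(f"F statistic must be >= 0, got {f}")
    return float(stats.f.sf(f, df1, df2))


def _ss_for_grouping(y: np.ndarray, codes: np.ndarray, n_levels: int, grand: float) -> float:
    """Between-group sum of squares for one grouping of a balanced layout."""
    sums = np.bincount(codes, weights=y, minlength=n_levels)
    counts = np.bincount(codes, minlength=n_levels)
    means = sums / counts
    return float(np.sum(counts * (means - grand) ** 2))


def _finish_table(rows: list[dict], total_ss: float, total_df: int) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    table.attrs["total_ss"] = total_ss
    table.attrs["total_df"] = total_df
    return table


def anova_combined(panel: TrialPanel) -> pd.DataFrame:
    """Combined factorial ANOVA: Treatment, Year, Genotypes, Treatment x
    Genotypes, Residuals.

    Returns a table with columns ``source, df, sum_sq, mean_sq, f_value,
    p_value``; F tests each source mean square against the pooled residual.
    The residual pools replicate variation and all year interactions, so its
    df is N - 1 - (T-1) - (S-1) - (G-1) - (T-1)(G-1).  With zero residual
    variance F is reported as +inf.

    Raises :class:`UnbalancedDesignError` on unbalanced panels and
    ``ValueError`` when any factor has a single level.
    """
    rec = panel.records
    for factor, col in (("Treatment", "treatment"), ("Year", "season"), ("Genotypes", "genotype")):
        if rec[col].nunique() < 2:
            raise ValueError(f"factor {factor} has a single level; model not estimable")
    _require_balanced(panel, ["genotype", "season", "treatment"])

    y = rec["viability"].to_numpy(float)
    n = y.size
    grand = float(y.mean())
    total_ss = float(np.sum((y - grand) ** 2))

    t_codes, t_levels = pd.factorize(rec["treatment"], sort=True)
    s_codes, s_levels = pd.factorize(rec["season"], sort=True)
    g_codes, g_levels = pd.factorize(rec["genotype"], sort=True)
    T, S, G = len(t_levels), len(s_levels), len(g_levels)

    ss_t = _ss_for_grouping(y, t_codes, T, grand)
    ss_s = _ss_for_grouping(y, s_codes, S, grand)
    ss_g = _ss_for_grouping(y, g_codes, G, grand)
    tg_codes = t_codes * G + g_codes
    ss_tg_cells = _ss_for_grouping(y, tg_codes, T * G, grand)
    ss_tg = ss_tg_cells - ss_t - ss_g
    ss_resid = total_ss - ss_t - ss_s - ss_g - ss_tg

    df_t, df_s, df_g = T - 1, S - 1, G - 1
    df_tg = (T - 1) * (G - 1)
    df_resid = n - 1 - df_t - df_s - df_g - df_tg
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom; need replication")
    ms_resid = ss_resid / df_resid

    rows = []
    for source, df, ss in (
        ("Treatment", df_t, ss_t),
        ("Year", df_s, ss_s),
        ("Genotypes", df_g, ss_g),
        ("Treatment x Genotypes", df_tg, ss_tg),
    ):
        ms = ss / df
        f = ms / ms_resid if ms_resid > 0 else np.inf
        rows.append(
            {
                "source": source,
                "df": df,
                "sum_sq": ss,
                "mean_sq": ms,
                "f_value": f,
                "p_value": f_pvalue(f, df, df_resid),
            }
        )
    rows.append(
        {
            "source": "Residuals",
            "df": df_resid,
            "sum_sq": ss_resid,
            "mean_sq": ms_resid,
            "f_value": np.nan,
            "p_value": np.nan,
        }
    )
    return _finish_table(rows, total_ss, n - 1)


def anova_oneway_genotype(
    panel: TrialPanel, treatment: str | None = None, season: str | None = None
) -> pd.DataFrame:
    """One-way genotype ANOVA within one condition.

    Restrict the panel to one treatment (and optionally one season; seasons
    pool otherwise) and partition into Genotypes (df G-1) and Residuals.  The
    two mean squares feed :func:`pollenheat.genetics.variance_components`,
    where the replicate divisor is the per-genotype observation count
    (replicates x pooled seasons).
    """
    sub = panel.subset(treatment=treatment, season=season)
    if sub.records["treatment"].nunique() != 1:
        raise ValueError(
            "one-way genotype ANOVA needs a single treatment level; pass treatment="
        )
    rec = sub.records
    if rec["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    sizes = rec.groupby("genotype").size()
    if sizes.nunique() != 1:
        raise UnbalancedDesignError(
            "balanced design required: unequal observation counts per genotype "
            f"(range {sizes.min()}-{sizes.max()})"
        )
    r = int(sizes.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 observations per genotype for a residual term")

    y = rec["viability"].to_numpy(float)
    n = y.size
    grand = float(y.mean())
    total_ss = float(np.sum((y - grand) ** 2))
    g_codes, g_levels = pd.factorize(rec["genotype"], sort=True)
    G = len(g_levels)
    ss_g = _ss_for_grouping(y, g_codes, G, grand)
    ss_resid = total_ss - ss_g
    df_g, df_resid = G - 1, n - G
    ms_g, ms_resid = ss_g / df_g, ss_resid / df_resid
    f = ms_g / ms_resid if ms_resid > 0 else np.inf
    rows = [
        {
            "source": "Genotypes",
            "df": df_g,
            "sum_sq": ss_g,
            "mean_sq": ms_g,
            "f_value": f,
            "p_value": f_pvalue(f, df_g, df_resid),
        },
        {
            "source": "Residuals",
            "df": df_resid,
            "sum_sq": ss_resid,
            "mean_sq": ms_resid,
            "f_value": np.nan,
            "p_value": np.nan,
        },
    ]
    table = _finish_table(rows, total_ss, n - 1)
    table.attrs["replicates_per_genotype"] = r
    table.attrs["grand_mean"] = grand
    return table
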