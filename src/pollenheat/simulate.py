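"""Synthetic balanced field-trial panels with known truth.

Generates plot-level percent viability for a G-genotype x 2-treatment x
S-season x r-replicate balanced trial under the additive model

    y_gist = mu + year_s - delta*1[stress] + g_i + gt_i*1[stress] + e_gist

with independent Gaussian genotype effects g_i ~ N(0, sigma2_g), genotype x
treatment effects gt_i ~ N(0, sigma2_gt), season effects year_s ~
N(0, sigma2_year) and residuals e ~ N(0, sigma2_e), clipped to the [0, 100]
percent scale (clip events are counted; heavy clipping biases variance
estimates).  The accompanying :class:`SimTruth` records the latent effects,
the true per-condition heritability and the true (noise-free) susceptibility
index per genotype, so recovery of every pipeline stage can be tested without
real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from pollenheat.trial_data import TrialPanel, make_panel

#: Table of 12 cross-season heat-tolerant genotypes: name, release year
#: (None = advanced line), and printed index values for the two seasons.
TABLE2_TOLERANT: tuple[tuple[str, int | None, float, float], ...] = (
    ("Chenab-70", 1970, 0.3, 0.1),
    ("Pari-73", 1973, 0.4, 0.2),
    ("Pak-81", 1981, 0.4, 0.3),
    ("MH-21", 2021, 0.2, 0.4),
    ("Punjab-76", 1976, 0.03, 0.3),
    ("NIFA-Aman", 2016, 0.2, 0.2),
    ("NUWYT-63", None, 0.4, 0.3),
    ("Swabi-1", 2020, 0.2, 0.2),
    ("Nisnan-21", 2021, 0.4, 0.3),
    ("Frontana", 1940, 0.4, 0.3),
    ("Amin-2000", 2000, 0.4, 0.3),
    ("Pirsabak-2004", 2004, 0.2, 0.4),
)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic trial.

    Defaults emulate a 200-genotype spring-wheat screening panel grown for
    two seasons under normal and terminal-heat-stress conditions in an RCBD
    with three replications: grand mean 90% viability, an 8-point mean stress
    decrement, and variance components giving plot-basis heritability of
    about 2/3 under normal and 3/4 under stress conditions.
    """

    n_genotypes: int = 200
    n_seasons: int = 2
    replicates: int = 3
    mu: float = 90.0  # grand mean viability under normal conditions, percent
    delta: float = 8.0  # mean stress decrement, percent
    sigma2_g: float = 8.0
    sigma2_gt: float = 4.0
    sigma2_year: float = 2.0
    sigma2_e: float = 4.0
    era_mix: tuple[float, float, float] = (0.10, 0.40, 0.50)  # pre / post / modern
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gt", "sigma2_year", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.mu <= 100):
            raise ValueError("mu must be in (0, 100]")
        if self.n_genotypes < 2 or self.n_seasons < 1 or self.replicates < 1:
            raise ValueError("need >= 2 genotypes, >= 1 season, >= 1 replicate")
        if abs(sum(self.era_mix) - 1.0) > 1e-9:
            raise ValueError("era_mix must sum to 1")


@dataclass
class SimTruth:
    """Latent state of a simulated panel, for recovery testing.

    ``h2_normal`` / ``h2_stress`` are the true plot-basis heritabilities
    implied by the generating variances (genetic variance under stress
    includes the interaction component).  ``hsi`` is the noise-free index per
    genotype computed from expected season-averaged means, and
    ``tolerant_set`` the genotypes with true index < 0.5.  ``clip_fraction``
    is the share of observations clipped to [0, 100].
    """

    config: SimConfig
    genotype_effects: pd.DataFrame  # genotype, g, gt
    season_effects: pd.DataFrame  # season, year_effect
    h2_normal: float
    h2_stress: float
    hsi: pd.DataFrame  # genotype, x_normal, x_stress, hsi
    tolerant_set: list[str] = field(default_factory=list)
    clip_fraction: float = 0.0


def _true_h2(cfg: SimConfig) -> tuple[float, float]:
    h2_n = cfg.sigma2_g / (cfg.sigma2_g + cfg.sigma2_e) if cfg.sigma2_g + cfg.sigma2_e > 0 else 0.0
    sg_s = cfg.sigma2_g + cfg.sigma2_gt
    h2_s = sg_s / (sg_s + cfg.sigma2_e) if sg_s + cfg.sigma2_e > 0 else 0.0
    return h2_n, h2_s


def simulate_panel(config: SimConfig | None = None, **overrides) -> tuple[TrialPanel, SimTruth]:
    """Draw one balanced panel and its truth from the configured model.

    Fully reproducible from ``config.seed``; the random stream is split per
    component (genotype effects, season effects, residuals, registry), so
    e.g. changing the replicate count does not reshuffle genotype effects.
    Keyword overrides build a modified copy of the config.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    cfg = config

    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_season, rng_resid, rng_reg = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    genotypes = [f"G{i + 1:03d}" for i in range(cfg.n_genotypes)]
    seasons = [f"S{j + 1}" for j in range(cfg.n_seasons)]
    g = rng_geno.normal(0.0, cfg.sigma2_g**0.5, cfg.n_genotypes)
    gt = rng_geno.normal(0.0, cfg.sigma2_gt**0.5, cfg.n_genotypes)
    year = rng_season.normal(0.0, cfg.sigma2_year**0.5, cfg.n_seasons)

    # expected plot value, shape (G, S, T) with treatment 0 = normal, 1 = stress
    expect = np.empty((cfg.n_genotypes, cfg.n_seasons, 2))
    expect[:, :, 0] = cfg.mu + g[:, None] + year[None, :]
    expect[:, :, 1] = expect[:, :, 0] - cfg.delta + gt[:, None]

    resid = rng_resid.normal(
        0.0, cfg.sigma2_e**0.5, (cfg.n_genotypes, cfg.n_seasons, 2, cfg.replicates)
    )
    y = expect[..., None] + resid
    clipped = (y < 0) | (y > 100)
    clip_fraction = float(clipped.mean())
    y = np.clip(y, 0.0, 100.0)
    if clip_fraction > 0.05:
        warnings.warn(
            f"{clip_fraction:.1%} of observations clipped to [0,100]; "
            "variance estimates will be biased",
            stacklevel=2,
        )

    gi, si, ti, ri = np.meshgrid(
        np.arange(cfg.n_genotypes),
        np.arange(cfg.n_seasons),
        np.arange(2),
        np.arange(cfg.replicates),
        indexing="ij",
    )
    records = pd.DataFrame(
        {
            "genotype": np.array(genotypes)[gi.ravel()],
            "season": np.array(seasons)[si.ravel()],
            "treatment": np.where(ti.ravel() == 0, "normal", "stress"),
            "replicate": ri.ravel() + 1,
            "viability": y.ravel(),
        }
    )

    # registry: eras in fixed proportions, release years drawn within era spans
    n_pre = int(round(cfg.era_mix[0] * cfg.n_genotypes))
    n_post = int(round(cfg.era_mix[1] * cfg.n_genotypes))
    n_modern = cfg.n_genotypes - n_pre - n_post
    eras = (
        ["pre_green_revolution"] * n_pre
        + ["post_green_revolution"] * n_post
        + ["modern"] * n_modern
    )
    years = np.concatenate(
        [
            rng_reg.integers(1920, 1965, n_pre),
            rng_reg.integers(1965, 2001, n_post),
            rng_reg.integers(2001, 2022, n_modern),
        ]
    )
    registry = pd.DataFrame(
        {
            "genotype": genotypes,
            "release_year": years,
            "era": eras,
            "pedigree": ["synthetic" for _ in genotypes],
        }
    )

    panel = make_panel(records, registry)

    # truth: noise-free index from expected season-averaged means
    xn = expect[:, :, 0].mean(axis=1)
    xs = expect[:, :, 1].mean(axis=1)
    d_bar = 1.0 - xs.mean() / xn.mean()
    hsi_true = (1.0 - xs / xn) / d_bar
    hsi_df = pd.DataFrame(
        {"genotype": genotypes, "x_normal": xn, "x_stress": xs, "hsi": hsi_true}
    )
    h2_n, h2_s = _true_h2(cfg)
    truth = SimTruth(
        config=cfg,
        genotype_effects=pd.DataFrame({"genotype": genotypes, "g": g, "gt": gt}),
        season_effects=pd.DataFrame({"season": seasons, "year_effect": year}),
        h2_normal=h2_n,
        h2_stress=h2_s,
        hsi=hsi_df,
        tolerant_set=sorted(np.array(genotypes)[hsi_true < 0.5].tolist()),
        clip_fraction=clip_fraction,
    )
    return panel, truth


def fixture_from_table2(
    d_bar: float = 0.10, x_normal: float = 95.0, n_anchors: int = 4
) -> TrialPanel:
    """Small panel reproducing the published cross-season tolerant set.

    The 12 published heat-tolerant genotypes are given normal-condition means
    of ``x_normal`` and stress means inverted from their printed index values
    at a chosen panel mean reduction ``d_bar``.  Because the panel-weighted
    mean of the index is identically 1, a panel of only below-average
    genotypes cannot reproduce their index values; ``n_anchors`` synthetic
    susceptible anchor genotypes (named ``ANCHOR-k``) are therefore added,
    with index values chosen so the whole panel's mean reduction comes out at
    exactly ``d_bar``.  Screening this panel then reproduces every printed
    index value exactly and the cross-season tolerant intersection is exactly
    the 12 published names.
    """
    names = [t[0] for t in TABLE2_TOLERANT]
    seasons = ("2020-2021", "2021-2022")
    targets = {
        seasons[0]: np.array([t[2] for t in TABLE2_TOLERANT]),
        seasons[1]: np.array([t[3] for t in TABLE2_TOLERANT]),
    }
    rows = []
    n_total = len(names) + n_anchors
    for season in seasons:
        t = targets[season]
        # anchors share one index value a with 12 targets: (sum(t) + n_anchors*a)
        # / n_total = 1  =>  a = (n_total - sum(t)) / n_anchors  (> 1, susceptible)
        a = (n_total - t.sum()) / n_anchors
        hsi_all = np.concatenate([t, np.full(n_anchors, a)])
        all_names = names + [f"ANCHOR-{k + 1}" for k in range(n_anchors)]
        for name, h in zip(all_names, hsi_all):
            x_stress = x_normal * (1.0 - h * d_bar)
            for treatment, value in (("normal", x_normal), ("stress", x_stress)):
                rows.append(
                    {
                        "genotype": name,
                        "season": season,
                        "treatment": treatment,
                        "replicate": 1,
                        "viability": value,
                    }
                )
    registry = pd.DataFrame(
        {
            "genotype": names + [f"ANCHOR-{k + 1}" for k in range(n_anchors)],
            "release_year": [t[1] for t in TABLE2_TOLERANT] + [None] * n_anchors,
            "era": pd.NA,
            "pedigree": pd.NA,
        }
    )
    return make_panel(pd.DataFrame(rows), registry)
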