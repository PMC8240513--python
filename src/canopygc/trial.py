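"""Partial-replicate trial design and latent ground-truth generation.

The simulated experiment mirrors a wheat early-vigour trial: plots laid out on
a row x column grid, each sown with one genotype, genotypes partially
replicated so average replication sits between 1 and 2. True ground cover per
plot is a logit-normal variable driven by genotype, field-row, field-column
and residual effects — exactly the random-effects structure the downstream
REML analysis assumes, so the statistics module is correctly specified for
this generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import InvalidDesignError


def inverse_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class TrialDesign:
    """Plot layout and genotype assignment of a field trial."""

    plots: pd.DataFrame  # columns: plot, row, col, genotype
    plot_length: float
    n_rows_per_plot: int
    row_spacing: float
    path_width: float

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_genotypes(self) -> int:
        return self.plots["genotype"].nunique()

    @property
    def nrep(self) -> float:
        """Mean genotype replication, n_plots / n_genotypes."""
        return self.n_plots / self.n_genotypes

    def genotype_of(self, plot: int) -> str:
        row = self.plots.loc[self.plots["plot"] == plot, "genotype"]
        if row.empty:
            raise KeyError(f"plot {plot} not in design")
        return row.iloc[0]

    def validate(self) -> None:
        if self.plots["plot"].duplicated().any():
            raise InvalidDesignError("duplicate plot ids")
        counts = self.plots["genotype"].value_counts()
        if (counts < 1).any():
            raise InvalidDesignError("every genotype must appear at least once")


@dataclass
class GroundTruth:
    """Latent per-plot state and the effects that generated it.

    ``table`` has one row per plot with columns: plot, genotype, true_gc,
    canopy_height, genotype_effect, row_effect, col_effect, residual_effect.
    """

    table: pd.DataFrame
    mu: float

    def true_gc(self, plot: int) -> float:
        return float(self.table.loc[self.table["plot"] == plot, "true_gc"].iloc[0])

    def canopy_height(self, plot: int) -> float:
        return float(
            self.table.loc[self.table["plot"] == plot, "canopy_height"].iloc[0]
        )


def _assign_genotypes(n_plots: int, n_genotypes: int, rng: np.random.Generator):
    """Partial-replicate assignment: each genotype gets 1 or 2 plots.

    ``n_plots - n_genotypes`` genotypes are duplicated; with the default
    192 / 99 design that is 93 two-plot genotypes and 6 singletons, giving
    mean replication 192/99 ~ 1.94.
    """
    n_dup = n_plots - n_genotypes
    if n_dup > n_genotypes:
        # allow >2 replicates by cycling, used only for tiny smoke configs
        reps = np.ones(n_genotypes, dtype=int)
        for i in range(n_dup):
            reps[i % n_genotypes] += 1
    else:
        reps = np.ones(n_genotypes, dtype=int)
        dup_idx = rng.choice(n_genotypes, size=n_dup, replace=False)
        reps[dup_idx] += 1
    labels = [f"G{g + 1:03d}" for g in range(n_genotypes)]
    assignment = np.repeat(labels, reps)
    rng.shuffle(assignment)
    return assignment


def simulate_trial(
    config: TrialConfig, seed: int
) -> tuple[TrialDesign, GroundTruth]:
    """Simulate a partial-replicate trial and its latent ground truth.

    Deterministic for a fixed seed. Effects are drawn independently from
    zero-mean Gaussians with the configured variances; identical genotype
    labels share one genotype effect.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))

    n = config.n_plots
    rows = np.arange(n) // config.n_field_cols
    cols = np.arange(n) % config.n_field_cols
    genotype = _assign_genotypes(n, config.n_genotypes, rng)

    plots = pd.DataFrame(
        {
            "plot": np.arange(1, n + 1),
            "row": rows,
            "col": cols,
            "genotype": genotype,
        }
    )
    design = TrialDesign(
        plots=plots,
        plot_length=config.plot_length,
        n_rows_per_plot=config.n_rows_per_plot,
        row_spacing=config.row_spacing,
        path_width=config.path_width,
    )
    design.validate()

    labels = sorted(plots["genotype"].unique())
    g_eff = dict(
        zip(labels, rng.normal(0.0, np.sqrt(config.sigma2_genotype), len(labels)))
    )
    r_eff = rng.normal(0.0, np.sqrt(config.sigma2_row), rows.max() + 1)
    c_eff = rng.normal(0.0, np.sqrt(config.sigma2_col), cols.max() + 1)
    e_eff = rng.normal(0.0, np.sqrt(config.sigma2_residual), n)

    ge = np.array([g_eff[g] for g in genotype])
    link = config.mu + ge + r_eff[rows] + c_eff[cols] + e_eff
    true_gc = inverse_logit(link)
    # strictly inside (0,1); inverse_logit is, numerically clamp to be safe
    true_gc = np.clip(true_gc, 1e-9, 1.0 - 1e-9)

    height = (
        config.height_intercept
        + config.height_slope * true_gc
        + rng.normal(0.0, config.height_noise_sd, n)
    )
    height = np.maximum(height, 0.01)

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "plot": plots["plot"],
                "genotype": genotype,
                "true_gc": true_gc,
                "canopy_height": height,
                "genotype_effect": ge,
                "row_effect": r_eff[rows],
                "col_effect": c_eff[cols],
                "residual_effect": e_eff,
            }
        ),
        mu=config.mu,
    )
    return design, truth
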