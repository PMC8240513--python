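"""REML variance components, BLUP genotype means, and repeatability.

For one GC method at one sampling event, the per-plot values are modelled as

    y = mu + genotype + row + column + residual,

with genotype, field-row, field-column and residual all independent zero-mean
Gaussian random effects. The model is fitted by REML: the restricted
log-likelihood is profiled over the residual variance and maximised over the
three variance ratios on the log scale with fixed starting values, so the fit
is deterministic given the data. Genotype BLUPs are predicted at the REML
solution; plot-level repeatability (broad-sense heritability) is

    rho = sigma2_g / (sigma2_g + sigma2_eps / nrep),

where nrep is the mean genotype replication of the trial.

Spatial trend is captured by the row and column effects only — no smooth 2-D
spline surface is fitted. The synthetic trials this package generates contain
exactly row + column structure, so the simplified model is correctly
specified for them; on real field data a spline surface may absorb additional
trend (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import InvalidDesignError
from .trial import TrialDesign

_LOG_GAMMA_BOUNDS = (-25.0, 12.0)


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


@dataclass
class VarianceComponentsResults:
    """REML estimates for one (event, method) fit.

    Variances are on the observation scale; ``blups`` maps genotype label to
    its predicted random effect (summing to ~0), and ``genotype_means()``
    returns ``mu + BLUP``.
    """

    sigma2_g: float
    sigma2_row: float
    sigma2_col: float
    sigma2_eps: float
    mu: float
    nrep: float
    blups: pd.Series
    n_obs: int
    converged: bool
    reml_criterion: float  # -2 * restricted log-likelihood (up to a constant)

    def genotype_means(self) -> pd.Series:
        return (self.mu + self.blups).rename("genotype_mean")

    def repeatability(self, nrep: float | None = None) -> float:
        return repeatability(self, nrep=nrep)

    def summary(self) -> str:
        rho = self.repeatability()
        lines = [
            "Random-effects variance components (REML)",
            "=" * 45,
            f"{'observations':<22}{self.n_obs}",
            f"{'genotypes':<22}{len(self.blups)}",
            f"{'mean replication':<22}{self.nrep:.3f}",
            f"{'converged':<22}{self.converged}",
            "-" * 45,
            f"{'sigma2_genotype':<22}{self.sigma2_g:.6g}",
            f"{'sigma2_row':<22}{self.sigma2_row:.6g}",
            f"{'sigma2_col':<22}{self.sigma2_col:.6g}",
            f"{'sigma2_residual':<22}{self.sigma2_eps:.6g}",
            f"{'grand mean':<22}{self.mu:.6g}",
            f"{'repeatability rho':<22}"
            + (f"{rho:.4f}" if np.isfinite(rho) else "undefined"),
            "=" * 45,
        ]
        return "\n".join(lines)


class GroundCoverVarianceModel:
    """Random-effects model for per-plot GC values of one event and method.

    Parameters
    ----------
    values : array-like
        One observation per plot.
    genotype, row, col : array-like
        Factor labels per plot (same length as ``values``).
    nrep : float, optional
        Mean genotype replication; defaults to n_obs / n_genotypes.
    """

    def __init__(self, values, genotype, row, col, nrep: float | None = None):
        y = np.asarray(values, dtype=float)
        mask = np.isfinite(y)
        self.y = y[mask]
        genotype = np.asarray(genotype)[mask]
        row = np.asarray(row)[mask]
        col = np.asarray(col)[mask]
        if len(self.y) < 3:
            raise InvalidDesignError("need at least 3 non-missing observations")

        self.genotype_levels, g_codes = np.unique(genotype, return_inverse=True)
        _, r_codes = np.unique(row, return_inverse=True)
        _, c_codes = np.unique(col, return_inverse=True)
        if len(self.genotype_levels) < 2:
            raise InvalidDesignError("variance partitioning needs >= 2 genotypes")

        self.Zg = _indicator(g_codes, len(self.genotype_levels))
        self.Zr = _indicator(r_codes, r_codes.max() + 1)
        self.Zc = _indicator(c_codes, c_codes.max() + 1)
        # Gram matrices reused at every likelihood evaluation
        self._G = [Z @ Z.T for Z in (self.Zg, self.Zr, self.Zc)]
        self.nrep = float(nrep) if nrep is not None else (
            len(self.y) / len(self.genotype_levels)
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        design: TrialDesign,
        value_col: str = "value",
    ) -> "GroundCoverVarianceModel":
        """Build from a per-plot value frame joined against a trial design.

        ``data`` needs columns ``plot`` and ``value_col``; genotype, row and
        column factors come from the design.
        """
        merged = design.plots.merge(data[["plot", value_col]], on="plot", how="inner")
        return cls(
            merged[value_col],
            merged["genotype"],
            merged["row"],
            merged["col"],
            nrep=design.nrep,
        )

    # -- restricted likelihood ------------------------------------------------

    def _profiled_crit(self, log_gamma: np.ndarray, y: np.ndarray):
        """-2 restricted log-likelihood profiled over the residual variance.

        Returns (criterion, sigma2_eps_hat, mu_hat, cho_factor(H), gammas)
        with all quantities on the scale of ``y``.
        """
        gam = np.exp(np.clip(log_gamma, *_LOG_GAMMA_BOUNDS))
        n = len(y)
        H = np.eye(n)
        for g, G in zip(gam, self._G):
            H += g * G
        cF = linalg.cho_factor(H, lower=True)
        logdetH = 2.0 * np.sum(np.log(np.diag(cF[0])))
        Hi_y = linalg.cho_solve(cF, y)
        ones = np.ones(n)
        Hi_1 = linalg.cho_solve(cF, ones)
        xhx = ones @ Hi_1
        mu = (ones @ Hi_y) / xhx
        ypy = y @ Hi_y - xhx * mu * mu
        ypy = max(ypy, 1e-300)
        s2e = ypy / (n - 1)
        crit = logdetH + np.log(xhx) + (n - 1) * np.log(ypy)
        return crit, s2e, mu, cF, gam

    def fit(self, tol: float = 1e-8) -> VarianceComponentsResults:
        """Maximise the restricted likelihood; deterministic given the data.

        Starting values split the total variance equally across the four
        components (all variance ratios 1).
        """
        y_raw = self.y
        y_sd = float(np.std(y_raw))
        if y_sd < 1e-12:
            warnings.warn("all observations identical; all variances set to 0",
                          stacklevel=2)
            blups = pd.Series(0.0, index=self.genotype_levels, name="blup")
            return VarianceComponentsResults(
                0.0, 0.0, 0.0, 0.0, float(y_raw[0]), self.nrep, blups,
                len(y_raw), True, np.nan,
            )
        y_mean = float(np.mean(y_raw))
        y = (y_raw - y_mean) / y_sd  # REML is location-invariant and
        # scale-equivariant, so standardising only improves conditioning.

        def objective(theta):
            return self._profiled_crit(theta, y)[0]

        res = optimize.minimize(
            objective,
            x0=np.zeros(3),
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * 3,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        crit, s2e_s, mu_s, cF, gam = self._profiled_crit(res.x, y)

        # BLUPs at the REML solution: u_g = gamma_g Zg' H^-1 (y - mu)
        resid = y - mu_s
        Hi_r = linalg.cho_solve(cF, resid)
        u_g = gam[0] * (self.Zg.T @ Hi_r)

        scale = y_sd * y_sd
        blups = pd.Series(u_g * y_sd, index=self.genotype_levels, name="blup")
        return VarianceComponentsResults(
            sigma2_g=float(gam[0] * s2e_s * scale),
            sigma2_row=float(gam[1] * s2e_s * scale),
            sigma2_col=float(gam[2] * s2e_s * scale),
            sigma2_eps=float(s2e_s * scale),
            mu=float(mu_s * y_sd + y_mean),
            nrep=self.nrep,
            blups=blups,
            n_obs=len(y_raw),
            converged=bool(res.success),
            reml_criterion=float(crit),
        )


def fit_random_effects(
    values, design: TrialDesign, value_col: str = "value"
) -> VarianceComponentsResults:
    """Fit the genotype + row + column random-effects model for one event/method.

    ``values`` may be a DataFrame with columns (plot, value), a Series indexed
    by plot, or an array aligned with ``design.plots``.
    """
    if isinstance(values, pd.DataFrame):
        data = values.rename(columns={value_col: "value"})
    elif isinstance(values, pd.Series):
        data = pd.DataFrame({"plot": values.index, "value": values.values})
    else:
        arr = np.asarray(values, dtype=float)
        if len(arr) != len(design.plots):
            raise InvalidDesignError("value array length does not match design")
        data = pd.DataFrame({"plot": design.plots["plot"].values, "value": arr})
    model = GroundCoverVarianceModel.from_dataframe(data, design)
    return model.fit()


def repeatability(vc, nrep: float | None = None) -> float:
    """Plot-level repeatability rho = s2_g / (s2_g + s2_eps / nrep).

    Accepts a VarianceComponentsResults or anything with ``sigma2_g``,
    ``sigma2_eps`` and ``nrep`` attributes. Undefined (NaN, with a warning)
    when both variances are zero.
    """
    s2g = float(vc.sigma2_g)
    s2e = float(vc.sigma2_eps)
    nrep = float(nrep if nrep is not None else vc.nrep)
    if s2g < 0 or s2e < 0 or nrep <= 0:
        raise ValueError("variances must be >= 0 and nrep > 0")
    denom = s2g + s2e / nrep
    if denom == 0:
        warnings.warn("repeatability undefined: sigma2_g = sigma2_eps = 0",
                      stacklevel=2)
        return float("nan")
    return s2g / denom
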