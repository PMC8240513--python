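"""Pearson correlation analyses: significance stars, ICC and phenotypic matrices.

Two correlation views of a GC table:

* **intraclass correlations (ICC)** — for one method, the Pearson correlation
  of per-plot values between every pair of sampling events; a stable sensor
  keeps these high across the whole diurnal schedule;
* **phenotypic correlations** — for one event, the Pearson correlation of
  genotype means (mu + BLUP) between every pair of methods.

Significance stars follow the strict thresholds **** P < 0.0001,
*** P < 0.001, ** P < 0.01, * P < 0.05. Missing pairs are dropped pairwise;
no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_for_p(p: float) -> str:
    """Significance stars for a two-sided p-value (strict inequalities)."""
    if not np.isfinite(p):
        return ""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    stars: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def pearson_with_stars(x, y) -> CorrelationResult:
    """Pearson r with two-sided p (t transform, n-2 df) and stars.

    Incomplete pairs are dropped pairwise; zero variance in either variable
    yields an undefined result (r = NaN) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, stars_for_p(float(p)))


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson correlations with star coding."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    @property
    def labels(self):
        return list(self.r.index)

    def mean_offdiagonal(self) -> float:
        """Mean of the defined off-diagonal correlations."""
        vals = self.r.values[~np.eye(len(self.r), dtype=bool)]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")


def _pairwise_matrix(frame: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson over the columns of a (units x variables) frame."""
    cols = list(frame.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    stars = np.full((k, k), "", dtype=object)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(frame[cols[i]].notna().sum())
        stars[i, i] = "****"
        for j in range(i + 1, k):
            xi, yj = frame[cols[i]].values, frame[cols[j]].values
            common = int((np.isfinite(xi) & np.isfinite(yj)).sum())
            if common < 3:
                n[i, j] = n[j, i] = common
                continue  # missing cell
            res = pearson_with_stars(xi, yj)
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
            n[i, j] = n[j, i] = res.n
            stars[i, j] = stars[j, i] = res.stars
    make = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationMatrix(make(r), make(p), make(n), make(stars))


def icc_matrix(table: pd.DataFrame, method: str) -> CorrelationMatrix:
    """Between-event ICC matrix of per-plot values for one method.

    ``table`` is a long GC table with columns plot, event_id, method, value.
    Cell (i, j) is the Pearson r over plots between events i and j.
    """
    sub = table[table["method"] == method]
    if sub["event_id"].nunique() < 2:
        raise ValueError(f"need >= 2 events with method {method!r}")
    wide = sub.pivot(index="plot", columns="event_id", values="value")
    return _pairwise_matrix(wide)


def phenotypic_corr_matrix(
    means_by_method: dict[str, pd.Series],
) -> CorrelationMatrix:
    """Between-method correlation of genotype means for one event.

    ``means_by_method`` maps method name to a Series of genotype means
    indexed by genotype label. Genotype sets are intersected; a warning is
    issued when less than 80% of the union is shared.
    """
    if len(means_by_method) < 2:
        raise ValueError("need >= 2 methods")
    sets = [set(s.index) for s in means_by_method.values()]
    common = set.intersection(*sets)
    union = set.union(*sets)
    if len(common) < 0.8 * len(union):
        warnings.warn(
            f"genotype sets overlap on only {len(common)}/{len(union)} labels",
            stacklevel=2,
        )
    idx = sorted(common)
    frame = pd.DataFrame({m: s.reindex(idx) for m, s in means_by_method.items()})
    return _pairwise_matrix(frame)
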