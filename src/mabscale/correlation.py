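"""Rank correlation and simple linear regression between species.

Reproduces the cross-species association analyses: Spearman's rho with a
Fisher-transform confidence interval for each species pair (CL and SC%F),
ordinary least-squares regression (r^2, slope/intercept, two-sided slope
t-test), and the within-species CL-versus-bioavailability regressions,
which are fit against log10(CL) to match their semi-log presentation.

SC%F values above 100% enter as experimentally determined; censoring them
at 100% is available as a sensitivity toggle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CrossSpeciesDataset, Measure, complete_cases

__all__ = [
    "CorrelationResult",
    "spearman",
    "linregress",
    "species_correlation_table",
    "cl_vs_f_regression",
]

#: species pairs in the reporting order used throughout
SPECIES_PAIRS = (("monkey", "human"), ("rat", "human"), ("rat", "monkey"))

#: largest n for which the exact permutation null of Spearman's rho is
#: enumerated (n! permutations; beyond this the t approximation is used)
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" | "ols"
    estimate: float  # rho or r^2
    p_value: float
    n: int
    ci95: tuple[float, float] | None = None  # Fisher-z interval (spearman)
    slope: float | None = None
    intercept: float | None = None
    p_exact: bool = False


def _spearman_ci(rho: float, n: int) -> tuple[float, float] | None:
    """Fisher z interval with SE = sqrt(1.06/(n-3)) (Fieller-Hartley-Pearson);
    approximate, for reporting only."""
    if n <= 3 or abs(rho) >= 1:
        return None
    z = np.arctanh(rho)
    se = np.sqrt(1.06 / (n - 3))
    return (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of the rank-permutation null."""
    n = len(x)
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    obs = abs(rho)
    count = 0
    total = 0
    denom = n * (n**2 - 1) / 6.0
    for perm in permutations(range(n)):
        d = rx - ry[list(perm)]
        r = 1.0 - np.sum(d * d) / denom
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman's rho on average (mid) ranks with a two-sided p-value.

    The p-value is exact (full permutation enumeration) for n <= 9 without
    ties, otherwise the t approximation on rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank variance undefined")
    rho, p_t = stats.spearmanr(x, y)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    exact = n <= EXACT_PERMUTATION_MAX_N and not has_ties
    p = _exact_spearman_p(x, y, rho) if exact else float(p_t)
    return CorrelationResult(
        method="spearman",
        estimate=float(rho),
        p_value=p,
        n=n,
        ci95=_spearman_ci(float(rho), n),
        p_exact=exact,
    )


def linregress(x, y) -> CorrelationResult:
    """Ordinary least squares y ~ x: r^2 and the two-sided slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]):
        raise ValueError("constant x: slope undefined")
    lr = stats.linregress(x, y)
    return CorrelationResult(
        method="ols",
        estimate=float(lr.rvalue**2),
        p_value=float(lr.pvalue),
        n=len(x),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
    )


def species_correlation_table(ds: CrossSpeciesDataset, measure: Measure) -> pd.DataFrame:
    """Spearman + OLS for every species pair, complete cases per pair.

    One row per pair in the order monkey-human, rat-human, rat-monkey.
    """
    rows = []
    for a, b in SPECIES_PAIRS:
        names, x, y = complete_cases(ds, a, b, measure)
        sp = spearman(x, y)
        ols = linregress(x, y)
        rows.append(
            dict(
                pair=f"{a}-{b}",
                measure=measure,
                n=sp.n,
                spearman_rho=sp.estimate,
                spearman_ci95_low=sp.ci95[0] if sp.ci95 else np.nan,
                spearman_ci95_high=sp.ci95[1] if sp.ci95 else np.nan,
                spearman_p=sp.p_value,
                ols_r2=ols.estimate,
                ols_slope=ols.slope,
                ols_intercept=ols.intercept,
                ols_p=ols.p_value,
            )
        )
    return pd.DataFrame(rows)


def cl_vs_f_regression(
    ds: CrossSpeciesDataset,
    species: str,
    log_cl: bool = True,
    censor_f_at_100: bool = False,
) -> CorrelationResult:
    """Within-species regression of SC%F on clearance.

    CL enters as log10(CL) by default (semi-log relationship); SC%F values
    above 100% are used as-is unless ``censor_f_at_100``.
    """
    xs, ys = [], []
    for rec in ds:
        c = rec.value(species, "CL")
        fv = rec.value(species, "SCF")
        if c is not None and fv is not None:
            xs.append(c)
            ys.append(min(fv, 100.0) if censor_f_at_100 else fv)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if log_cl:
        x = np.log10(x)
    return linregress(x, y)
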