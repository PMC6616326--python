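"""Per-line least-square means, trait correlations, and the residual-variance F test.

The phenotype model throughout is one-way fixed effects (line), under which
least-square means coincide with per-line arithmetic means, balanced or not.
The residual-variance test compares two traits' one-way residual variances
with an F ratio on (n_obs - n_lines) degrees of freedom each; because traits
are measured in different units the default standardizes each trait by its
grand standard deviation before taking residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .trait_extraction import TraitRecord

__all__ = [
    "LineMeans",
    "CorrelationResult",
    "VarianceTestResult",
    "records_to_frame",
    "least_square_means",
    "pearson_correlation",
    "residual_variance_ftest",
    "trait_variance_ftest",
    "trait_correlation_matrix",
]


@dataclass(frozen=True)
class LineMeans:
    line_id: str
    trait: str
    lsmean: float
    n_obs: int


@dataclass(frozen=True)
class CorrelationResult:
    trait_x: str
    trait_y: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class VarianceTestResult:
    df1: int
    df2: int
    f_stat: float
    p_value: float


def records_to_frame(records: list[TraitRecord]) -> pd.DataFrame:
    """Long-format DataFrame (line_id, replicate, trait, value) from records."""
    return pd.DataFrame(
        [(r.line_id, r.replicate, r.trait, r.value) for r in records],
        columns=["line_id", "replicate", "trait", "value"],
    )


def least_square_means(records: list[TraitRecord], trait: str) -> list[LineMeans]:
    """Per-line least-square means for one trait under the one-way line model.

    In a one-way layout the LS mean is the per-line arithmetic mean whatever
    the replication pattern; n_obs is reported per line.
    """
    df = records_to_frame(records)
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    grouped = sub.groupby("line_id")["value"].agg(["mean", "count"])
    return [
        LineMeans(line_id=str(lid), trait=trait, lsmean=float(row["mean"]), n_obs=int(row["count"]))
        for lid, row in grouped.iterrows()
    ]


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(trait_x="x", trait_y="y", r=r, p_value=p, n=n)


def residual_variance_ftest(resid_x, resid_y, df1: int | None = None, df2: int | None = None) -> VarianceTestResult:
    """Two-sided F test that two residual vectors share a variance.

    F = (SS_x/df1) / (SS_y/df2); dfs default to n-1 but callers fitting a
    one-way model should pass n_obs - n_lines.  Two-sided p is
    2 * min(P(F <= f), P(F >= f)) since the null is equality with no
    directional alternative.
    """
    rx = np.asarray(resid_x, dtype=np.float64)
    ry = np.asarray(resid_y, dtype=np.float64)
    if rx.size < 2 or ry.size < 2:
        raise ValueError("need at least 2 residuals per trait")
    d1 = int(df1) if df1 is not None else rx.size - 1
    d2 = int(df2) if df2 is not None else ry.size - 1
    if d1 < 1 or d2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    s2x = float(np.sum(rx**2)) / d1
    s2y = float(np.sum(ry**2)) / d2
    if s2y == 0:
        raise ValueError("zero denominator variance")
    f = s2x / s2y
    p = 2.0 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return VarianceTestResult(df1=d1, df2=d2, f_stat=f, p_value=min(1.0, float(p)))


def _one_way_residuals(df: pd.DataFrame, trait: str, standardize: bool) -> tuple[np.ndarray, int]:
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    values = sub["value"].to_numpy(dtype=np.float64)
    if standardize:
        sd = values.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {trait!r} has zero grand variance")
        values = values / sd
    line_means = sub.groupby("line_id")["value"].transform("mean").to_numpy(dtype=np.float64)
    if standardize:
        line_means = line_means / sub["value"].std(ddof=1)
    resid = values - line_means
    df_resid = values.size - sub["line_id"].nunique()
    return resid, df_resid


def trait_variance_ftest(
    records: list[TraitRecord], trait_x: str, trait_y: str, standardize: bool = True
) -> VarianceTestResult:
    """F test of equal residual variance between two traits.

    Residuals are deviations from the per-line mean (one-way fixed-effects
    model); df = n_obs - n_lines per trait.  With ``standardize`` (default)
    each trait is z-scaled by its grand SD first so traits in different units
    are comparable; pass False for the raw-scale ratio.
    """
    df = records_to_frame(records)
    rx, d1 = _one_way_residuals(df, trait_x, standardize)
    ry, d2 = _one_way_residuals(df, trait_y, standardize)
    return residual_variance_ftest(rx, ry, df1=d1, df2=d2)


def trait_correlation_matrix(means: list[LineMeans]) -> list[CorrelationResult]:
    """All pairwise Pearson correlations among traits' per-line LS means.

    Each pair uses complete-case lines only (lines with a mean for both
    traits); pairs with fewer than 3 shared lines are an input error.
    """
    df = pd.DataFrame([(m.line_id, m.trait, m.lsmean) for m in means], columns=["line_id", "trait", "lsmean"])
    traits = sorted(df["trait"].unique())
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    wide = df.pivot(index="line_id", columns="trait", values="lsmean")
    results: list[CorrelationResult] = []
    for tx, ty in combinations(traits, 2):
        pair = wide[[tx, ty]].dropna()
        if len(pair) < 3:
            raise ValueError(f"traits {tx!r} and {ty!r} share fewer than 3 lines")
        res = pearson_correlation(pair[tx].to_numpy(), pair[ty].to_numpy())
        results.append(CorrelationResult(trait_x=tx, trait_y=ty, r=res.r, p_value=res.p_value, n=res.n))
    return results
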