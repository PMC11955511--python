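"""Phenology curves, light/movement summaries, and the rank-test battery.

Seasonal phenology is summarized by a locally weighted regression (loess:
tricube weights, locally quadratic, default span 0.75) of daily observation
counts against day-of-year. Light use is the fraction of follow time spent
in sun; movement level is the summed linear distance between consecutive
waypoints of a follow.

Group comparisons use the field's standard nonparametric battery:
Kruskal-Wallis across species, Dunn's pairwise post-hoc test with Bonferroni
correction, and the Scheirer-Ray-Hare (SRH) two-way rank test for species,
sex, and their interaction. All tests use midranks; the Kruskal-Wallis and
Dunn denominators carry the usual tie correction 1 - sum(t^3 - t)/(N^3 - N).
The SRH statistic divides each effect's rank sum of squares by the sample
variance of the midranks, which is algebraically identical to applying that
same tie correction, so a single-factor SRH equals tie-corrected
Kruskal-Wallis exactly. Unbalanced designs are handled with sequential
(type-I) sums of squares in the order species, sex, interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import LightBoutSeries, Track

__all__ = [
    "RankTestResult",
    "phenology_curve",
    "light_fraction",
    "path_length",
    "kruskal_wallis",
    "dunn_test",
    "scheirer_ray_hare",
    "loess",
]


@dataclass(frozen=True)
class RankTestResult:
    """One test (or one pairwise comparison) from the rank battery."""

    test: str
    statistic_name: str  # "H", "X2" or "Z"
    statistic: float
    df: int | None
    p: float
    comparison: str | None = None
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# smoothing


def loess(
    x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point the nearest ``ceil(span * n)`` observations are
    fit by weighted least squares of the given degree; weights are tricube in
    the distance scaled by the window radius.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} observations, got {n}")
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = np.clip(1 - (d[idx] / dmax) ** 3, 0, None) ** 3
            if w.sum() <= 0:
                w = np.ones(q)
        # weighted polynomial fit, centered at x0 for conditioning
        deg = min(degree, len(np.unique(x[idx])) - 1)
        coeffs = np.polynomial.polynomial.polyfit(x[idx] - x0, y[idx], deg, w=np.sqrt(w))
        out[i] = coeffs[0]
    return out


def phenology_curve(
    dates_by_group: dict[str, list[int]],
    span: float = 0.75,
    min_obs: int = 5,
) -> pd.DataFrame:
    """Smoothed daily abundance per group over the pooled season.

    ``dates_by_group`` maps a group label to its observation days-of-year.
    Daily counts (zeros included) are formed over the pooled day range and
    loess-smoothed per group. Groups with fewer than ``min_obs`` observations
    are skipped with a warning. Returns a tidy frame with columns
    ``group, day, count, smoothed``.
    """
    all_days = [d for ds in dates_by_group.values() for d in ds]
    if not all_days:
        raise ValueError("no observation dates supplied")
    grid = np.arange(min(all_days), max(all_days) + 1)
    frames = []
    for group, ds in dates_by_group.items():
        if len(ds) < min_obs:
            warnings.warn(
                f"group {group!r} has {len(ds)} < {min_obs} observations; skipped"
            )
            continue
        counts = np.array([np.sum(np.asarray(ds) == day) for day in grid], dtype=float)
        smoothed = loess(grid, counts, grid, span=span)
        frames.append(
            pd.DataFrame(
                {"group": group, "day": grid, "count": counts, "smoothed": smoothed}
            )
        )
    if not frames:
        raise ValueError("no group met the minimum observation count")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# per-individual summaries


def light_fraction(series: LightBoutSeries) -> float:
    """Fraction of total follow time spent in sun."""
    series.validate()
    sun = sum(b.end - b.start for b in series.bouts if b.state == "sun")
    total = sum(b.end - b.start for b in series.bouts)
    return sun / total


def path_length(track: Track) -> float:
    """Summed Euclidean distance (m) between consecutive waypoints; 0 if single."""
    track.validate()
    if len(track.waypoints) < 2:
        return 0.0
    xy = np.array([(w.x, w.y) for w in track.waypoints])
    return float(np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# rank tests


def _tie_term(values: np.ndarray) -> float:
    """sum over tied groups of t^3 - t."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list) -> RankTestResult:
    """Kruskal-Wallis H across groups (midranks, tie-corrected, chi-square p).

    All values identical returns H = 0, p = 1 rather than raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need at least 3 values in total")
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return RankTestResult("kruskal_wallis", "H", 0.0, df, 1.0)
    h, p = stats.kruskal(*groups)
    return RankTestResult("kruskal_wallis", "H", float(h), df, float(p))


def dunn_test(
    groups: dict[str, list] | list,
    family: str = "bonferroni",
) -> list[RankTestResult]:
    """Dunn's pairwise post-hoc z tests on the Kruskal-Wallis ranks.

    Z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T = sum(t^3 - t) over tied values; two-sided normal p, Bonferroni
    adjusted over all k(k-1)/2 comparisons (the only supported family).
    """
    if family != "bonferroni":
        raise ValueError(f"unsupported correction family {family!r}")
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(data))]
    if len(data) < 2 or any(len(g) == 0 for g in data):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(data)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in data]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    tie = _tie_term(pooled)
    var_base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    m = len(data) * (len(data) - 1) // 2
    out = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
            out.append(
                RankTestResult(
                    test="dunn",
                    statistic_name="Z",
                    statistic=float(z),
                    df=None,
                    p=float(p),
                    comparison=f"{labels[i]} vs {labels[j]}",
                    p_adjusted=float(min(1.0, p * m)),
                )
            )
    return out


def scheirer_ray_hare(
    values, factor_a, factor_b, factor_names: tuple[str, str] = ("species", "sex")
) -> dict[str, RankTestResult]:
    """Scheirer-Ray-Hare two-way test on ranks.

    Values are midranked; sequential (type-I) sums of squares are computed on
    the ranks for factor A, factor B, and A x B in that order; each effect's
    H = SS_effect / MS_total with MS_total the sample variance of the ranks,
    compared to chi-square with the effect's df. Empty cells are tolerated
    (with a warning): the fit simply uses the populated cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a, dtype=object)
    b = np.asarray(factor_b, dtype=object)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels differ in length")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("each factor needs at least 2 levels")
    name_a, name_b = factor_names

    cells = pd.crosstab(pd.Series(a), pd.Series(b))
    if (cells.to_numpy() == 0).any():
        warnings.warn("empty factor cells: SRH computed on available data")

    ranks = stats.rankdata(y)
    ms_total = float(np.var(ranks, ddof=1))
    if ms_total == 0:  # all values identical
        dfs = {
            name_a: len(np.unique(a)) - 1,
            name_b: len(np.unique(b)) - 1,
            f"{name_a}:{name_b}": (len(np.unique(a)) - 1) * (len(np.unique(b)) - 1),
        }
        return {
            eff: RankTestResult("scheirer_ray_hare", "H", 0.0, d, 1.0, comparison=eff)
            for eff, d in dfs.items()
        }

    df_fit = pd.DataFrame({"rank": ranks, "A": a, "B": b})
    model = smf.ols("rank ~ C(A) + C(B) + C(A):C(B)", data=df_fit).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on 0-df residuals
        table = sm.stats.anova_lm(model, typ=1)

    effects = {"C(A)": name_a, "C(B)": name_b, "C(A):C(B)": f"{name_a}:{name_b}"}
    out: dict[str, RankTestResult] = {}
    for row_name, eff in effects.items():
        if row_name not in table.index:
            continue
        ss = float(table.loc[row_name, "sum_sq"])
        df_eff = int(table.loc[row_name, "df"])
        if df_eff <= 0:
            continue
        h = ss / ms_total
        p = float(stats.chi2.sf(h, df_eff))
        out[eff] = RankTestResult(
            "scheirer_ray_hare", "H", float(h), df_eff, p, comparison=eff
        )
    return out
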