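"""Cross-species statistics for testing the satDNA library model.

A shared "library" of satDNA families predicts that interspecies
differences are mostly quantitative: families amplify or contract in
individual lineages while remaining present everywhere. The statistics
here quantify that picture: per-family summary statistics (mean, SD, CV)
across species; z-score standardization of abundance (zs-abun) and
intraspecific divergence (zs-div), optionally excluding the outgroup so
the American-species mean stands in for the ancestral library state;
per-lineage substitution rates calibrated on a dated radiation; a pooled
Student t comparing within- versus between-clade consensus distances; and
a tie-corrected Spearman correlation of abundance against FISH locus
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "StandardizedProfile",
    "TestResult",
    "RateEstimate",
    "summary_stats",
    "z_scores",
    "standardize_profiles",
    "substitution_rate",
    "clade_distance_test",
    "spearman_ties",
    "spearman_t_statistic",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD (n-1) and coefficient of variation (%)."""

    mean: float
    sd: float
    cv_pct: float
    n: int


@dataclass(frozen=True)
class StandardizedProfile:
    species_code: str
    family_id: str
    zs_abun: float
    zs_div: float
    outgroup_excluded: bool


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class RateEstimate:
    """Per-lineage substitution rate from the distance to the outgroup.

    With the radiation dated T Myr ago, the outgroup and each ingroup
    lineage have evolved independently for T Myr each, so the per-lineage
    rate is D / (2T), reported in % per Myr.
    """

    family_id: str
    species_code: str
    p_dist_to_outgroup: float
    time_myr: float
    rate_pct_per_myr: float


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD and CV% of per-species values for one family."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return SummaryStats(mean, sd, 100.0 * sd / mean, int(v.size))


def z_scores(
    values: Mapping[str, float],
    exclude: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Standardize species values against the included species' mean and SD.

    Excluded species (e.g. the outgroup) do not enter the baseline but
    still receive z-scores against it, which is what flags an outgroup
    amplification relative to the ingroup average.
    """
    excluded = set(exclude or ())
    unknown = excluded - set(values)
    if unknown:
        raise KeyError(f"excluded species not in values: {sorted(unknown)}")
    included = {k: v for k, v in values.items() if k not in excluded}
    if len(included) < 3:
        raise ValueError("need at least 3 included species")
    arr = np.array(list(included.values()), dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: all included values equal")
    return {k: (v - mean) / sd for k, v in values.items()}


def standardize_profiles(
    abundance: Mapping[str, float],
    divergence: Mapping[str, float],
    family_id: str,
    exclude: Optional[Iterable[str]] = None,
) -> list[StandardizedProfile]:
    """zs-abun and zs-div for one family across species."""
    if set(abundance) != set(divergence):
        raise ValueError("abundance and divergence cover different species")
    za = z_scores(abundance, exclude)
    zd = z_scores(divergence, exclude)
    flag = bool(exclude)
    return [
        StandardizedProfile(sp, family_id, za[sp], zd[sp], flag)
        for sp in abundance
    ]


def substitution_rate(family_id: str, species_code: str,
                      p_dist_to_outgroup: float,
                      time_myr: float) -> RateEstimate:
    """Rate (%/Myr) = 100 x D / (2T) for a radiation dated T Myr ago."""
    if not 0.0 <= p_dist_to_outgroup <= 1.0:
        raise ValueError("p distance must lie in [0, 1]")
    if time_myr <= 0:
        raise ValueError("time since radiation must be positive")
    rate = 100.0 * p_dist_to_outgroup / (2.0 * time_myr)
    return RateEstimate(family_id, species_code, p_dist_to_outgroup,
                        time_myr, rate)


def clade_distance_test(
    matrix, clade_map: Mapping[str, str],
    outgroup: Optional[str] = None,
) -> TestResult:
    """Pooled-variance Student t on within- vs between-clade distances.

    All unordered species pairs (outgroup excluded) are split by whether
    the two species share a clade. The statistic is
    (mean between - mean within) / SE, so t > 0 means distances are lower
    within clades, i.e. sequence change tracks the phylogeny. df is the
    total number of pairs minus 2. The pairs are not independent (m species
    yield m(m-1)/2 pairs); the test is reported as-is, as is conventional
    for this design.
    """
    labels = [l for l in matrix.labels if l != outgroup]
    missing = [l for l in labels if l not in clade_map]
    if missing:
        raise KeyError(f"species missing from clade map: {missing}")
    clades = {clade_map[l] for l in labels}
    if len(clades) < 2:
        raise ValueError("need at least 2 clades")
    for c in clades:
        if sum(1 for l in labels if clade_map[l] == c) < 2:
            raise ValueError(f"clade {c!r} has fewer than 2 species")
    within, between = [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = matrix.get(a, b)
            (within if clade_map[a] == clade_map[b] else between).append(d)
    if not within or not between:
        raise ValueError("within- or between-clade pair set is empty")
    w = np.asarray(within)
    b = np.asarray(between)
    df = w.size + b.size - 2
    diff = float(b.mean() - w.mean())
    sp2 = ((w.size - 1) * w.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / w.size + 1.0 / b.size))
    eps = 1e-12 * (abs(float(w.mean())) + abs(float(b.mean())) + 1.0)
    if se <= eps:  # degenerate: (near-)constant distances
        t = 0.0 if abs(diff) <= eps else math.copysign(math.inf, diff)
        p = 1.0 if abs(diff) <= eps else 0.0
    else:
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t, df, p, "pooled t, within vs between clades")


def spearman_ties(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Tie-corrected Spearman rank correlation with a t-based p-value.

    Mid-ranks are assigned to ties; rho is the Pearson correlation of the
    rank vectors and t = rho*sqrt(n-2)/sqrt(1-rho^2) with df = n-2.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = int(x.size)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        rho = math.copysign(1.0, rho)
        t = math.inf * rho
        p = 0.0
    else:
        t = rho * math.sqrt(n - 2) / math.sqrt(1.0 - rho * rho)
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(rho, n - 2, p, "Spearman (mid-ranks)")


def spearman_t_statistic(result: TestResult) -> float:
    """The t value paired with a Spearman rho (df = n-2)."""
    rho, df = result.statistic, result.df
    if abs(rho) >= 1.0:
        return math.inf * math.copysign(1.0, rho)
    return rho * math.sqrt(df) / math.sqrt(1.0 - rho * rho)
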