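"""Population vital-sign distribution analytics.

Percentile tables, pooled means with conservative confidence intervals, and
area-normalized histograms over a monitored cohort, pooling every sample
with equal weight (so long-monitored patients contribute proportionally
more, as in a measurement-level database).

Percentiles use the nearest-rank definition — the smallest pooled value
whose rank reaches the requested fraction of the sample, with no
interpolation — which is exactly reproducible across implementations.

Because the pool consists of repeated measures on far fewer patients than
measurements, and the within-patient correlation is unknown, the 95 %
confidence interval for the pooled mean conservatively uses the number of
patients (not measurements) for both the t degrees of freedom and the
standard-error denominator:

    mean +/- t(0.975, df=n_patients) * sd(pooled) / sqrt(n_patients)

The df convention is recorded in the profile metadata and can be switched
to n_patients - 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .timeseries import Cohort, DataError, ParameterError, canonical_channel

__all__ = [
    "DEFAULT_RANKS",
    "NormalizedHistogram",
    "PopulationProfile",
    "ProfileComparison",
    "nearest_rank",
    "pooled_percentiles",
    "pooled_mean_ci",
    "normalized_histogram",
    "population_profile",
    "compare_profiles",
]

#: Percentile ranks of the standard distribution table (plus the median).
DEFAULT_RANKS = (1.0, 5.0, 10.0, 50.0, 90.0, 95.0, 99.0)


def nearest_rank(values: np.ndarray, rank: float) -> float:
    """Nearest-rank percentile of a pool: value at index ceil(r/100 * n)."""
    if not 0 < rank < 100:
        raise ParameterError("percentile ranks must lie in (0, 100)")
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DataError("empty sample pool")
    idx = max(math.ceil(rank / 100.0 * v.size), 1) - 1
    return float(v[idx])


def pooled_percentiles(
    cohort: Cohort, channel: str, ranks: Sequence[float] = DEFAULT_RANKS
) -> dict[float, float]:
    """Nearest-rank percentiles over all samples pooled across patients."""
    pool = cohort.pooled_values(channel)
    if pool.size == 0:
        raise DataError(f"no samples on channel {canonical_channel(channel)}")
    v = np.sort(pool)
    out = {}
    for r in ranks:
        if not 0 < r < 100:
            raise ParameterError("percentile ranks must lie in (0, 100)")
        out[float(r)] = float(v[max(math.ceil(r / 100.0 * v.size), 1) - 1])
    return out


def pooled_mean_ci(
    cohort: Cohort, channel: str, df_mode: str = "patients"
) -> tuple[float, tuple[float, float]]:
    """Pooled mean and conservative 95 % CI (df and SE based on patients)."""
    if df_mode not in ("patients", "patients-1"):
        raise ParameterError("df_mode must be 'patients' or 'patients-1'")
    pool = cohort.pooled_values(channel)
    if pool.size == 0:
        raise DataError(f"no samples on channel {canonical_channel(channel)}")
    n_pat = cohort.n_patients_with(channel)
    if n_pat < 2:
        warnings.warn(
            "confidence interval degenerate with a single patient", stacklevel=2
        )
    mean = float(pool.mean())
    sd = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    df = n_pat if df_mode == "patients" else max(n_pat - 1, 1)
    half = float(stats.t.ppf(0.975, df) * sd / math.sqrt(n_pat))
    return mean, (mean - half, mean + half)


@dataclass(frozen=True)
class NormalizedHistogram:
    """Histogram with per-unit densities whose total area is exactly 1."""

    channel: str
    bin_edges: tuple[float, ...]
    densities: tuple[float, ...]

    @property
    def area(self) -> float:
        edges = np.asarray(self.bin_edges)
        return float(np.sum(np.asarray(self.densities) * np.diff(edges)))


def normalized_histogram(
    cohort: Cohort, channel: str, bin_width: float
) -> NormalizedHistogram:
    """Area-1 histogram on integer-aligned bins spanning the observed range.

    Bin edges are multiples of ``bin_width``; heights are
    count / (total count x bin width).
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    pool = cohort.pooled_values(channel)
    if pool.size == 0:
        raise DataError(f"no samples on channel {canonical_channel(channel)}")
    lo = math.floor(pool.min() / bin_width) * bin_width
    n_bins = max(int(math.ceil((pool.max() - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < pool.max():  # guard float round-off at the top edge
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(pool, bins=edges)
    densities = counts / (pool.size * bin_width)
    return NormalizedHistogram(
        canonical_channel(channel), tuple(map(float, edges)), tuple(map(float, densities))
    )


@dataclass(frozen=True)
class PopulationProfile:
    """One channel's distribution summary: percentiles, mean and 95 % CI."""

    channel: str
    percentiles: Mapping[float, float]
    mean: float
    ci95: tuple[float, float]
    n_patients: int
    n_measurements: int
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = sorted(self.percentiles)
        vals = [self.percentiles[r] for r in ranks]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise DataError("percentile values must be non-decreasing in rank")
        if not self.ci95[0] <= self.mean <= self.ci95[1]:
            raise DataError("mean must lie inside its confidence interval")

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "percentiles": {str(r): v for r, v in sorted(self.percentiles.items())},
            "mean": self.mean,
            "ci95": list(self.ci95),
            "n_patients": self.n_patients,
            "n_measurements": self.n_measurements,
            "metadata": dict(self.metadata),
        }


def population_profile(
    cohort: Cohort,
    channel: str,
    ranks: Sequence[float] = DEFAULT_RANKS,
    df_mode: str = "patients",
) -> PopulationProfile:
    """Full distribution summary for one channel of a cohort."""
    channel = canonical_channel(channel)
    pcts = pooled_percentiles(cohort, channel, ranks)
    mean, ci = pooled_mean_ci(cohort, channel, df_mode=df_mode)
    return PopulationProfile(
        channel=channel,
        percentiles=pcts,
        mean=mean,
        ci95=ci,
        n_patients=cohort.n_patients_with(channel),
        n_measurements=int(cohort.pooled_values(channel).size),
        metadata={
            "percentile_method": "nearest-rank",
            "ci_method": f"mean +/- t(0.975, df=n_{df_mode}) * sd(pooled)/sqrt(n_patients)",
            "weighting": "each pooled measurement weighted equally",
        },
    )


@dataclass(frozen=True)
class ProfileComparison:
    """Signed differences (a - b) between two profiles of one channel."""

    channel: str
    rank_differences: Mapping[float, float]
    mean_difference: float
    tolerance: Optional[float] = None
    within_tolerance: Optional[Mapping[str, bool]] = None

    @property
    def all_within(self) -> Optional[bool]:
        if self.within_tolerance is None:
            return None
        return all(self.within_tolerance.values())


def compare_profiles(
    a: PopulationProfile, b: PopulationProfile, tolerance: float | None = None
) -> ProfileComparison:
    """Compare two distribution summaries at their shared percentile ranks."""
    if a.channel != b.channel:
        raise ParameterError(
            f"channel mismatch: {a.channel} vs {b.channel}"
        )
    shared = sorted(set(a.percentiles) & set(b.percentiles))
    if not shared:
        raise ParameterError("profiles share no percentile ranks")
    diffs = {r: a.percentiles[r] - b.percentiles[r] for r in shared}
    mean_diff = a.mean - b.mean
    within = None
    if tolerance is not None:
        within = {f"p{r:g}": abs(d) <= tolerance for r, d in diffs.items()}
        within["mean"] = abs(mean_diff) <= tolerance
    return ProfileComparison(a.channel, diffs, mean_diff, tolerance, within)
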