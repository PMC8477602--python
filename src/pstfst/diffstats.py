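"""Differentiation statistics: F_ST from allele frequencies and P_ST from phenotypes.

Both statistics measure the proportion of variance (genetic or phenotypic)
attributable to population structure.  P_ST is defined here as

    P_ST = 1 - SSW / SST

the complement of the within-population fraction of the total phenotypic sum
of squares, which is identically the R-squared of a one-way fixed-effects
decomposition by population.  Three additional estimators recover P_ST from
the summary quantities source studies typically publish: a model R-squared,
an F ratio (with optional covariate F ratios), or per-population means and
standard deviations.

F_ST is computed from per-population allele frequencies as

    F_ST = sum_j (p_j - pbar)^2 N_j / ( pbar (1 - pbar) sum_j N_j )

with pbar the census-weighted pooled frequency.

A bounded logit transform (floor 0.005 by default) maps these
proportion-of-variance statistics onto an unbounded, approximately normal
scale on which doubling the between-population variance component shifts the
statistic by exactly ln 2, regardless of the starting level of
differentiation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StatisticKind",
    "ValueSource",
    "PopulationSample",
    "SummaryPhenotype",
    "FRatioTerm",
    "AlleleFrequencySet",
    "DifferentiationValue",
    "LogitValue",
    "fst_single_locus",
    "fst_multilocus",
    "pst_from_raw",
    "pst_from_rsq",
    "pst_from_fratio",
    "pst_from_summary",
    "pst_significance_ftest",
    "logit_bounded",
    "inverse_logit",
    "DEFAULT_LOGIT_FLOOR",
]

DEFAULT_LOGIT_FLOOR = 0.005


class StatisticKind(str, enum.Enum):
    """Which differentiation statistic a value represents."""

    PST = "PST"
    FST_NEUTRAL = "FST_neutral"
    FST_NONNEUTRAL = "FST_nonneutral"


class ValueSource(str, enum.Enum):
    """How a differentiation value was obtained."""

    RAW = "raw"
    RSQ = "rsq"
    FRATIO = "fratio"
    SUMMARY = "summary"
    REPORTED = "reported"
    SIMULATED = "simulated"


@dataclass(frozen=True)
class PopulationSample:
    """Raw phenotype measurements for one population."""

    population_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError(f"population {self.population_id!r}: at least one value required")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"population {self.population_id!r}: non-finite phenotype value")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SummaryPhenotype:
    """Published per-population phenotype summary: mean, SD, and sample size."""

    population_id: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise ValueError(f"population {self.population_id!r}: non-finite summary")
        if self.sd < 0:
            raise ValueError(f"population {self.population_id!r}: sd must be >= 0")
        if self.n < 2:
            raise ValueError(f"population {self.population_id!r}: n must be >= 2")


@dataclass(frozen=True)
class FRatioTerm:
    """One term of a published linear model: its F ratio and degrees of freedom.

    Exactly one term in the set passed to :func:`pst_from_fratio` must carry
    ``is_population_term=True`` (the categorical population variable).
    """

    name: str
    f: float
    df_num: int
    df_den: int
    is_population_term: bool = False

    def __post_init__(self) -> None:
        if self.f < 0 or not math.isfinite(self.f):
            raise ValueError(f"term {self.name!r}: F ratio must be finite and >= 0")
        if self.df_num < 1 or self.df_den < 1:
            raise ValueError(f"term {self.name!r}: degrees of freedom must be >= 1")

    @property
    def variance_ratio(self) -> float:
        """f * df_num / df_den — the term's contribution on the variance-ratio scale."""
        return self.f * self.df_num / self.df_den


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Per-population allele frequencies and census sizes for one locus."""

    locus_id: str
    freqs: tuple[float, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(p) for p in self.freqs)
        sizes = tuple(int(n) for n in self.sizes)
        if len(freqs) != len(sizes):
            raise ValueError(f"locus {self.locus_id!r}: freqs and sizes length mismatch")
        if len(freqs) < 2:
            raise ValueError(f"locus {self.locus_id!r}: insufficient populations")
        if any(p < 0 or p > 1 for p in freqs):
            raise ValueError(f"locus {self.locus_id!r}: allele frequency outside [0, 1]")
        if any(n < 1 for n in sizes):
            raise ValueError(f"locus {self.locus_id!r}: census sizes must be >= 1")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "sizes", sizes)

    @property
    def pooled_frequency(self) -> float:
        """Census-weighted mean allele frequency across populations."""
        n = np.asarray(self.sizes, dtype=float)
        p = np.asarray(self.freqs, dtype=float)
        return float(np.sum(p * n) / np.sum(n))

    @property
    def is_monomorphic(self) -> bool:
        pbar = self.pooled_frequency
        return pbar == 0.0 or pbar == 1.0


@dataclass(frozen=True)
class DifferentiationValue:
    """A proportion-of-variance differentiation statistic with provenance."""

    value: float
    kind: StatisticKind
    source: ValueSource

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"differentiation value {self.value} outside [0, 1]")

    def logit(self, floor: float = DEFAULT_LOGIT_FLOOR) -> "LogitValue":
        return logit_bounded(self.value, floor=floor)


@dataclass(frozen=True)
class LogitValue:
    """A bounded-logit-transformed statistic; records whether the floor clipped it."""

    value: float
    floor_applied: bool
    floor: float = DEFAULT_LOGIT_FLOOR


def fst_single_locus(
    freq_set: AlleleFrequencySet,
    kind: StatisticKind = StatisticKind.FST_NEUTRAL,
) -> DifferentiationValue:
    """F_ST for a single locus from per-population allele frequencies.

    Returns ``sum_j (p_j - pbar)^2 N_j / (pbar (1 - pbar) sum_j N_j)`` with
    pbar the census-weighted pooled frequency.  A monomorphic locus
    (pbar in {0, 1}) expresses no differentiation and returns 0 rather than
    the indeterminate 0/0.  ``kind`` records whether the locus is treated as
    neutral or putatively under selection; the arithmetic is identical.
    """
    p = np.asarray(freq_set.freqs, dtype=float)
    n = np.asarray(freq_set.sizes, dtype=float)
    pbar = freq_set.pooled_frequency
    if pbar == 0.0 or pbar == 1.0 or len(set(freq_set.freqs)) == 1:
        # monomorphic or identical frequencies: no differentiation expressible
        return DifferentiationValue(0.0, kind, ValueSource.RAW)
    num = float(np.sum((p - pbar) ** 2 * n))
    den = pbar * (1.0 - pbar) * float(np.sum(n))
    value = min(1.0, max(0.0, num / den))
    return DifferentiationValue(value, kind, ValueSource.RAW)


def fst_multilocus(
    loci: Sequence[AlleleFrequencySet],
    kind: StatisticKind = StatisticKind.FST_NEUTRAL,
) -> DifferentiationValue:
    """Unweighted mean of per-locus F_ST over polymorphic loci.

    Monomorphic loci carry no information about differentiation and are
    skipped; if every locus is monomorphic there is nothing to average.
    """
    if len(loci) < 1:
        raise ValueError("at least one locus required")
    values = [fst_single_locus(l).value for l in loci if not l.is_monomorphic]
    if not values:
        raise ValueError("no polymorphic loci")
    return DifferentiationValue(float(np.mean(values)), kind, ValueSource.RAW)


def _check_samples(samples: Sequence[PopulationSample]) -> list[np.ndarray]:
    if len(samples) < 2:
        raise ValueError("insufficient populations: at least 2 required")
    arrays = [np.asarray(s.values, dtype=float) for s in samples]
    if sum(a.size for a in arrays) < 2:
        raise ValueError("at least 2 total individuals required")
    return arrays


def pst_from_raw(samples: Sequence[PopulationSample]) -> DifferentiationValue:
    """P_ST from raw per-individual phenotypes: 1 - SSW/SST.

    SSW sums squared deviations of each individual from its own population
    mean; SST sums squared deviations from the grand (metapopulation) mean.
    Equals the R-squared of a one-way fixed-effects ANOVA by population.
    """
    arrays = _check_samples(samples)
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    sst = float(np.sum((pooled - grand) ** 2))
    if sst <= 0.0:
        raise ValueError("degenerate phenotype: zero total variance")
    ssw = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    value = min(1.0, max(0.0, 1.0 - ssw / sst))
    return DifferentiationValue(value, StatisticKind.PST, ValueSource.RAW)


def pst_from_rsq(r2: float) -> DifferentiationValue:
    """P_ST from the R-squared of a model whose only predictor is population."""
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"R-squared {r2} outside [0, 1]")
    return DifferentiationValue(float(r2), StatisticKind.PST, ValueSource.RSQ)


def pst_from_fratio(terms: Sequence[FRatioTerm]) -> DifferentiationValue:
    """P_ST from published F ratios of a linear model containing a population term.

    With v_T = f_T * df_num_T / df_den_T for each term T,

        P_ST = v_pop / (1 + v_pop + sum_{Z != pop} v_Z)

    The population term appears in the denominator so that with no covariates
    the estimator reduces exactly to the one-way R-squared (v/(1+v) with
    v = SSB/SSW), keeping it consistent with the raw-data definition.
    """
    pop_terms = [t for t in terms if t.is_population_term]
    if len(pop_terms) != 1:
        raise ValueError("exactly one population term required")
    v_pop = pop_terms[0].variance_ratio
    v_other = sum(t.variance_ratio for t in terms if not t.is_population_term)
    value = v_pop / (1.0 + v_pop + v_other)
    return DifferentiationValue(value, StatisticKind.PST, ValueSource.FRATIO)


def pst_from_summary(
    summaries: Sequence[SummaryPhenotype],
    convention: str = "printed_n",
) -> DifferentiationValue:
    """P_ST from per-population means, SDs, and sample sizes.

    B = sum_j (mean_j - grand)^2 N_j with the census-weighted grand mean;
    W = sum_j sd_j^2 * N_j       under convention ``"printed_n"``, or
    W = sum_j sd_j^2 * (N_j - 1) under convention ``"sum_of_squares"``.

    Returns the between fraction B / (B + W).  The ``sum_of_squares``
    convention recovers the raw-data P_ST exactly when sd_j are sample
    (n-1 denominator) standard deviations.
    """
    if convention not in ("printed_n", "sum_of_squares"):
        raise ValueError(f"unknown convention {convention!r}")
    if len(summaries) < 2:
        raise ValueError("insufficient populations: at least 2 required")
    n = np.asarray([s.n for s in summaries], dtype=float)
    means = np.asarray([s.mean for s in summaries], dtype=float)
    sds = np.asarray([s.sd for s in summaries], dtype=float)
    grand = float(np.sum(means * n) / np.sum(n))
    b = float(np.sum((means - grand) ** 2 * n))
    w_weights = n if convention == "printed_n" else n - 1.0
    w = float(np.sum(sds**2 * w_weights))
    if b + w <= 0.0:
        raise ValueError("degenerate phenotype: zero total variance")
    return DifferentiationValue(b / (b + w), StatisticKind.PST, ValueSource.SUMMARY)


def pst_significance_ftest(samples: Sequence[PopulationSample]) -> tuple[float, float]:
    """One-way ANOVA F test that P_ST > 0 (population means differ).

    Returns ``(F, p)`` with F on (k-1, N-k) degrees of freedom; p is the
    upper tail of the F distribution.  A comparison passes at p < 0.05.
    """
    arrays = _check_samples(samples)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if n_total - k < 1:
        raise ValueError("insufficient residual degrees of freedom")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    sst = float(np.sum((pooled - grand) ** 2))
    if sst <= 0.0:
        raise ValueError("degenerate phenotype: zero total variance")
    ssw = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    ssb = sst - ssw
    df_num, df_den = k - 1, n_total - k
    if ssw <= 0.0:
        return math.inf, 0.0
    f = (ssb / df_num) / (ssw / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p


def logit_bounded(x: float, floor: float = DEFAULT_LOGIT_FLOOR) -> LogitValue:
    """Natural-log logit with symmetric clamping into [floor, 1 - floor].

    Proportion-of-variance statistics of 0 or 1 have no finite logit; values
    below the floor (or above the ceiling) are clipped before transforming,
    and ``floor_applied`` records that this happened.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"value {x} outside [0, 1]")
    if not (0.0 < floor < 0.5):
        raise ValueError(f"floor {floor} outside (0, 0.5)")
    clamped = min(max(x, floor), 1.0 - floor)
    return LogitValue(
        value=math.log(clamped / (1.0 - clamped)),
        floor_applied=(clamped != x),
        floor=floor,
    )


def inverse_logit(y: float) -> float:
    """Inverse of the natural-log logit, mapping the real line into (0, 1)."""
    return float(1.0 / (1.0 + math.exp(-y)))
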