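"""Synthetic data with known truth for the P_ST / F_ST pipeline.

Two generators:

* a diverging metapopulation — population allele frequencies drawn from the
  Balding-Nichols beta model around a uniform ancestral frequency, diploid
  genotypes sampled binomially, and an additive phenotype built from a chosen
  set of causal loci with environmental noise scaled to a target
  within-population heritability.  True P_ST, neutral F_ST, and non-neutral
  F_ST for every population pair come straight from :mod:`pstfst.diffstats`.

* a fabricated multi-paper comparison database — logit(nnF_ST), a correlated
  logit(neutral F_ST), and a proportion of non-neutral loci are drawn per
  comparison, and logit(P_ST) is assembled from a configurable true slope on
  logit(nnF_ST), a true proportion-of-loci slope, factor-level shifts, and
  Gaussian noise.  The output is a schema-valid list of
  :class:`~pstfst.studydb.StudyRecord`, so the whole ingest/prepare/fit
  pipeline forms a closed loop whose parameters are recoverable.

All draws go through one ``numpy.random.Generator`` seeded from the config,
so every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np

from .diffstats import (
    AlleleFrequencySet,
    PopulationSample,
    StatisticKind,
    fst_multilocus,
    inverse_logit,
    pst_from_raw,
)
from .studydb import StudyRecord, expand_pairwise

__all__ = [
    "ArchitectureConfig",
    "SimulatedMetapop",
    "DatabaseGenConfig",
    "simulate_allele_frequencies",
    "simulate_genotypes_and_phenotypes",
    "simulate_metapop",
    "simulate_study_database",
    "records_from_metapop",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genetic architecture and sampling design of a simulated metapopulation.

    ``fst_neutral`` / ``fst_nonneutral`` are the Balding-Nichols target
    differentiation levels for the two locus classes (non-neutral loci are
    simulated with elevated F as a proxy for directional divergence).
    ``effect_sizes`` are per-causal-locus additive effects (defaults to 1.0
    for every non-neutral locus); ``h2`` is the within-population narrow-sense
    heritability that sets the environmental noise variance.  With
    ``causal_set="neutral"`` the phenotype is built from neutral loci disjoint
    from the flagged non-neutral set — the null in which phenotypic and
    flagged-locus divergence share no mechanism.
    """

    n_pops: int = 2
    n_individuals: int = 30
    n_loci_neutral: int = 500
    n_loci_nonneutral: int = 20
    fst_neutral: float = 0.05
    fst_nonneutral: float = 0.2
    effect_sizes: Optional[tuple[float, ...]] = None
    h2: float = 0.5
    ancestral_low: float = 0.1
    ancestral_high: float = 0.9
    causal_set: str = "nonneutral"  # or "neutral"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_individuals", "n_loci_neutral", "n_loci_nonneutral"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_pops < 2:
            raise ValueError("n_pops must be >= 2")
        for name in ("fst_neutral", "fst_nonneutral"):
            f = getattr(self, name)
            if not (0.0 < f < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]; h2 = 0 leaves no genetic signal to recover")
        if not (0.0 <= self.ancestral_low < self.ancestral_high <= 1.0):
            raise ValueError("ancestral frequency bounds must satisfy 0 <= low < high <= 1")
        if self.causal_set not in ("nonneutral", "neutral"):
            raise ValueError("causal_set must be 'nonneutral' or 'neutral'")

    def resolved_effects(self) -> np.ndarray:
        n_causal = (
            self.n_loci_nonneutral if self.causal_set == "nonneutral" else self.n_loci_neutral
        )
        if self.effect_sizes is None:
            return np.ones(n_causal)
        eff = np.asarray(self.effect_sizes, dtype=float)
        if eff.size > n_causal:
            raise ValueError("more effect sizes than causal loci")
        out = np.zeros(n_causal)
        out[: eff.size] = eff
        return out


@lru_cache(maxsize=64)
def _calibrate_divergence(target_f: float, n_pops: int, low: float, high: float) -> float:
    """Beta parameter F' such that the realized per-locus statistic hits target_f.

    Under Balding-Nichols with parameter F', population frequencies are
    Beta(pbar (1-F')/F', (1-pbar) (1-F')/F') with variance F' pbar (1-pbar).
    The realized Box-2 statistic centres frequencies on the *sample* pooled
    mean, which absorbs 1/k of the between-population variance (and its ratio
    form adds Jensen curvature), so its expectation sits below F' — severely
    so for two populations.  We solve E[statistic | F'] = target_f by
    root-finding on a common-random-numbers Monte Carlo estimate of the
    expectation (fixed internal draws pushed through the beta quantile
    function, so the objective is deterministic and smooth in F').
    """
    from scipy import optimize, stats

    crn = np.random.default_rng(987654321)
    n_mc = 8000
    u = crn.uniform(size=(n_mc, n_pops))
    ancestral = crn.uniform(low, high, size=n_mc)[:, None]

    def realized_mean(f: float) -> float:
        shape = (1.0 - f) / f
        p = stats.beta.ppf(u, ancestral * shape, (1.0 - ancestral) * shape)
        pbar = p.mean(axis=1)
        ok = (pbar > 0) & (pbar < 1)
        num = ((p - pbar[:, None]) ** 2).sum(axis=1)
        den = n_pops * pbar * (1.0 - pbar)
        return float((num[ok] / den[ok]).mean())

    lo, hi = 1e-8, 1.0 - 1e-8
    if realized_mean(hi) <= target_f:
        return hi
    return float(optimize.brentq(lambda f: realized_mean(f) - target_f, lo, hi, xtol=1e-10))


def _balding_nichols(
    rng: np.random.Generator,
    n_loci: int,
    n_pops: int,
    fst: float,
    low: float,
    high: float,
    n_ind: int,
    prefix: str,
) -> list[AlleleFrequencySet]:
    """Beta-distributed population frequencies around uniform ancestral ones.

    The beta parameter is calibrated (see :func:`_calibrate_divergence`) so
    that the mean realized single-locus statistic across loci matches the
    requested ``fst``, not just the parametric variance ratio.
    """
    ancestral = rng.uniform(low, high, size=n_loci)
    f_eff = _calibrate_divergence(float(fst), int(n_pops), float(low), float(high))
    shape = (1.0 - f_eff) / f_eff
    out = []
    for i, pbar in enumerate(ancestral):
        freqs = rng.beta(pbar * shape, (1.0 - pbar) * shape, size=n_pops)
        out.append(
            AlleleFrequencySet(
                locus_id=f"{prefix}{i}",
                freqs=tuple(np.clip(freqs, 0.0, 1.0)),
                sizes=(n_ind,) * n_pops,
            )
        )
    return out


def simulate_allele_frequencies(
    config: ArchitectureConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[AlleleFrequencySet]]:
    """Draw per-locus, per-population allele frequencies for both locus classes."""
    rng = rng or np.random.default_rng(config.seed)
    return {
        "neutral": _balding_nichols(
            rng,
            config.n_loci_neutral,
            config.n_pops,
            config.fst_neutral,
            config.ancestral_low,
            config.ancestral_high,
            config.n_individuals,
            "neu_",
        ),
        "nonneutral": _balding_nichols(
            rng,
            config.n_loci_nonneutral,
            config.n_pops,
            config.fst_nonneutral,
            config.ancestral_low,
            config.ancestral_high,
            config.n_individuals,
            "nn_",
        ),
    }


@dataclass
class SimulatedMetapop:
    """Realized genotypes, phenotypes, and per-pair truth statistics."""

    config: ArchitectureConfig
    neutral_freqs: list[AlleleFrequencySet]
    nonneutral_freqs: list[AlleleFrequencySet]
    genotypes: np.ndarray  # individuals x loci, values in {0, 1, 2}
    locus_ids: list[str]
    population_labels: list[str]  # one per individual (row of genotypes)
    phenotypes: np.ndarray  # one per individual
    truth: dict[tuple[str, str], dict[str, float]]  # per-pair P_ST / F_ST / nnF_ST

    @property
    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for lab in self.population_labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def _pair_subset(loci: Sequence[AlleleFrequencySet], i: int, j: int) -> list[AlleleFrequencySet]:
    return [
        AlleleFrequencySet(
            locus_id=l.locus_id,
            freqs=(l.freqs[i], l.freqs[j]),
            sizes=(l.sizes[i], l.sizes[j]),
        )
        for l in loci
    ]


def simulate_genotypes_and_phenotypes(
    config: ArchitectureConfig,
    freqs: Optional[dict[str, list[AlleleFrequencySet]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedMetapop:
    """Sample genotypes and an additive phenotype; compute per-pair truth.

    Diploid genotypes are Binomial(2, p_j) per locus and population.  The
    genetic value is the effect-weighted genotype sum over the causal loci;
    environmental noise has variance Vg_within (1 - h2) / h2, with Vg_within
    the mean within-population genetic variance, so the realized
    within-population heritability matches ``config.h2`` in expectation.
    """
    rng = rng or np.random.default_rng(config.seed)
    if freqs is None:
        freqs = simulate_allele_frequencies(config, rng)
    neutral, nonneutral = freqs["neutral"], freqs["nonneutral"]

    n_ind, n_pops = config.n_individuals, config.n_pops
    all_loci = neutral + nonneutral
    pop_names = [f"pop{j}" for j in range(n_pops)]

    blocks = []
    for j in range(n_pops):
        p_j = np.array([l.freqs[j] for l in all_loci])
        blocks.append(rng.binomial(2, p_j, size=(n_ind, len(all_loci))))
    genotypes = np.vstack(blocks)
    labels = [pop_names[j] for j in range(n_pops) for _ in range(n_ind)]

    causal_slice = (
        slice(len(neutral), len(all_loci))
        if config.causal_set == "nonneutral"
        else slice(0, len(neutral))
    )
    effects = config.resolved_effects()
    genetic = genotypes[:, causal_slice] @ effects

    within_vars = [
        np.var(genetic[j * n_ind : (j + 1) * n_ind], ddof=1) for j in range(n_pops)
    ]
    vg_within = float(np.mean(within_vars))
    noise_var = vg_within * (1.0 - config.h2) / config.h2
    noise = rng.normal(0.0, math.sqrt(noise_var), size=genetic.size) if noise_var > 0 else 0.0
    phenotypes = genetic + noise

    truth: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in expand_pairwise(pop_names):
        i, j = pop_names.index(a), pop_names.index(b)
        samples = [
            PopulationSample(a, tuple(phenotypes[i * n_ind : (i + 1) * n_ind])),
            PopulationSample(b, tuple(phenotypes[j * n_ind : (j + 1) * n_ind])),
        ]
        truth[(a, b)] = {
            "pst": pst_from_raw(samples).value,
            "fst_neutral": fst_multilocus(_pair_subset(neutral, i, j)).value,
            "fst_nonneutral": fst_multilocus(
                _pair_subset(nonneutral, i, j), kind=StatisticKind.FST_NONNEUTRAL
            ).value,
        }

    return SimulatedMetapop(
        config=config,
        neutral_freqs=neutral,
        nonneutral_freqs=nonneutral,
        genotypes=genotypes,
        locus_ids=[l.locus_id for l in all_loci],
        population_labels=labels,
        phenotypes=np.asarray(phenotypes),
        truth=truth,
    )


def simulate_metapop(config: ArchitectureConfig) -> SimulatedMetapop:
    """Frequencies + genotypes + phenotypes + truth, in one seeded call."""
    rng = np.random.default_rng(config.seed)
    return simulate_genotypes_and_phenotypes(config, simulate_allele_frequencies(config, rng), rng)


# ---------------------------------------------------------------------------
# Fabricated multi-paper comparison database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatabaseGenConfig:
    """True statistical structure of a fabricated comparison database.

    Defaults emulate the heterogeneous multi-study database the congruence
    models are designed for: ~31 papers contributing a few population-pair
    comparisons each, a true logit(P_ST)-on-logit(nnF_ST) slope of 0.43, a
    negative proportion-of-non-neutral-loci effect of -0.3, and enough
    residual noise that the global fit explains a modest share of variance.
    ``slope_sd`` adds paper x phenotype slope heterogeneity for within-study
    analyses; ``factor_effects`` maps factor level -> intercept shift (e.g.
    ``{"marker": {"aflp": 0.5}}``); ``slope_effects`` does the same for the
    factor x logit(nnF_ST) interaction.
    """

    n_papers: int = 31
    comparisons_per_paper: int = 3
    phenotypes_per_paper: int = 1
    beta_0: float = 0.0
    true_slope: float = 0.43
    true_beta_l: float = -0.3
    slope_sd: float = 0.0
    residual_sd: float = 1.1
    nn_logit_mean: float = -2.0
    nn_logit_sd: float = 1.5
    neutral_offset: float = -1.0
    neutral_noise_sd: float = 0.5
    prop_logit_mean: float = -2.2
    prop_logit_sd: float = 1.0
    prop_within_sd: float = 0.3
    factor_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    slope_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_papers < 1 or self.comparisons_per_paper < 1 or self.phenotypes_per_paper < 1:
            raise ValueError("counts must be >= 1")


def records_from_metapop(
    sim: SimulatedMetapop,
    paper_id: str,
    phenotype_id: str = "trait00",
    method: str = "outlier",
    analysis_group: str = "non_bayesian",
    marker: str = "snp",
    rng: Optional[np.random.Generator] = None,
) -> list[StudyRecord]:
    """Convert a simulated metapopulation's per-pair truth into study records.

    One record per population pair, carrying the true P_ST, neutral F_ST, and
    nnF_ST.  The flagged non-neutral locus count is jittered (+/- up to 20%)
    per pair when an ``rng`` is given, emulating outlier scans that flag
    slightly different locus sets for different pairs (and keeping the
    proportion-of-loci covariate from being confounded with study identity).
    """
    cfg = sim.config
    n_total = cfg.n_loci_neutral + cfg.n_loci_nonneutral
    out = []
    for (a, b), t in sorted(sim.truth.items()):
        n_nn = cfg.n_loci_nonneutral
        if rng is not None:
            jitter = max(1, int(round(cfg.n_loci_nonneutral * 0.2)))
            n_nn = int(np.clip(n_nn + rng.integers(-jitter, jitter + 1), 1, n_total))
        out.append(
            StudyRecord(
                paper_id=paper_id,
                species=paper_id,
                phenotype_id=phenotype_id,
                pop_a=a,
                pop_b=b,
                pst=t["pst"],
                fst_neutral=t["fst_neutral"],
                fst_nonneutral=t["fst_nonneutral"],
                n_loci_nonneutral=n_nn,
                n_loci_total=n_total,
                mean_n_individuals=float(cfg.n_individuals),
                method=method,
                marker=marker,
                analysis_group=analysis_group,
                common_garden=False,
            )
        )
    return out


_MARKER_POOL = ("snp", "msat", "aflp", "qtl")
_METHOD_POOL = ("outlier", "candidate", "gwas")
_ANALYSIS_POOL = ("non_bayesian", "bayesian", "raw", "gwas_specific")


def _pairs_for(n_comparisons: int) -> list[tuple[str, str]]:
    k = 2
    while k * (k - 1) // 2 < n_comparisons:
        k += 1
    return expand_pairwise([f"P{i:02d}" for i in range(k)])[:n_comparisons]


def simulate_study_database(config: DatabaseGenConfig) -> list[StudyRecord]:
    """Fabricate a schema-valid multi-paper comparison database.

    Per paper: a marker, method, software group, common-garden flag, total
    locus count, and mean sample size are drawn once.  Per comparison and
    phenotype: logit(nnF_ST) ~ N(nn_logit_mean, nn_logit_sd^2), logit(neutral
    F_ST) = logit(nnF_ST) + neutral_offset + noise (the strong empirical
    coupling of the two F_ST kinds), and the proportion of non-neutral loci
    is logit-normal around a per-paper mean.  Then

        logit(P_ST) = beta_0 + slope_zc * logit(nnF_ST)
                      + beta_L * logit(realized proportion)
                      + factor shifts + N(0, residual_sd^2)

    with slope_zc = true_slope + N(0, slope_sd^2) drawn per paper x phenotype.
    The proportion entering the predictor is the realized count ratio
    n_nonneutral / n_total after rounding, so generator parameters are
    recoverable from the emitted records alone.
    """
    rng = np.random.default_rng(config.seed)
    records: list[StudyRecord] = []
    for ip in range(config.n_papers):
        paper = f"paper{ip:03d}"
        marker = str(rng.choice(_MARKER_POOL))
        method = str(rng.choice(_METHOD_POOL))
        analysis = "gwas_specific" if method == "gwas" else str(
            rng.choice([g for g in _ANALYSIS_POOL if g != "gwas_specific"])
        )
        garden = bool(rng.random() < 0.3)
        n_total = int(rng.integers(100, 5000))
        mean_n = float(rng.uniform(10, 150))
        prop_mean_paper = rng.normal(config.prop_logit_mean, config.prop_logit_sd)

        shift = 0.0
        for factor, levels in config.factor_effects.items():
            level = {
                "marker": marker,
                "method": method,
                "analysis_group": analysis,
                "common_garden": "yes" if garden else "no",
            }[factor]
            shift += levels.get(level, 0.0)
        slope_shift = 0.0
        for factor, levels in config.slope_effects.items():
            level = {
                "marker": marker,
                "method": method,
                "analysis_group": analysis,
                "common_garden": "yes" if garden else "no",
            }[factor]
            slope_shift += levels.get(level, 0.0)

        pairs = _pairs_for(config.comparisons_per_paper)
        for iph in range(config.phenotypes_per_paper):
            phen = f"trait{iph:02d}"
            slope = config.true_slope + (
                rng.normal(0.0, config.slope_sd) if config.slope_sd > 0 else 0.0
            )
            for pop_a, pop_b in pairs:
                l_nn = rng.normal(config.nn_logit_mean, config.nn_logit_sd)
                l_neu = l_nn + config.neutral_offset + rng.normal(0.0, config.neutral_noise_sd)
                l_prop = prop_mean_paper + rng.normal(0.0, config.prop_within_sd)
                n_nn = int(np.clip(round(inverse_logit(l_prop) * n_total), 1, n_total))
                realized_l_prop = math.log(n_nn / n_total / (1.0 - n_nn / n_total)) if n_nn < n_total else l_prop
                l_pst = (
                    config.beta_0
                    + (slope + slope_shift) * l_nn
                    + config.true_beta_l * realized_l_prop
                    + shift
                    + rng.normal(0.0, config.residual_sd)
                )
                records.append(
                    StudyRecord(
                        paper_id=paper,
                        species=f"species{ip:03d}",
                        phenotype_id=phen,
                        pop_a=pop_a,
                        pop_b=pop_b,
                        pst=inverse_logit(l_pst),
                        fst_neutral=inverse_logit(l_neu),
                        fst_nonneutral=inverse_logit(l_nn),
                        n_loci_nonneutral=n_nn,
                        n_loci_total=n_total,
                        mean_n_individuals=mean_n,
                        method=method,
                        marker=marker,
                        analysis_group=analysis,
                        common_garden=garden,
                    )
                )
    return records
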