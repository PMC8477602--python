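"""Readers and writers for the raw-data side of the statistics core.

Formats are deliberately plain delimited text:

* phenotype table — columns ``population_id, individual_id, trait_id, value``;
* allele-frequency table — columns ``locus_id, population_id, freq, n``;
* genotype matrix — one row per individual (``individual_id`` first column,
  then one column per locus with dosages in {0, 1, 2}) plus a two-column
  ``individual_id, population_id`` map, from which per-population allele
  frequencies and census sizes are computed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .diffstats import (
    DEFAULT_LOGIT_FLOOR,
    AlleleFrequencySet,
    DifferentiationValue,
    PopulationSample,
)

__all__ = [
    "read_phenotype_table",
    "read_allele_frequency_table",
    "read_genotype_matrix",
    "statistic_record",
    "write_phenotype_table",
    "write_allele_frequency_table",
]


def read_phenotype_table(path: str | Path) -> dict[str, list[PopulationSample]]:
    """Read raw phenotypes; returns one list of PopulationSamples per trait."""
    df = pd.read_csv(path)
    required = {"population_id", "individual_id", "trait_id", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[PopulationSample]] = {}
    for trait, tgrp in df.groupby("trait_id", sort=True):
        out[str(trait)] = [
            PopulationSample(str(pop), tuple(pgrp["value"].astype(float)))
            for pop, pgrp in tgrp.groupby("population_id", sort=True)
        ]
    return out


def write_phenotype_table(
    samples_by_trait: dict[str, list[PopulationSample]], path: str | Path
) -> None:
    rows = []
    for trait, samples in samples_by_trait.items():
        for s in samples:
            for i, v in enumerate(s.values):
                rows.append(
                    {
                        "population_id": s.population_id,
                        "individual_id": f"{s.population_id}_{i}",
                        "trait_id": trait,
                        "value": v,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_allele_frequency_table(path: str | Path) -> list[AlleleFrequencySet]:
    """Read per-population allele frequencies, one AlleleFrequencySet per locus."""
    df = pd.read_csv(path)
    required = {"locus_id", "population_id", "freq", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for locus, grp in df.groupby("locus_id", sort=True):
        grp = grp.sort_values("population_id")
        out.append(
            AlleleFrequencySet(
                locus_id=str(locus),
                freqs=tuple(grp["freq"].astype(float)),
                sizes=tuple(grp["n"].astype(int)),
            )
        )
    return out


def write_allele_frequency_table(
    loci: Iterable[AlleleFrequencySet],
    population_ids: list[str],
    path: str | Path,
) -> None:
    rows = []
    for l in loci:
        for pop, p, n in zip(population_ids, l.freqs, l.sizes):
            rows.append({"locus_id": l.locus_id, "population_id": pop, "freq": p, "n": n})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotype_matrix(
    matrix_path: str | Path, population_map_path: str | Path
) -> list[AlleleFrequencySet]:
    """Compute allele frequencies from a 0/1/2 genotype matrix.

    The allele frequency in population j is the mean dosage / 2 over its
    individuals; the census size is the individual count.
    """
    geno = pd.read_csv(matrix_path)
    if "individual_id" not in geno.columns:
        raise ValueError(f"{matrix_path}: missing individual_id column")
    popmap = pd.read_csv(population_map_path)
    if not {"individual_id", "population_id"} <= set(popmap.columns):
        raise ValueError(f"{population_map_path}: need individual_id and population_id")
    merged = geno.merge(popmap[["individual_id", "population_id"]], on="individual_id")
    if len(merged) < len(geno):
        raise ValueError("individuals missing from the population map")
    loci = [c for c in geno.columns if c != "individual_id"]
    bad = merged[loci].stack()
    if not bad.isin([0, 1, 2]).all():
        raise ValueError("genotype dosages must be in {0, 1, 2}")
    out = []
    pops = sorted(merged["population_id"].unique())
    for locus in loci:
        freqs, sizes = [], []
        for pop in pops:
            sub = merged.loc[merged["population_id"] == pop, locus]
            freqs.append(float(sub.mean() / 2.0))
            sizes.append(int(len(sub)))
        out.append(AlleleFrequencySet(locus_id=str(locus), freqs=tuple(freqs), sizes=tuple(sizes)))
    return out


def statistic_record(
    value: DifferentiationValue, floor: float = DEFAULT_LOGIT_FLOOR
) -> dict:
    """Emit a differentiation value as a flat record with its bounded logit."""
    lv = value.logit(floor)
    return {
        "statistic_kind": value.kind.value,
        "source": value.source.value,
        "value": value.value,
        "logit_value": lv.value,
        "floor_applied": lv.floor_applied,
    }
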