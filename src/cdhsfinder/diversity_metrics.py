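"""Defense-repertoire diversity: p_sys, Shannon entropy, genome fractions
and rarefaction curves.

For a species, p_sys of a system is that system's occurrence count divided
by the total count of all system occurrences in the species (multiset
counting: every instance counts, including multiple instances within one
genome). Shannon entropy of defense, H = -sum p_sys * log2(p_sys), is the
diversity proxy used to rank species. The per-genome presence variant
(fraction of genomes carrying at least one instance) is kept separate as
``genome_fraction``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeDB
from .system_caller import SystemCall

DEFAULT_MIN_GENOMES = 200


@dataclass
class DefenseRepertoire:
    species: str
    system_counts: dict[str, int] = field(default_factory=dict)
    genome_count: int = 0
    genomes_with_system: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.system_counts.values())


@dataclass
class RarefactionCurve:
    points: list[tuple[int, float, float]]  # (n_genomes, mean, sd)
    replicates: int
    seed: int


def build_repertoires(
    calls: Sequence[SystemCall], db: GenomeDB
) -> dict[str, DefenseRepertoire]:
    """Aggregate system calls into one repertoire per species."""
    reps: dict[str, DefenseRepertoire] = {}
    for species, genome_ids in db.species_index.items():
        rep = DefenseRepertoire(species=species, genome_count=len(genome_ids))
        reps[species] = rep
    genome_species = {g.genome_id: g.species for g in db.genomes.values()}
    seen_pairs: set[tuple[str, str]] = set()
    for call in calls:
        species = genome_species[call.genome_id]
        rep = reps[species]
        rep.system_counts[call.system_name] = (
            rep.system_counts.get(call.system_name, 0) + 1
        )
        pair = (call.genome_id, call.system_name)
        if pair not in seen_pairs:
            seen_pairs.add(pair)
            rep.genomes_with_system[call.system_name] = (
                rep.genomes_with_system.get(call.system_name, 0) + 1
            )
    return reps


def system_frequency(rep: DefenseRepertoire, system: str) -> float:
    """p_sys: occurrences of ``system`` over all system occurrences."""
    total = rep.total_count
    if total == 0:
        raise ValueError(f"repertoire for {rep.species} is empty")
    return rep.system_counts.get(system, 0) / total


def shannon_entropy(rep: DefenseRepertoire) -> float:
    """H = -sum p log2 p over systems present, in bits."""
    total = rep.total_count
    if total == 0:
        raise ValueError(f"repertoire for {rep.species} is empty")
    h = 0.0
    for count in rep.system_counts.values():
        if count > 0:
            p = count / total
            h -= p * math.log2(p)
    return h


def genome_fraction(rep: DefenseRepertoire, system: str) -> float:
    """Fraction of the species' genomes carrying >= 1 instance."""
    if rep.genome_count == 0:
        raise ValueError(f"no genomes for {rep.species}")
    return rep.genomes_with_system.get(system, 0) / rep.genome_count


def genome_fraction_table(
    rep: DefenseRepertoire, min_fraction: float | None = 0.01
) -> pd.DataFrame:
    """Per-system genome fractions, optionally filtered at a floor
    (default: keep systems present in at least 1% of genomes)."""
    rows = [
        {"system_name": s, "genome_fraction": genome_fraction(rep, s)}
        for s in sorted(rep.genomes_with_system)
    ]
    df = pd.DataFrame(rows, columns=["system_name", "genome_fraction"])
    if min_fraction is not None and len(df):
        df = df[df["genome_fraction"] >= min_fraction].reset_index(drop=True)
    return df.sort_values(
        ["genome_fraction", "system_name"], ascending=[False, True]
    ).reset_index(drop=True)


def species_entropy_table(
    calls: Sequence[SystemCall],
    db: GenomeDB,
    min_genomes: int = DEFAULT_MIN_GENOMES,
) -> pd.DataFrame:
    """One row per species with >= ``min_genomes`` genomes, sorted by
    defense entropy descending. Species with no calls get entropy 0."""
    reps = build_repertoires(calls, db)
    rows = []
    for species, rep in reps.items():
        if rep.genome_count < min_genomes:
            continue
        h = shannon_entropy(rep) if rep.total_count else 0.0
        rows.append(
            {"species": species, "entropy_bits": h,
             "n_genomes": rep.genome_count, "n_systems": rep.total_count}
        )
    df = pd.DataFrame(
        rows, columns=["species", "entropy_bits", "n_genomes", "n_systems"]
    )
    return df.sort_values(
        ["entropy_bits", "species"], ascending=[False, True]
    ).reset_index(drop=True)


def rarefaction(
    calls: Sequence[SystemCall],
    db: GenomeDB,
    replicates: int = 100,
    seed: int = 0,
    n_points: int = 10,
) -> RarefactionCurve:
    """Expected number of distinct system types as genomes are sampled.

    For each n on an evenly spaced grid up to the genome count, sample n
    genomes without replacement ``replicates`` times and count distinct
    system names; report mean and sd per n.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    genome_ids = sorted(db.genomes)
    systems_by_genome: dict[str, set[str]] = {g: set() for g in genome_ids}
    for c in calls:
        systems_by_genome[c.genome_id].add(c.system_name)
    n_genomes = len(genome_ids)
    grid = sorted(
        {max(1, round(n_genomes * i / n_points)) for i in range(1, n_points + 1)}
    )
    rng = np.random.default_rng(seed)
    points = []
    for n in grid:
        counts = []
        for _ in range(replicates):
            sample = rng.choice(genome_ids, size=n, replace=False)
            distinct: set[str] = set()
            for g in sample:
                distinct |= systems_by_genome[g]
            counts.append(len(distinct))
        arr = np.asarray(counts, dtype=float)
        points.append((int(n), float(arr.mean()), float(arr.std(ddof=0))))
    return RarefactionCurve(points=points, replicates=replicates, seed=seed)


def write_rarefaction(curve: RarefactionCurve, path: str) -> None:
    pd.DataFrame(
        curve.points, columns=["n_genomes", "mean_unique_systems", "sd"]
    ).to_csv(path, sep="\t", index=False)
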