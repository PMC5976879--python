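"""Survey summaries: per-species BSH content, category breakdown,
multiplicity, and lifestyle cross-tabulation.

Takes per-strain classification counts plus strain metadata and produces
the survey's summary artifacts: a per-species table of BSH-positive
strain counts (species with no positive strain are listed separately in
a companion full table), the four-way PVA/BSH/both/neither species
percentages, the distribution of per-strain BSH copy number across
species, and the lifestyle cross-tabulation of encoding species.

Counting is inclusive: a species "encodes BSH" when at least one strain
carries at least one BSH protein, and the BSH and PVA sets both include
the species encoding both — the only reading under which
``pva + bsh - both + neither == total`` holds for the published counts
(82 + 39 - 8 + 57 = 170).  Percentages round half-up: two decimals for
tables, whole percents for the multiplicity figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .seqio import StrainMetadata


def _round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    if denominator == 0:
        return 0.0
    return _round_half_up(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True)
class StrainCallRecord:
    """Classified protein counts for one strain."""

    species: str
    strain: str
    n_bsh: int
    n_pva: int

    def __post_init__(self) -> None:
        if self.n_bsh < 0 or self.n_pva < 0:
            raise ValidationError("protein counts must be >= 0")


@dataclass(frozen=True)
class SpeciesSummary:
    """One row of the per-species BSH content table."""

    species: str
    total_strains: int
    n_with_bsh: int
    pct_with_bsh: float
    n_with_exactly_1: int
    n_with_exactly_2: int
    n_with_exactly_3: int


@dataclass(frozen=True)
class CategoryBreakdown:
    """Species counted by enzyme repertoire (inclusive counting)."""

    n_species_pva: int
    n_species_bsh: int
    n_species_both: int
    n_species_neither: int
    pct_pva: float
    pct_bsh: float
    pct_both: float
    pct_neither: float
    total_species: int


def summarize_species(records: Sequence[StrainCallRecord]) -> list[SpeciesSummary]:
    """Per-species summary of BSH-positive strains.

    Only species with at least one BSH-positive strain appear (the
    published table's semantics); use :func:`full_species_table` for the
    all-species view.  Strains with more than three copies count in the
    three-copy column.
    """
    if not records:
        raise ConfigError("summarize_species needs at least one record")
    out = []
    by_species: dict[str, list[StrainCallRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    for species in sorted(by_species):
        strains = by_species[species]
        positive = [r for r in strains if r.n_bsh >= 1]
        if not positive:
            continue
        exactly = {k: sum(1 for r in positive if min(r.n_bsh, 3) == k) for k in (1, 2, 3)}
        out.append(
            SpeciesSummary(
                species=species,
                total_strains=len(strains),
                n_with_bsh=len(positive),
                pct_with_bsh=pct(len(positive), len(strains)),
                n_with_exactly_1=exactly[1],
                n_with_exactly_2=exactly[2],
                n_with_exactly_3=exactly[3],
            )
        )
    return out


def full_species_table(records: Sequence[StrainCallRecord]) -> pd.DataFrame:
    """All species (zeros included) with BSH and PVA presence columns."""
    rows = []
    by_species: dict[str, list[StrainCallRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    for species in sorted(by_species):
        strains = by_species[species]
        rows.append(
            {
                "species": species,
                "total_strains": len(strains),
                "n_with_bsh": sum(1 for r in strains if r.n_bsh >= 1),
                "n_with_pva": sum(1 for r in strains if r.n_pva >= 1),
                "encodes_bsh": any(r.n_bsh >= 1 for r in strains),
                "encodes_pva": any(r.n_pva >= 1 for r in strains),
            }
        )
    return pd.DataFrame(rows)


def category_breakdown(
    records: Sequence[StrainCallRecord], total_species: int
) -> CategoryBreakdown:
    """Four-way species classification over a survey of ``total_species``.

    Species absent from ``records`` count as encoding neither enzyme.
    Inclusive counting: the BSH and PVA counts both include the "both"
    species, so ``pva + bsh - both + neither == total``.
    """
    species = {r.species for r in records}
    if total_species < len(species):
        raise ConfigError(
            f"total_species {total_species} is smaller than the "
            f"{len(species)} distinct species in the records"
        )
    bsh = {r.species for r in records if r.n_bsh >= 1}
    pva = {r.species for r in records if r.n_pva >= 1}
    both = bsh & pva
    neither = total_species - len(bsh | pva)
    return CategoryBreakdown(
        n_species_pva=len(pva),
        n_species_bsh=len(bsh),
        n_species_both=len(both),
        n_species_neither=neither,
        pct_pva=pct(len(pva), total_species),
        pct_bsh=pct(len(bsh), total_species),
        pct_both=pct(len(both), total_species),
        pct_neither=pct(neither, total_species),
        total_species=total_species,
    )


def bsh_multiplicity(summaries: Sequence[SpeciesSummary]) -> dict[int, int]:
    """Distribution over BSH-encoding species of the max per-strain copy count.

    A species counts as single-copy (key 1) iff its two- and three-copy
    columns are both zero; key 2 means some strain carries two copies but
    none three; key 3 means some strain carries three (or more).  Values
    are whole-percent shares of BSH-encoding species (half-up).
    """
    if not summaries:
        raise ConfigError("bsh_multiplicity needs at least one summary")
    n = len(summaries)
    singles = sum(
        1 for s in summaries if s.n_with_exactly_2 == 0 and s.n_with_exactly_3 == 0
    )
    triples = sum(1 for s in summaries if s.n_with_exactly_3 > 0)
    doubles = n - singles - triples
    return {
        1: int(pct(singles, n, decimals=0)),
        2: int(pct(doubles, n, decimals=0)),
        3: int(pct(triples, n, decimals=0)),
    }


def per_species_range(summaries: Sequence[SpeciesSummary]) -> tuple[float, float]:
    """(min, max) of the per-species percent of BSH-positive strains."""
    if not summaries:
        raise ConfigError("per_species_range needs at least one summary")
    values = [s.pct_with_bsh for s in summaries]
    return (min(values), max(values))


@dataclass(frozen=True)
class LifestyleCrosstab:
    """Per enzyme class: encoding-species counts and percentages by lifestyle."""

    bsh_counts: dict[str, int]
    pva_counts: dict[str, int]
    bsh_pct: dict[str, float]
    pva_pct: dict[str, float]


def lifestyle_crosstab(
    records: Sequence[StrainCallRecord],
    metadata: Sequence[StrainMetadata],
) -> LifestyleCrosstab:
    """Lifestyle distribution of the BSH- and PVA-encoding species.

    Lifestyle is a species-level attribute (all strains of a species share
    one label).  Percentages are of encoding species within each enzyme
    class, 2 dp half-up.  Species in ``records`` missing from ``metadata``
    raise, listing the offenders.
    """
    lifestyle_of: dict[str, str] = {}
    for m in metadata:
        prev = lifestyle_of.setdefault(m.species, m.lifestyle)
        if prev != m.lifestyle:
            raise ValidationError(
                f"species {m.species!r} carries two lifestyles ({prev}, {m.lifestyle})"
            )
    species = {r.species for r in records}
    missing = sorted(species - set(lifestyle_of))
    if missing:
        raise ValidationError(f"species missing from metadata: {missing}")

    bsh = sorted({r.species for r in records if r.n_bsh >= 1})
    pva = sorted({r.species for r in records if r.n_pva >= 1})
    out_counts = {}
    out_pct = {}
    for key, group in (("bsh", bsh), ("pva", pva)):
        counts: dict[str, int] = {}
        for sp in group:
            counts[lifestyle_of[sp]] = counts.get(lifestyle_of[sp], 0) + 1
        out_counts[key] = counts
        out_pct[key] = {
            ls: pct(c, len(group)) for ls, c in sorted(counts.items())
        }
    return LifestyleCrosstab(
        bsh_counts=out_counts["bsh"],
        pva_counts=out_counts["pva"],
        bsh_pct=out_pct["bsh"],
        pva_pct=out_pct["pva"],
    )


# ---------------------------------------------------------------------------
# Derivation from classification results

def strain_calls_from_labels(
    labels: Mapping[str, str], provenance: Mapping[str, tuple[str, str]]
) -> list[StrainCallRecord]:
    """Aggregate per-protein labels into per-strain counts.

    ``labels`` maps protein id -> {BSH, PVA, removed}; ``provenance`` maps
    protein id -> (species, strain).  Strains appear even when every one
    of their proteins was removed.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for pid, label in labels.items():
        key = provenance[pid]
        bucket = counts.setdefault(key, [0, 0])
        if label == "BSH":
            bucket[0] += 1
        elif label == "PVA":
            bucket[1] += 1
    return [
        StrainCallRecord(species=sp, strain=st, n_bsh=c[0], n_pva=c[1])
        for (sp, st), c in sorted(counts.items())
    ]


def write_species_table(summaries: Sequence[SpeciesSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\ttotal_strains\tn_with_bsh\tpct_with_bsh\t"
            "n_with_1_bsh\tn_with_2_bsh\tn_with_3_bsh\n"
        )
        for s in summaries:
            fh.write(
                f"{s.species}\t{s.total_strains}\t{s.n_with_bsh}\t"
                f"{s.pct_with_bsh:.2f}\t{s.n_with_exactly_1}\t"
                f"{s.n_with_exactly_2}\t{s.n_with_exactly_3}\n"
            )
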