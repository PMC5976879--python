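"""Greedy representative-based clustering of classified BSH proteins.

Stand-in for CD-HIT at desk scale: sequences are sorted longest-first,
each unassigned sequence joins the first existing cluster whose
representative it matches at or above the identity threshold, otherwise
it founds a new cluster.  Identity uses the CD-HIT convention by default
— identical aligned pairs over the length of the shorter sequence —
computed from an exact Smith-Waterman alignment (no k-mer pre-filter;
correctness over speed at these input sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .seqio import ProteinRecord
from .orfscreen import smith_waterman


@dataclass(frozen=True)
class ClusterMember:
    protein: ProteinRecord
    identity_to_representative: float


@dataclass
class Cluster:
    """A representative plus the members that matched it."""

    representative: ProteinRecord
    members: list[ClusterMember]
    name: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(
    proteins: Sequence[ProteinRecord],
    threshold: float = 0.95,
    identity_mode: Literal["cdhit", "blast"] = "cdhit",
) -> list[Cluster]:
    """Partition proteins into identity clusters.

    Deterministic: inputs are sorted by descending length with ties broken
    by ascending id, so the representative of every cluster is its longest
    member.  Every member reaches at least ``threshold`` identity to its
    representative.
    """
    if not proteins:
        raise ConfigError("greedy_cluster requires at least one protein")
    if not (0.0 < threshold <= 1.0):
        raise ConfigError("threshold must lie in (0, 1]")
    ordered = sorted(proteins, key=lambda p: (-p.length, p.id))
    clusters: list[Cluster] = []
    for prot in ordered:
        placed = False
        for cl in clusters:
            if prot.id == cl.representative.id:
                continue
            res = smith_waterman(prot, cl.representative, identity_mode=identity_mode)
            if res.identity >= threshold:
                cl.members.append(ClusterMember(prot, res.identity))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=prot, members=[ClusterMember(prot, 1.0)])
            )
    return clusters


def name_clusters(
    clusters: Sequence[Cluster], provenance: Mapping[str, str] | None = None
) -> list[Cluster]:
    """Name clusters from their member species.

    The base name joins the sorted unique species abbreviations (the last
    whitespace token of each binomial) with ``_and_``; clusters sharing a
    base name get ordinals in cluster order (``gasseri_1``, ``gasseri_2``).
    ``provenance`` maps protein id -> species and falls back to each
    record's own ``species`` field.
    """
    counters: dict[str, int] = {}
    named: list[Cluster] = []
    for cl in clusters:
        species: set[str] = set()
        for m in cl.members:
            sp = (provenance or {}).get(m.protein.id, m.protein.species)
            if not sp:
                raise ValidationError(
                    f"no species provenance for protein {m.protein.id!r}"
                )
            species.add(sp.split()[-1])
        base = "_and_".join(sorted(species))
        counters[base] = counters.get(base, 0) + 1
        cl.name = f"{base}_{counters[base]}"
        named.append(cl)
    return named


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise identity percentages between representatives."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("identity matrix shape mismatch")


def identity_matrix(
    representatives: Sequence[ProteinRecord],
    identity_mode: Literal["blast", "cdhit"] = "blast",
) -> IdentityMatrix:
    """All-vs-all percent identity (computed once per pair, mirrored)."""
    if len(representatives) < 2:
        raise ConfigError("identity_matrix needs at least two representatives")
    n = len(representatives)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = smith_waterman(
                representatives[i], representatives[j], identity_mode=identity_mode
            )
            values[i, j] = values[j, i] = 100.0 * res.identity
    return IdentityMatrix(
        ids=tuple(r.id for r in representatives), values=values
    )


# ---------------------------------------------------------------------------
# Output formats

def write_clstr(clusters: Sequence[Cluster], path: str | Path) -> None:
    """CD-HIT-like .clstr text output."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters):
            fh.write(f">Cluster {i} {cl.name}\n")
            for k, m in enumerate(cl.members):
                star = (
                    "*"
                    if m.protein.id == cl.representative.id
                    else f"at {100.0 * m.identity_to_representative:.2f}%"
                )
                fh.write(f"{k}\t{m.protein.length}aa, >{m.protein.id}... {star}\n")


def write_cluster_tsv(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tname\trepresentative\tmember\tspecies\tstrain\tidentity_pct\n")
        for i, cl in enumerate(clusters):
            for m in cl.members:
                fh.write(
                    f"{i}\t{cl.name}\t{cl.representative.id}\t{m.protein.id}\t"
                    f"{m.protein.species}\t{m.protein.strain}\t"
                    f"{100.0 * m.identity_to_representative:.2f}\n"
                )


def write_identity_matrix(matrix: IdentityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.ids) + "\n")
        for rid, row in zip(matrix.ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")
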