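"""Synthetic datasets for exercising every pipeline stage without downloads.

The generator emulates the structure of a genus-wide survey of bile salt
hydrolase (BSH) content: two homologous ~320-aa protein families — a
BSH-like family and a penicillin-V-acylase-like (PVA-like) family that are
confusable at the sequence level — are evolved from a pair of consensus
sequences sharing a configurable fraction of ancestry, embedded as open
reading frames in genome-like nucleotide records organised into species
and strains, and accompanied by reference sets (26 BSH-like + 8 PVA-like
members by default), trivially-aligned reference MSAs, a strain metadata
table with lifestyle labels, one marker gene per species evolved along a
known species tree, and a complete truth table.

Every output is a pure function of (config, seed).  The substitution
model is deliberately simple — uniform replacement over the 19
alternative residues, no indels by default — so that sequence identity is
directly controllable.  Planted motif anchors (including the catalytic
Cys at consensus position 2) are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .seqio import (
    AA20,
    GenomeRecord,
    Msa,
    ProteinRecord,
    StrainMetadata,
    write_fasta,
    write_metadata,
    write_stockholm,
)

_AA = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")

# Default planted motif blocks (0-based start, length, anchor residues).
# The BSH-like family carries the six canonical active-site positions of
# choloylglycine hydrolases — Cys2, Arg18, Asp21, Asn82, Asn175, Arg228
# (1-based consensus coordinates) — inside five of its blocks plus the
# N-terminal block holding Cys2 itself.
DEFAULT_BSH_BLOCKS: tuple[tuple[int, int, str], ...] = (
    (0, 5, "MCTAG"),
    (16, 6, "ARGTDI"),
    (57, 4, "GSLV"),
    (79, 5, "GSNDT"),
    (126, 4, "NYSP"),
    (172, 5, "AGNLG"),
    (225, 4, "GVRS"),
    (288, 4, "KDEP"),
)

# The PVA-like family shares the N-terminal Met/Cys anchor (both real
# enzyme families are N-terminal cysteine hydrolases) but otherwise has
# its own conserved blocks.
DEFAULT_PVA_BLOCKS: tuple[tuple[int, int, str], ...] = (
    (0, 3, "MCD"),
    (40, 4, "WGRE"),
    (150, 3, "TQP"),
    (260, 4, "HGNV"),
)

#: Six canonical active-site residues planted in the BSH-like consensus,
#: as (residue, 1-based consensus position).
DEFAULT_ACTIVE_SITES: tuple[tuple[str, int], ...] = (
    ("C", 2),
    ("R", 18),
    ("D", 21),
    ("N", 82),
    ("N", 175),
    ("R", 228),
)


@dataclass(frozen=True)
class FamilySpec:
    """Design of one simulated protein family."""

    name: str
    consensus_len: int = 320
    motif_blocks: tuple[tuple[int, int, str], ...] = ()
    family_divergence: float = 0.30
    shared_ancestry: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 <= self.family_divergence < 1.0):
            raise ConfigError("family_divergence must lie in [0, 1)")
        if not (0.0 <= self.shared_ancestry <= 1.0):
            raise ConfigError("shared_ancestry must lie in [0, 1]")
        covered: set[int] = set()
        for start, length, anchor in self.motif_blocks:
            if length < 3:
                raise ConfigError(f"motif block at {start}: length {length} < 3")
            if len(anchor) != length:
                raise ConfigError(
                    f"motif block at {start}: anchor {anchor!r} does not match "
                    f"length {length}"
                )
            span = set(range(start, start + length))
            if start < 0 or start + length > self.consensus_len:
                raise ConfigError(f"motif block at {start} exceeds consensus")
            if covered & span:
                raise ConfigError(f"motif block at {start} overlaps another block")
            covered |= span

    @property
    def anchor_positions(self) -> frozenset[int]:
        pos: set[int] = set()
        for start, length, _ in self.motif_blocks:
            pos.update(range(start, start + length))
        return frozenset(pos)


def default_bsh_spec(**overrides) -> FamilySpec:
    return FamilySpec(name="BSH-like", motif_blocks=DEFAULT_BSH_BLOCKS, **overrides)


def default_pva_spec(**overrides) -> FamilySpec:
    return FamilySpec(name="PVA-like", motif_blocks=DEFAULT_PVA_BLOCKS, **overrides)


# ---------------------------------------------------------------------------
# Core evolutionary primitives

def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length))


def make_consensus_pair(
    spec_bsh: FamilySpec, spec_pva: FamilySpec, seed: int
) -> tuple[str, str]:
    """Build the two family consensus sequences.

    The fraction of identical positions is driven to ``shared_ancestry``
    (of the first spec): motif anchors are written first, then exactly
    enough additional positions are made identical (or forced to differ)
    to land the overall identity on target.  Both consensuses start with
    Met so that reverse-translated members open with a genuine ATG start.
    """
    if spec_bsh.consensus_len != spec_pva.consensus_len:
        raise ConfigError(
            "consensus lengths differ; shared-ancestry construction needs "
            f"equal lengths ({spec_bsh.consensus_len} vs {spec_pva.consensus_len})"
        )
    L = spec_bsh.consensus_len
    rng = np.random.default_rng(seed)
    a = np.array(list(_random_protein(L, rng)))
    b = a.copy()

    for start, length, anchor in spec_bsh.motif_blocks:
        a[start : start + length] = list(anchor)
    for start, length, anchor in spec_pva.motif_blocks:
        b[start : start + length] = list(anchor)
    a[0] = b[0] = "M"

    anchored = spec_bsh.anchor_positions | spec_pva.anchor_positions | {0}
    free = np.array(sorted(set(range(L)) - anchored))
    rng.shuffle(free)
    n_equal_target = int(round(spec_bsh.shared_ancestry * L))
    n_equal_anchored = int(sum(a[p] == b[p] for p in anchored))
    n_equal_free = max(0, min(len(free), n_equal_target - n_equal_anchored))

    for p in free[:n_equal_free]:
        b[p] = a[p]
    for p in free[n_equal_free:]:
        choices = [r for r in AA20 if r != a[p]]
        b[p] = choices[int(rng.integers(len(choices)))]
    return "".join(a), "".join(b)


def evolve_member(
    consensus: str,
    divergence: float,
    motif_blocks: Sequence[tuple[int, int, str]],
    seed: int,
) -> str:
    """Evolve one family member by point substitution.

    Each position outside the motif anchors is substituted independently
    with probability ``divergence``, drawing uniformly from the 19
    alternative residues.  Anchors are never touched; no indels.
    """
    if not (0.0 <= divergence < 1.0):
        raise ConfigError("divergence must lie in [0, 1)")
    anchors: set[int] = {0}
    for start, length, _ in motif_blocks:
        anchors.update(range(start, start + length))
    rng = np.random.default_rng(seed)
    out = list(consensus)
    hits = np.nonzero(rng.random(len(consensus)) < divergence)[0]
    for p in hits:
        if int(p) in anchors:
            continue
        choices = [r for r in AA20 if r != consensus[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Reverse translation and genome embedding

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _codon_choices() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]  # bacterial code
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        choices.setdefault(aa, []).append(codon)
    return choices

_CODONS = _codon_choices()
_STOPS = ("TAA", "TAG", "TGA")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice under the bacterial code."""
    parts = []
    for aa in protein:
        codons = _CODONS[aa]
        parts.append(codons[int(rng.integers(len(codons)))])
    return "".join(parts)


def _random_flank(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def embed_in_genome(
    proteins: Sequence[ProteinRecord],
    flank_len: int,
    seed: int,
    genome_id: str = "genome",
    species: str = "",
    strain: str = "",
) -> tuple[GenomeRecord, pd.DataFrame]:
    """Reverse-translate proteins and embed each as an ORF in one genome.

    Each coding cassette is ``flank + TAA + CDS + stop + flank``; the
    in-frame TAA immediately upstream of the start codon guarantees the
    planted ATG opens the maximal ORF, and codons themselves can never be
    stops, so six-frame ORF extraction recovers each protein exactly.
    Cassettes land on a random strand.  Returns the genome plus truth
    rows with forward-strand 0-based half-open CDS coordinates (start
    codon through stop codon inclusive).
    """
    if not proteins:
        raise ConfigError("embed_in_genome needs at least one protein")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    rows = []
    offset = 0
    for prot in proteins:
        if not prot.sequence.startswith("M"):
            raise ConfigError(
                f"protein {prot.id}: embedded ORFs must start with Met"
            )
        cds = reverse_translate(prot.sequence, rng) + _STOPS[int(rng.integers(3))]
        left = _random_flank(flank_len, rng)
        right = _random_flank(flank_len, rng)
        cassette = left + "TAA" + cds + right
        s_local = len(left) + 3
        e_local = s_local + len(cds)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            cassette = revcomp(cassette)
            s_local, e_local = len(cassette) - e_local, len(cassette) - s_local
        rows.append(
            {
                "protein_id": prot.id,
                "species": species or prot.species,
                "strain": strain or prot.strain,
                "family": "decoy",
                "genome_id": genome_id,
                "strand": strand,
                "start": offset + s_local,
                "end": offset + e_local,
            }
        )
        chunks.append(cassette)
        offset += len(cassette)
    genome = GenomeRecord(
        id=genome_id, sequence="".join(chunks), species=species, strain=strain
    )
    return genome, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Species tree and marker genes

def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random bifurcating topology as nested tuples of labels."""
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    left = _random_topology(labels[:k], rng)
    right = _random_topology(labels[k:], rng)
    return (left, right)


def _tree_to_newick(node, bl) -> str:
    if isinstance(node, str):
        return f"{node.replace(' ', '_')}:{bl(node):.4f}"
    left, right = node
    return f"({_tree_to_newick(left, bl)},{_tree_to_newick(right, bl)}):{bl(node):.4f}"


_NT = np.array(list("ACGT"))


def _evolve_marker(node, seq: str, bl, rng, out: dict) -> None:
    if isinstance(node, str):
        out[node] = seq
        return
    for child in node:
        p = bl(child)
        child_seq = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < p)[0]
        for i in hits:
            alts = [n for n in "ACGT" if n != seq[i]]
            child_seq[i] = alts[int(rng.integers(3))]
        _evolve_marker(child, "".join(child_seq), bl, rng, out)


# ---------------------------------------------------------------------------
# Full dataset generation

@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic genus survey.

    Copy numbers per species lie in {0, 1, 2, 3}.  When explicit
    ``bsh_copies`` / ``pva_copies`` lists are not given, copy numbers are
    sampled from ``*_copy_probs``; the defaults mirror the published
    survey shape (about 23% of species BSH-positive, with a 64/28/8
    one/two/three split among positives, and about 48% PVA-positive).
    """

    n_species: int = 12
    strains_per_species: int = 3
    bsh_copies: tuple[int, ...] | None = None
    pva_copies: tuple[int, ...] | None = None
    bsh_copy_probs: tuple[float, float, float, float] = (0.771, 0.147, 0.064, 0.018)
    pva_copy_probs: tuple[float, float, float, float] = (0.518, 0.350, 0.100, 0.032)
    decoys_per_genome: int = 1
    family_divergence: float = 0.30
    shared_ancestry: float = 0.40
    strain_divergence: float = 0.02
    ref_divergence: float = 0.12
    n_refs_bsh: int = 26
    n_refs_pva: int = 8
    #: Fraction of strains of a positive species that nevertheless lack the
    #: family (the survey shows 4.35-100% of strains positive per species).
    strain_dropout: float = 0.15
    flank_len: int = 120
    marker_len: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 0 or self.strains_per_species < 1:
            raise ConfigError("need n_species >= 0 and strains_per_species >= 1")
        for name in ("bsh_copies", "pva_copies"):
            copies = getattr(self, name)
            if copies is not None:
                if len(copies) != self.n_species:
                    raise ConfigError(f"{name} must list one value per species")
                if any(c not in (0, 1, 2, 3) for c in copies):
                    raise ConfigError(f"{name} values must lie in {{0,1,2,3}}")
        for name in ("bsh_copy_probs", "pva_copy_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1")


@dataclass
class Bundle:
    """In-memory result of :func:`generate_dataset` (plus file paths if written)."""

    genomes: list[GenomeRecord]
    refs_bsh: list[ProteinRecord]
    refs_pva: list[ProteinRecord]
    msa_bsh: Msa
    msa_pva: Msa
    metadata: list[StrainMetadata]
    truth: pd.DataFrame
    proteins: list[ProteinRecord]
    markers: list[GenomeRecord]
    species_tree_newick: str
    consensus_bsh: str
    consensus_pva: str
    paths: dict[str, Path] = field(default_factory=dict)


_TRUTH_COLUMNS = [
    "protein_id", "species", "strain", "family",
    "genome_id", "strand", "start", "end",
]

_LIFESTYLE_RULES = {
    # lifestyle sampling for BSH-positive, PVA-only and negative species;
    # weights follow the niche association reported for the real genus.
    "bsh": (("vertebrate-adapted", 0.846), ("unknown", 0.128), ("nomadic", 0.026)),
    "pva": (
        ("free-living", 0.402), ("unknown", 0.403),
        ("vertebrate-adapted", 0.134), ("nomadic", 0.061),
    ),
    "neither": (
        ("free-living", 0.40), ("unknown", 0.30),
        ("insect-adapted", 0.20), ("vertebrate-adapted", 0.10),
    ),
}


def _sample_lifestyle(kind: str, rng: np.random.Generator) -> str:
    labels, weights = zip(*_LIFESTYLE_RULES[kind])
    return str(rng.choice(np.array(labels), p=np.array(weights)))


def generate_dataset(config: SimulationConfig, out_dir: str | Path | None = None) -> Bundle:
    """Generate a complete synthetic survey bundle.

    Deterministic under ``config.seed``.  When ``out_dir`` is given the
    bundle is also written to disk (genomes.fna, refs_*.faa, refs_*.sto,
    metadata.tsv, truth.tsv, markers.fna, species_tree.nwk) and the paths
    are recorded on the returned :class:`Bundle`.
    """
    rng = np.random.default_rng(config.seed)
    spec_bsh = default_bsh_spec(
        family_divergence=config.family_divergence,
        shared_ancestry=config.shared_ancestry,
    )
    spec_pva = default_pva_spec(
        family_divergence=config.family_divergence,
        shared_ancestry=config.shared_ancestry,
    )
    cons_bsh, cons_pva = make_consensus_pair(
        spec_bsh, spec_pva, seed=int(rng.integers(2**31))
    )

    def _refs(name: str, consensus: str, blocks, n: int) -> list[ProteinRecord]:
        return [
            ProteinRecord(
                id=f"{name}_ref_{i + 1:02d}",
                sequence=evolve_member(
                    consensus, config.ref_divergence, blocks, int(rng.integers(2**31))
                ),
            )
            for i in range(n)
        ]

    refs_bsh = _refs("bsh", cons_bsh, spec_bsh.motif_blocks, config.n_refs_bsh)
    refs_pva = _refs("pva", cons_pva, spec_pva.motif_blocks, config.n_refs_pva)
    # No indels in the generator, so the reference MSAs are the sequences
    # stacked as-is.
    msa_bsh = Msa(rows=tuple((r.id, r.sequence) for r in refs_bsh))
    msa_pva = Msa(rows=tuple((r.id, r.sequence) for r in refs_pva))

    species_names = [f"Lactobacillus sim{i:03d}" for i in range(config.n_species)]
    if config.bsh_copies is not None:
        bsh_copies = list(config.bsh_copies)
    else:
        bsh_copies = [
            int(rng.choice(4, p=np.array(config.bsh_copy_probs)))
            for _ in species_names
        ]
    if config.pva_copies is not None:
        pva_copies = list(config.pva_copies)
    else:
        pva_copies = [
            int(rng.choice(4, p=np.array(config.pva_copy_probs)))
            for _ in species_names
        ]

    genomes: list[GenomeRecord] = []
    metadata: list[StrainMetadata] = []
    proteins: list[ProteinRecord] = []
    truth_frames: list[pd.DataFrame] = []

    for si, species in enumerate(species_names):
        kind = "bsh" if bsh_copies[si] > 0 else ("pva" if pva_copies[si] > 0 else "neither")
        lifestyle = _sample_lifestyle(kind, rng)
        founders: list[tuple[str, str, str]] = []  # (family, copy tag, sequence)
        for c in range(bsh_copies[si]):
            founders.append((
                "BSH", f"b{c + 1}",
                evolve_member(cons_bsh, config.family_divergence,
                              spec_bsh.motif_blocks, int(rng.integers(2**31))),
            ))
        for c in range(pva_copies[si]):
            founders.append((
                "PVA", f"p{c + 1}",
                evolve_member(cons_pva, config.family_divergence,
                              spec_pva.motif_blocks, int(rng.integers(2**31))),
            ))
        for ti in range(config.strains_per_species):
            strain = f"st{ti + 1:02d}"
            metadata.append(StrainMetadata(species, strain, lifestyle))
            carried = [
                f for f in founders
                if ti == 0 or rng.random() >= config.strain_dropout
            ]
            strain_prots: list[tuple[str, ProteinRecord]] = []
            for family, tag, founder in carried:
                blocks = spec_bsh.motif_blocks if family == "BSH" else spec_pva.motif_blocks
                seq = evolve_member(
                    founder, config.strain_divergence, blocks, int(rng.integers(2**31))
                )
                pid = f"sp{si:03d}_{strain}_{tag}"
                strain_prots.append(
                    (family, ProteinRecord(pid, seq, species=species, strain=strain))
                )
            for d in range(config.decoys_per_genome):
                dlen = int(rng.integers(150, 400))
                seq = "M" + _random_protein(dlen - 1, rng)
                pid = f"sp{si:03d}_{strain}_decoy{d + 1}"
                strain_prots.append(
                    ("decoy", ProteinRecord(pid, seq, species=species, strain=strain))
                )
            genome_id = f"g_sp{si:03d}_{strain}"
            genome, rows = embed_in_genome(
                [p for _, p in strain_prots],
                flank_len=config.flank_len,
                seed=int(rng.integers(2**31)),
                genome_id=genome_id,
                species=species,
                strain=strain,
            )
            rows["family"] = [fam for fam, _ in strain_prots]
            genomes.append(genome)
            proteins.extend(p for _, p in strain_prots)
            truth_frames.append(rows)

    truth = (
        pd.concat(truth_frames, ignore_index=True)[_TRUTH_COLUMNS]
        if truth_frames
        else pd.DataFrame(columns=_TRUTH_COLUMNS)
    )

    # Species tree + marker genes.
    markers: list[GenomeRecord] = []
    newick = ";"
    if config.n_species >= 2:
        topo = _random_topology(list(species_names), rng)
        lengths: dict = {}

        def bl(node) -> float:
            key = node if isinstance(node, str) else id(node)
            if key not in lengths:
                lengths[key] = float(rng.uniform(0.03, 0.12))
            return lengths[key]

        root_seq = "".join(rng.choice(_NT, size=config.marker_len))
        leaf_seqs: dict[str, str] = {}
        _evolve_marker(topo, root_seq, bl, rng, leaf_seqs)
        newick = _tree_to_newick(topo, bl) + ";"
        markers = [
            GenomeRecord(
                id=f"marker_{name.replace(' ', '_')}",
                sequence=leaf_seqs[name],
                species=name,
            )
            for name in species_names
        ]

    bundle = Bundle(
        genomes=genomes,
        refs_bsh=refs_bsh,
        refs_pva=refs_pva,
        msa_bsh=msa_bsh,
        msa_pva=msa_pva,
        metadata=metadata,
        truth=truth,
        proteins=proteins,
        markers=markers,
        species_tree_newick=newick,
        consensus_bsh=cons_bsh,
        consensus_pva=cons_pva,
    )
    if out_dir is not None:
        bundle.paths = write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fna",
        "refs_bsh": out / "refs_bsh.faa",
        "refs_pva": out / "refs_pva.faa",
        "msa_bsh": out / "refs_bsh.sto",
        "msa_pva": out / "refs_pva.sto",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "markers": out / "markers.fna",
        "species_tree": out / "species_tree.nwk",
    }
    write_fasta(bundle.genomes, paths["genomes"])
    write_fasta(bundle.refs_bsh, paths["refs_bsh"])
    write_fasta(bundle.refs_pva, paths["refs_pva"])
    write_stockholm(bundle.msa_bsh, paths["msa_bsh"])
    write_stockholm(bundle.msa_pva, paths["msa_pva"])
    write_metadata(bundle.metadata, paths["metadata"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(bundle.markers, paths["markers"])
    paths["species_tree"].write_text(bundle.species_tree_newick + "\n")
    return paths
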