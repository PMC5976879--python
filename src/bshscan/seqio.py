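"""Sequence and metadata I/O plus run configuration.

Every external format the pipeline touches goes through this module:
FASTA (nucleotide and protein), Stockholm 1.0 alignments, the TSV strain
metadata table, and the YAML run configuration.  Parsing is strict — an
illegal residue or an unknown lifestyle label raises instead of being
silently coerced — so that downstream stages can trust their inputs.

FASTA headers follow an ``id key=value`` dialect: the first whitespace
token is the record id and ``species=...`` / ``strain=...`` pairs carry
provenance.  Headers that do not follow the dialect are kept verbatim as
the id.  Internally all coordinates are 0-based half-open; report files
use 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .errors import ConfigError, ParseError, SchemaError, ValidationError

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Protein residues accepted on input. 'X' marks residues translated from
#: ambiguous codons (draft genomes contain Ns).
PROTEIN_ALPHABET = frozenset(AA20 + "X")
#: Nucleotides accepted on input; 'N' is permitted (draft genomes).
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: The closed set of lifestyle designations used for niche mapping.
LIFESTYLES = (
    "vertebrate-adapted",
    "free-living",
    "insect-adapted",
    "nomadic",
    "unknown",
)


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence with species/strain provenance."""

    id: str
    sequence: str
    species: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"genome record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence (no gaps) with species/strain provenance."""

    id: str
    sequence: str
    species: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        """Number of residues."""
        return len(self.sequence)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ordered (id, aligned sequence) rows.

    All rows share the same number of columns; '-' marks a gap.  Ungapping
    any row yields a plain protein (or nucleotide) sequence.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.rows:
            width = len(self.rows[0][1])
            for rid, seq in self.rows:
                if len(seq) != width:
                    raise ValidationError(
                        f"alignment row {rid!r} has {len(seq)} columns, "
                        f"expected {width} (ragged alignment)"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def column(self, j: int) -> str:
        """Residues (and gaps) of 0-based column ``j``, in row order."""
        return "".join(seq[j] for _, seq in self.rows)

    def ungapped(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq.replace("-", "").replace(".", "")
        raise KeyError(rid)


@dataclass(frozen=True)
class StrainMetadata:
    """Species/strain row with a lifestyle label from the closed five-value set."""

    species: str
    strain: str
    lifestyle: str

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"unknown lifestyle {self.lifestyle!r} for {self.species} "
                f"{self.strain}; legal values: {', '.join(LIFESTYLES)}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run.

    Defaults mirror the published screen: ORFs under 100 aa are dropped,
    candidates need >=30% identity to a reference, classified proteins are
    retained only when their best-model E-value is below 1e-99, BSH
    proteins are clustered at 95% identity, and motifs are runs of >=3
    alignment columns conserved at >=0.75.
    """

    min_orf_len: int = 100
    min_ref_identity: float = 0.30
    retention_evalue: float = 1e-99
    cluster_identity: float = 0.95
    conservation_threshold: float = 0.75
    min_motif_len: int = 3
    bootstrap_reps: int = 100
    rng_seed: int = 0
    #: If True (default), candidates are RETAINED only when their best-model
    #: E-value is below ``retention_evalue`` (weak hits removed).  The
    #: literal inverse reading is exposed for completeness.
    retain_strong: bool = True

    def __post_init__(self) -> None:
        for name in ("min_ref_identity", "cluster_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if not (0.0 <= self.conservation_threshold <= 1.0):
            raise ConfigError("conservation_threshold must lie in [0, 1]")
        if self.min_orf_len < 1:
            raise ConfigError("min_orf_len must be >= 1")
        if self.min_motif_len < 1:
            raise ConfigError("min_motif_len must be >= 1")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")
        if self.retention_evalue <= 0:
            raise ConfigError("retention_evalue must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"config file {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(description: str) -> tuple[str, str, str]:
    """Split a FASTA description into (id, species, strain).

    Dialect: first token is the id; later ``key=value`` tokens set species
    and strain (values may contain spaces only via underscores).  Anything
    unparseable keeps the full header as the id.
    """
    tokens = description.split()
    if not tokens:
        return description, "", ""
    rid = tokens[0]
    species = strain = ""
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key == "species":
                species = value.replace("_", " ")
                continue
            if key == "strain":
                strain = value
                continue
        # Not the id key=value dialect: keep the entire header as id.
        return description, "", ""
    return rid, species, strain


def _format_header(rec: GenomeRecord | ProteinRecord) -> str:
    parts = [rec.id]
    if rec.species:
        parts.append(f"species={rec.species.replace(' ', '_')}")
    if rec.strain:
        parts.append(f"strain={rec.strain}")
    return " ".join(parts)


def _validate_sequence(rid: str, seq: str, alphabet: frozenset, what: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValidationError(
                f"{what} record {rid!r}: illegal residue {ch!r} at position "
                f"{pos + 1}"
            )


def read_fasta(
    path: str | Path, kind: Literal["nucleotide", "protein"]
) -> list[GenomeRecord] | list[ProteinRecord]:
    """Read a FASTA file into genome or protein records.

    Sequences are uppercased and validated against the nucleotide
    (``ACGTN``) or protein (20 amino acids + ``X``) alphabet.  An empty
    file yields an empty list; a file whose first non-blank character is
    not ``>`` raises :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected '>' to start the first "
                    f"FASTA record, got {line[:30]!r}"
                )
            break
    else:
        return []

    cls = GenomeRecord if kind == "nucleotide" else ProteinRecord
    alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
    out = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        rid, species, strain = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        _validate_sequence(rid, seq, alphabet, kind)
        if rid in seen:
            raise ValidationError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        out.append(cls(id=rid, sequence=seq, species=species, strain=strain))
    return out


def write_fasta(
    records: Iterable[GenomeRecord | ProteinRecord], path: str | Path, width: int = 70
) -> None:
    """Write records in the ``id species=... strain=...`` header dialect."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Stockholm 1.0

def read_stockholm(path: str | Path) -> Msa:
    """Read a Stockholm 1.0 alignment into an :class:`Msa`.

    Annotation lines (``#=GC``, ``#=GS``...) are ignored.  A missing
    ``# STOCKHOLM`` header or ``//`` terminator raises :class:`ParseError`;
    ragged rows raise :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped.startswith("# STOCKHOLM"):
        raise ParseError(f"{path}: missing '# STOCKHOLM 1.0' header")
    if "//" not in text:
        raise ParseError(f"{path}: missing '//' terminator")
    try:
        aln = AlignIO.read(io.StringIO(text), "stockholm")
    except ValueError as exc:
        msg = str(exc)
        if "length" in msg.lower():
            raise ValidationError(f"{path}: ragged alignment rows ({msg})") from exc
        raise ParseError(f"{path}: {msg}") from exc
    return Msa(rows=tuple((rec.id, str(rec.seq).upper()) for rec in aln))


def write_stockholm(msa: Msa, path: str | Path) -> None:
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.rows]
    )
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, "stockholm")


# ---------------------------------------------------------------------------
# Strain metadata TSV

def read_metadata(path: str | Path) -> list[StrainMetadata]:
    """Read the species/strain/lifestyle TSV.

    Rows come back in file order.  A missing column raises
    :class:`SchemaError`; a lifestyle outside the closed five-value set
    raises :class:`ValidationError` listing the legal values.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ("species", "strain", "lifestyle")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; need {required}")
    return [
        StrainMetadata(species=r.species, strain=r.strain, lifestyle=r.lifestyle)
        for r in df.itertuples()
    ]


def write_metadata(rows: Sequence[StrainMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tstrain\tlifestyle\n")
        for r in rows:
            fh.write(f"{r.species}\t{r.strain}\t{r.lifestyle}\n")
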