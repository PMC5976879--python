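"""Translated search of genomes against the reference protein set.

Re-creates the screening stage of the survey: every genome is translated
in all six reading frames, maximal ATG-to-stop ORFs are extracted, ORFs
shorter than the 100-aa floor are dropped (the target enzymes are ~320
aa), and the survivors are aligned locally against the reference set;
only loci reaching the 30%-identity floor are kept as candidates.

Alignment uses optimal affine-gap Smith-Waterman under BLOSUM62 with
gap open 11 / extend 1 (translated-BLAST defaults).  Percent identity is
reported BLAST-style — identical pairs over aligned columns, internal
gaps included — with the shorter-sequence denominator (the clustering
convention) available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .errors import ConfigError
from .seqio import GenomeRecord, ProteinRecord
from .simulate import revcomp

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class FrameSet:
    """Six-frame translation of one genome (stops rendered '*')."""

    genome_id: str
    genome_len: int
    translations: dict[int, str]


@dataclass(frozen=True)
class Orf:
    """A maximal ATG-to-stop open reading frame.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand and include the stop codon, so the encoded protein has
    (end - start) / 3 - 1 residues.
    """

    genome_id: str
    frame: int
    start: int
    end: int
    protein: ProteinRecord


@dataclass(frozen=True)
class Candidate:
    """An ORF that survived the reference-identity screen."""

    orf: Orf
    best_ref_id: str
    best_identity: float
    score: float


def six_frame_translate(genome: GenomeRecord) -> FrameSet:
    """Translate a genome in frames +1..+3 and -1..-3.

    Frames +k read the forward sequence from offset k-1; frames -k read
    the reverse complement from offset k-1.  Trailing partial codons are
    dropped; stop codons appear as '*', codons containing N as 'X'.
    """
    seq = genome.sequence
    if len(seq) < 3:
        warnings.warn(f"genome {genome.id}: shorter than one codon, empty frames")
        return FrameSet(genome.id, len(seq), {f: "" for f in FRAMES})
    rc = revcomp(seq)
    translations: dict[int, str] = {}
    for k in (1, 2, 3):
        for frame, source in ((k, seq), (-k, rc)):
            sub = source[k - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partial/ambiguous codons
                translations[frame] = str(Seq(sub).translate(table=11))
    return FrameSet(genome.id, len(seq), translations)


def _orf_coordinates(frame: int, genome_len: int, p_start: int, p_stop: int) -> tuple[int, int]:
    """Forward-strand nucleotide coordinates of an ORF.

    ``p_start`` is the protein index of the initiator Met within the frame
    translation and ``p_stop`` the index of the terminating '*'.
    """
    offset = abs(frame) - 1
    s = offset + 3 * p_start
    e = offset + 3 * (p_stop + 1)
    if frame > 0:
        return s, e
    return genome_len - e, genome_len - s


def extract_orfs(frames: FrameSet, min_orf_len: int) -> list[Orf]:
    """Extract maximal ATG-to-stop ORFs of at least ``min_orf_len`` residues.

    Within each frame, every stop closes at most one ORF: the one opened
    by the first Met since the previous stop.  ORFs whose protein is
    shorter than ``min_orf_len`` are discarded (length exactly equal is
    retained); ORFs not terminated by a stop are ignored.
    """
    if min_orf_len < 1:
        raise ConfigError("min_orf_len must be >= 1")
    orfs: list[Orf] = []
    for frame in FRAMES:
        prot = frames.translations[frame]
        first_met: int | None = None
        for i, ch in enumerate(prot):
            if ch == "*":
                if first_met is not None and i - first_met >= min_orf_len:
                    s, e = _orf_coordinates(frame, frames.genome_len, first_met, i)
                    pid = f"{frames.genome_id}|{frame:+d}|{s}-{e}"
                    orfs.append(
                        Orf(
                            genome_id=frames.genome_id,
                            frame=frame,
                            start=s,
                            end=e,
                            protein=ProteinRecord(id=pid, sequence=prot[first_met:i]),
                        )
                    )
                first_met = None
            elif ch == "M" and first_met is None:
                first_met = i
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# Local alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length k costs open + k * extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    identity: float


def smith_waterman(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    identity_mode: Literal["blast", "cdhit"] = "blast",
) -> AlignmentResult:
    """Optimal local alignment with affine gaps.

    Identity is identical aligned residue pairs divided by the number of
    aligned columns (gap columns included) for ``blast`` mode, or by the
    length of the shorter input for ``cdhit`` mode.  A best score <= 0 is
    treated as "no alignment" (identity 0).
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ConfigError("smith_waterman requires non-empty sequences")
    aligner = _make_aligner(matrix if matrix is not None else _BLOSUM62,
                            gap_open, gap_extend)
    score = aligner.score(sa, sb)
    if score <= 0:
        return AlignmentResult(score=0.0, aligned_a="", aligned_b="", identity=0.0)
    aln = next(iter(aligner.align(sa, sb)))
    col_a, col_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(col_a, col_b) if x == y and x != "-")
    denom = len(col_a) if identity_mode == "blast" else min(len(sa), len(sb))
    identity = matches / denom if denom else 0.0
    return AlignmentResult(
        score=float(score), aligned_a=col_a, aligned_b=col_b, identity=identity
    )


def screen_candidates(
    orfs: Sequence[Orf],
    references: Sequence[ProteinRecord],
    min_ref_identity: float = 0.30,
    identity_mode: Literal["blast", "cdhit"] = "blast",
    min_coverage: float = 0.5,
) -> list[Candidate]:
    """Align every ORF to every reference and keep loci at >= the identity floor.

    An alignment only counts when it spans at least ``min_coverage`` of
    the shorter sequence: percent identity over a handful of aligned
    columns is meaningless, and without the floor random ORFs routinely
    "hit" a reference over a 10-column local alignment.  Each retained
    candidate records its best qualifying reference (highest identity,
    ties broken by score then reference id).  Overlapping ORFs at the
    same genetic locus — same genome, intersecting coordinates — are
    collapsed to the highest-identity one.
    """
    if not references:
        raise ConfigError("screen_candidates requires a non-empty reference set")
    retained: list[Candidate] = []
    for orf in orfs:
        best: tuple[float, float, str] | None = None
        for ref in references:
            res = smith_waterman(orf.protein, ref, identity_mode=identity_mode)
            span = min(len(orf.protein.sequence), len(ref.sequence))
            if len(res.aligned_a) < min_coverage * span:
                continue
            key = (res.identity, res.score, ref.id)
            if best is None or (key[0], key[1]) > (best[0], best[1]):
                best = key
        if best is None:
            continue
        identity, score, ref_id = best
        if identity >= min_ref_identity:
            retained.append(
                Candidate(orf=orf, best_ref_id=ref_id,
                          best_identity=identity, score=score)
            )

    # Collapse overlapping same-locus candidates to the best one.
    retained.sort(
        key=lambda c: (-c.best_identity, -c.score, c.orf.genome_id, c.orf.start)
    )
    kept: list[Candidate] = []
    for cand in retained:
        clash = any(
            k.orf.genome_id == cand.orf.genome_id
            and k.orf.start < cand.orf.end
            and cand.orf.start < k.orf.end
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.orf.genome_id, c.orf.start, c.orf.frame))
    return kept


def candidates_to_proteins(candidates: Iterable[Candidate]) -> list[ProteinRecord]:
    """Candidate proteins with genome provenance propagated."""
    return [
        ProteinRecord(
            id=c.orf.protein.id,
            sequence=c.orf.protein.sequence,
            species=c.orf.protein.species,
            strain=c.orf.protein.strain,
        )
        for c in candidates
    ]
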