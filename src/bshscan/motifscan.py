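"""Column conservation, motif extraction, and active-site auditing.

Works on the alignment of cluster representatives.  The conservation
score of a column is the fraction of rows carrying the modal non-gap
residue, with gaps counted in the denominator — the simplest score on
[0, 1] compatible with a 0.75 motif threshold.  A Shannon-entropy-based
alternative is available behind a flag.  Motifs are maximal runs of at
least ``min_len`` consecutive columns scoring at or above the threshold;
coordinates are reported in 1-based alignment-column space.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .seqio import AA20, Msa

_GAPS = {"-", "."}


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores and modal (consensus) residues."""

    scores: tuple[float, ...]
    column_consensus: str

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.column_consensus):
            raise ValidationError("profile scores/consensus length mismatch")
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ValidationError("conservation scores must lie in [0, 1]")


@dataclass(frozen=True)
class Motif:
    """A conserved run of alignment columns (1-based inclusive)."""

    start_col: int
    end_col: int
    consensus: str
    min_score: float

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1


def column_conservation(
    msa: Msa, method: Literal["modal", "entropy"] = "modal"
) -> ConservationProfile:
    """Score every column of the alignment.

    ``modal``: count of the modal non-gap residue over the number of rows
    (all-gap columns score 0).  ``entropy``: 1 - H/log2(20) over the
    non-gap residues, scaled by the non-gap fraction.  Modal ties break
    alphabetically for the consensus display.
    """
    if msa.n_rows == 0:
        raise ConfigError("cannot profile an empty alignment")
    scores: list[float] = []
    consensus: list[str] = []
    for j in range(msa.n_cols):
        column = msa.column(j)
        counts = Counter(ch for ch in column if ch not in _GAPS)
        if not counts:
            scores.append(0.0)
            consensus.append("-")
            continue
        top = max(counts.values())
        modal_residue = min(r for r, c in counts.items() if c == top)
        if method == "modal":
            score = counts[modal_residue] / msa.n_rows
        else:
            total = sum(counts.values())
            h = -sum((c / total) * math.log2(c / total) for c in counts.values())
            score = (1.0 - h / math.log2(20)) * (total / msa.n_rows)
        scores.append(score)
        consensus.append(modal_residue)
    return ConservationProfile(scores=tuple(scores), column_consensus="".join(consensus))


def find_motifs(
    profile: ConservationProfile, threshold: float = 0.75, min_len: int = 3
) -> list[Motif]:
    """Maximal runs of >= ``min_len`` columns scoring >= ``threshold``.

    Runs are non-overlapping by construction and returned in column order.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    motifs: list[Motif] = []
    run_start: int | None = None
    scores = profile.scores + (-1.0,)  # sentinel closes a trailing run
    for j, score in enumerate(scores):
        if score >= threshold:
            if run_start is None:
                run_start = j
        elif run_start is not None:
            if j - run_start >= min_len:
                motifs.append(
                    Motif(
                        start_col=run_start + 1,
                        end_col=j,
                        consensus=profile.column_consensus[run_start:j],
                        min_score=min(profile.scores[run_start:j]),
                    )
                )
            run_start = None
    return motifs


@dataclass(frozen=True)
class ActiveSiteReport:
    residue: str
    column: int
    conserved: bool
    in_motif: bool
    consensus_residue: str
    matches_expected: bool


#: Default audit: only the N-terminal catalytic cysteine (consensus
#: position 2) is assumed; further sites are caller-supplied.
DEFAULT_SITE_SPEC: tuple[tuple[str, int], ...] = (("C", 2),)


def audit_active_sites(
    msa: Msa,
    motifs: Sequence[Motif],
    site_spec: Sequence[tuple[str, int]] = DEFAULT_SITE_SPEC,
    threshold: float = 0.75,
    method: Literal["modal", "entropy"] = "modal",
) -> list[ActiveSiteReport]:
    """Check each expected active-site residue against the alignment.

    ``site_spec`` lists (expected residue, 1-based alignment column).  For
    each site the report states whether the column is conserved at the
    threshold, whether it falls inside any motif, and whether the modal
    residue matches the expectation.
    """
    profile = column_conservation(msa, method=method)
    reports = []
    for residue, col in site_spec:
        if not (1 <= col <= msa.n_cols):
            raise ConfigError(
                f"active site column {col} outside alignment (1..{msa.n_cols})"
            )
        j = col - 1
        consensus_residue = profile.column_consensus[j]
        reports.append(
            ActiveSiteReport(
                residue=residue,
                column=col,
                conserved=profile.scores[j] >= threshold,
                in_motif=any(m.start_col <= col <= m.end_col for m in motifs),
                consensus_residue=consensus_residue,
                matches_expected=consensus_residue == residue,
            )
        )
    return reports


def logo_matrix(msa: Msa) -> pd.DataFrame:
    """Per-column residue frequencies (gaps excluded entirely).

    Rows are 1-based alignment columns, columns the 20 residues; non-empty
    rows sum to 1.  The table is directly consumable by logo plotters.
    """
    if msa.n_rows == 0:
        raise ConfigError("cannot build a logo from an empty alignment")
    data = []
    for j in range(msa.n_cols):
        counts = Counter(ch for ch in msa.column(j) if ch in set(AA20))
        total = sum(counts.values())
        data.append(
            [counts.get(aa, 0) / total if total else 0.0 for aa in AA20]
        )
    return pd.DataFrame(data, columns=list(AA20), index=range(1, msa.n_cols + 1))


def map_to_ungapped(msa: Msa, rid: str, column: int) -> int | None:
    """1-based residue position in ``rid`` for a 1-based alignment column.

    Returns None when the row has a gap in that column.
    """
    for r, seq in msa.rows:
        if r == rid:
            if seq[column - 1] in _GAPS:
                return None
            return sum(1 for ch in seq[: column] if ch not in _GAPS)
    raise KeyError(rid)


def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tscore\tconsensus\n")
        for j, (s, c) in enumerate(zip(profile.scores, profile.column_consensus), 1):
            fh.write(f"{j}\t{s:.4f}\t{c}\n")


def write_motifs_tsv(motifs: Sequence[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_col\tend_col\tlength\tconsensus\tmin_score\n")
        for m in motifs:
            fh.write(f"{m.start_col}\t{m.end_col}\t{m.length}\t{m.consensus}\t{m.min_score:.4f}\n")
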