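"""Profile-HMM construction, forward scoring, E-values, and classification.

The discriminator at the heart of the pipeline: one profile hidden Markov
model is estimated from the BSH reference alignment and one from the PVA
reference alignment, every candidate protein is scored against both with
the forward algorithm, scores are converted to E-values calibrated on
random decoy sequences, and each candidate is labelled BSH, PVA, or
removed by comparing the two E-values against the retention rule.

Architecture
------------
Classic match/insert/delete profile architecture (Durbin-style, global
with respect to the model): nodes 1..M each carry a match state with a
20-residue emission distribution and a delete state; insert states I_0..I_M
(I_0 and I_M absorb N-/C-terminal overhangs) emit as well.  All nine
transition types among {M, I, D} are estimated per node from the observed
state paths of the training alignment with +1 Laplace smoothing; emission
rows use the same +1 smoothing.  All arithmetic is in log space
(log-sum-exp), so sequences of thousands of residues score without
underflow.

Scores are log-odds in bits against an i.i.d. background model (the mean
residue frequency of the training alignment).  Unknown residues ('X')
contribute probability 1 under both the model emission and the
background, i.e. zero bits.

E-values
--------
``E(s) = db_size * (1 - GumbelCDF(s; mu, lambda))``.  The default
calibration fixes the Gumbel slope at the conjugate value for log-odds
scores, ``lambda = ln 2`` per bit — the universal exponential tail bound
``P(score > t) <= 2**-t`` for likelihood-ratio scores, and the slope
profile-search tools use for forward scores — and anchors the location
``mu`` at the Gumbel-location quantile (36.8th percentile) of the decoy
score distribution, so that ``P(score > mu) = 1 - 1/e`` empirically.  A
full maximum-likelihood Gumbel fit to the decoy scores is available as
``method="mle"``; it matches the bulk of the decoy distribution but
badly underestimates the tail decay of log-odds scores, which makes
thresholds like 1e-99 unreachable for genuine hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .errors import CalibrationError, ConfigError, ConstructionError
from .seqio import AA20, Msa, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
_LN2 = math.log(2.0)
_NEG = -np.inf

#: Gumbel CDF at its location parameter: exp(-1).
_LOCATION_QUANTILE = math.exp(-1.0)


# ---------------------------------------------------------------------------
# Model construction

def select_match_columns(msa: Msa, gap_fraction_threshold: float = 0.5) -> list[int]:
    """Columns whose gap fraction is strictly below the threshold.

    These become match states; the rest are treated as insertions.  An
    alignment yielding no match column cannot support a model and raises
    :class:`ConstructionError`.
    """
    if msa.n_rows == 0:
        raise ConstructionError("cannot build a model from an empty alignment")
    cols = []
    for j in range(msa.n_cols):
        column = msa.column(j)
        gap_fraction = sum(1 for ch in column if ch in "-.") / msa.n_rows
        if gap_fraction < gap_fraction_threshold:
            cols.append(j)
    if not cols:
        raise ConstructionError(
            "no match columns: every alignment column is at least "
            f"{gap_fraction_threshold:.0%} gaps"
        )
    return cols


@dataclass(frozen=True)
class ProfileHmm:
    """Estimated profile HMM.

    ``match_emissions``: (n_match, 20); ``insert_emissions``: (n_match+1, 20);
    ``transitions``: (n_match+1, 3, 3) giving, for source node j and source
    state (0=M, 1=I, 2=D), the probability of moving to target state
    (M/I of the next node... see layout note) — concretely
    ``transitions[j, s, 0]`` is s_j -> M_{j+1} (node n_match targets End),
    ``transitions[j, s, 1]`` is s_j -> I_j, and ``transitions[j, s, 2]``
    is s_j -> D_{j+1}.  Node 0's M row is the Begin state; delete rows at
    node 0 and D-targets at the last node are structurally zero.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        M = self.n_match
        if M < 1:
            raise ConstructionError("a profile needs at least one match state")
        for name, arr, expect in (
            ("match_emissions", self.match_emissions, (M, 20)),
            ("insert_emissions", self.insert_emissions, (M + 1, 20)),
            ("transitions", self.transitions, (M + 1, 3, 3)),
            ("background", self.background, (20,)),
        ):
            if arr.shape != expect:
                raise ConstructionError(f"{name}: shape {arr.shape} != {expect}")
            if np.any(arr < 0):
                raise ConstructionError(f"{name}: negative probability")
        for name, rows in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
            ("background", self.background[None, :]),
        ):
            sums = rows.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ConstructionError(f"{name}: rows do not sum to 1")
        # Transition rows sum to 1 over their structurally allowed targets.
        tsums = self.transitions.sum(axis=-1)
        valid = np.ones_like(tsums, dtype=bool)
        valid[0, 2] = False  # no D state at node 0
        if not np.allclose(tsums[valid], 1.0, atol=1e-9):
            raise ConstructionError("transitions: rows do not sum to 1")


def _state_path(row: str, is_match: np.ndarray) -> list[tuple[str, int]]:
    """(state, node) sequence for one aligned row, Begin/End excluded."""
    path = []
    node = 0
    for j, ch in enumerate(row):
        if is_match[j]:
            node += 1
            path.append(("D" if ch in "-." else "M", node))
        elif ch not in "-.":
            path.append(("I", node))
    return path


_STATE_IDX = {"M": 0, "I": 1, "D": 2}


def estimate_parameters(
    msa: Msa, match_columns: Sequence[int], pseudocount: float = 1.0
) -> ProfileHmm:
    """Estimate a :class:`ProfileHmm` from an alignment by counting.

    Emissions: ``(count + pc) / (total + 20 pc)`` per state.  Transitions:
    counted along each row's Begin -> ... -> End state path, smoothed with
    ``+pc`` over the structurally allowed targets of each node.
    Background: overall residue frequency of the ungapped alignment
    residues, with the same ``+pc`` smoothing.
    """
    M = len(match_columns)
    if M == 0:
        raise ConstructionError("match_columns is empty")
    is_match = np.zeros(msa.n_cols, dtype=bool)
    is_match[list(match_columns)] = True

    em_match = np.zeros((M, 20))
    em_insert = np.zeros((M + 1, 20))
    trans = np.zeros((M + 1, 3, 3))
    bg = np.zeros(20)

    for _, row in msa.rows:
        for ch in row:
            if ch in _AA_INDEX:
                bg[_AA_INDEX[ch]] += 1
        path = _state_path(row, is_match)
        # Emission counts: walk the columns (cheap, keeps path logic simple).
        node = 0
        for j, ch in enumerate(row):
            if is_match[j]:
                node += 1
                if ch in _AA_INDEX:
                    em_match[node - 1, _AA_INDEX[ch]] += 1
            elif ch in _AA_INDEX:
                em_insert[node, _AA_INDEX[ch]] += 1
        # Transition counts, Begin = ("M", 0), End = ("M", M+1).
        full = [("M", 0)] + path + [("M", M + 1)]
        for (s1, n1), (s2, n2) in zip(full, full[1:]):
            trans[n1, _STATE_IDX[s1], _STATE_IDX[s2]] += 1

    pc = float(pseudocount)
    em_match = (em_match + pc) / (em_match.sum(axis=1, keepdims=True) + 20 * pc)
    em_insert = (em_insert + pc) / (em_insert.sum(axis=1, keepdims=True) + 20 * pc)
    bg = (bg + pc) / (bg.sum() + 20 * pc)

    smoothed = np.zeros_like(trans)
    for node in range(M + 1):
        sources = (0, 1) if node == 0 else (0, 1, 2)  # no D at node 0
        targets = (0, 1) if node == M else (0, 1, 2)  # no D past last node
        for s in sources:
            row = trans[node, s, list(targets)] + pc
            smoothed[node, s, list(targets)] = row / row.sum()
    return ProfileHmm(
        name="profile",
        match_emissions=em_match,
        insert_emissions=em_insert,
        transitions=smoothed,
        background=bg,
    )


def build_profile(
    msa: Msa, name: str = "profile", gap_fraction_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHmm:
    """Convenience: column selection + parameter estimation."""
    cols = select_match_columns(msa, gap_fraction_threshold)
    hmm = estimate_parameters(msa, cols, pseudocount)
    return replace(hmm, name=name)


def consensus_sequence(hmm: ProfileHmm) -> str:
    """Most probable residue of each match state."""
    return "".join(AA20[i] for i in hmm.match_emissions.argmax(axis=1))


# ---------------------------------------------------------------------------
# Forward algorithm

def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def _lse3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.logaddexp(np.logaddexp(a, b), c)


def _delete_chain(vm: np.ndarray, vi: np.ndarray, tMD, tID, tDD) -> np.ndarray:
    """Propagate probability through the delete-state chain at one position.

    ``D_j = lse(M_{j-1} + t_MD[j-1], I_{j-1} + t_ID[j-1], D_{j-1} + t_DD[j-1])``
    is a linear recurrence; dividing through by the running product of
    D->D transitions turns it into a cumulative log-sum-exp.
    """
    M = len(vm) - 1
    out = np.full(M + 1, _NEG)
    if M == 0:
        return out
    # Entry into D_j from the previous node's M/I states, j = 1..M.
    a = np.logaddexp(vm[:-1] + tMD[:-1], vi[:-1] + tID[:-1])
    # c[j] = log t(D_j -> D_{j+1}) contributing to D_{j+1}; align so that
    # cum[j] is the accumulated D->D weight entering D_{j+1}.
    c = np.concatenate(([0.0], tDD[1:M]))
    cum = np.cumsum(c)
    out[1:] = cum + np.logaddexp.accumulate(a - cum)
    return out


def forward_logprob(hmm: ProfileHmm, seq: str) -> float:
    """log P(seq | hmm) via the forward recursion in log space."""
    if not seq:
        raise ConfigError("cannot score an empty sequence")
    M = hmm.n_match
    lem_M = _log(hmm.match_emissions)          # (M, 20)
    lem_I = _log(hmm.insert_emissions)         # (M+1, 20)
    lt = _log(hmm.transitions)                 # (M+1, 3, 3)
    # Structurally absent transitions must be -inf, not log(0 + smoothing).
    lt = lt.copy()
    lt[0, 2, :] = _NEG
    tMM, tMI, tMD = lt[:, 0, 0], lt[:, 0, 1], lt[:, 0, 2]
    tIM, tII, tID = lt[:, 1, 0], lt[:, 1, 1], lt[:, 1, 2]
    tDM, tDD, tDI = lt[:, 2, 0], lt[:, 2, 2], lt[:, 2, 1]

    x = _encode(seq)
    vM = np.full(M + 1, _NEG)
    vM[0] = 0.0  # Begin
    vI = np.full(M + 1, _NEG)
    vD = _delete_chain(vM, vI, tMD, tID, tDD)

    for xi in x:
        # 'X' (unknown residue): emission probability 1 under the model.
        eM = lem_M[:, xi] if xi >= 0 else np.zeros(M)
        eI = lem_I[:, xi] if xi >= 0 else np.zeros(M + 1)
        newM = np.full(M + 1, _NEG)
        newM[1:] = eM + _lse3(
            vM[:-1] + tMM[:-1], vI[:-1] + tIM[:-1], vD[:-1] + tDM[:-1]
        )
        newI = eI + _lse3(vM + tMI, vI + tII, vD + tDI)
        newD = _delete_chain(newM, newI, tMD, tID, tDD)
        vM, vI, vD = newM, newI, newD

    return float(_lse3(vM[M] + tMM[M], vI[M] + tIM[M], vD[M] + tDM[M]))


def null_logprob(hmm: ProfileHmm, seq: str) -> float:
    """log P(seq | background), 'X' contributing probability 1."""
    lbg = _log(hmm.background)
    x = _encode(seq)
    return float(lbg[x[x >= 0]].sum())


def forward_score(hmm: ProfileHmm, seq: str | ProteinRecord) -> float:
    """Log-odds score in bits: log2 P(seq|hmm) / P(seq|background)."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    return (forward_logprob(hmm, s) - null_logprob(hmm, s)) / _LN2


# ---------------------------------------------------------------------------
# E-value calibration

@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel location/slope for converting bit scores to E-values."""

    mu: float
    lam: float
    n_decoys: int
    decoy_len: int
    db_size: int
    method: str = "conjugate"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise CalibrationError("Gumbel slope lambda must be positive")
        if self.n_decoys < 100:
            raise CalibrationError("calibration needs at least 100 decoys")


def calibrate_evalues(
    hmm: ProfileHmm,
    n_decoys: int = 200,
    decoy_len: int = 320,
    seed: int = 0,
    method: Literal["conjugate", "mle"] = "conjugate",
    db_size: int | None = None,
) -> EvalueCalibration:
    """Score i.i.d. background decoys and calibrate the Gumbel parameters.

    ``conjugate`` (default) fixes ``lambda = ln 2`` per bit and sets ``mu``
    to the decoys' 36.8th percentile (the Gumbel CDF value at its
    location), so the location check P(score > mu) ~ 0.632 holds by
    construction and the slope matches the exponential tail law of
    log-odds scores.  ``mle`` fits both parameters to the decoy scores by
    maximum likelihood.  Deterministic under ``seed``.
    """
    if n_decoys < 100:
        raise CalibrationError("n_decoys must be >= 100")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        decoy = "".join(rng.choice(_AA, p=hmm.background, size=decoy_len))
        scores[i] = forward_score(hmm, decoy)
    if np.std(scores) < 1e-12:
        raise CalibrationError("degenerate decoy score variance")
    if method == "conjugate":
        mu = float(np.quantile(scores, _LOCATION_QUANTILE))
        lam = _LN2
    elif method == "mle":
        loc, scale = gumbel_r.fit(scores)
        mu, lam = float(loc), float(1.0 / scale)
    else:
        raise ConfigError(f"unknown calibration method {method!r}")
    return EvalueCalibration(
        mu=mu, lam=lam, n_decoys=n_decoys, decoy_len=decoy_len,
        db_size=db_size if db_size is not None else n_decoys, method=method,
    )

_AA = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")


def evalue(score: float, calib: EvalueCalibration, db_size: int | None = None) -> float:
    """Expected number of decoy scores >= ``score`` in a database.

    ``E = db_size * (1 - GumbelCDF(score))``, computed through the
    survival function so the far tail does not round to zero prematurely;
    exactly linear in ``db_size`` and monotone decreasing in the score.
    """
    n = calib.db_size if db_size is None else db_size
    sf = gumbel_r.sf(score, loc=calib.mu, scale=1.0 / calib.lam)
    return float(n * sf)


# ---------------------------------------------------------------------------
# Classification

@dataclass(frozen=True)
class ClassificationResult:
    candidate_id: str
    score_bsh: float
    score_pva: float
    evalue_bsh: float
    evalue_pva: float
    label: Literal["BSH", "PVA", "removed"]
    ambiguous: bool = False


def classify(
    candidate: ProteinRecord,
    hmm_bsh: ProfileHmm,
    hmm_pva: ProfileHmm,
    calib_bsh: EvalueCalibration,
    calib_pva: EvalueCalibration,
    retention_evalue: float = 1e-99,
    db_size: int | None = None,
    retain_strong: bool = True,
) -> ClassificationResult:
    """Score a candidate under both models and assign a label.

    With ``retain_strong`` (default, the reading under which the published
    filter makes sense) a candidate is kept only when its best-model
    E-value is below ``retention_evalue``; the label is the model with the
    smaller E-value.  An exact tie is flagged ambiguous and removed.
    The inverted literal reading (remove E < threshold) is available via
    ``retain_strong=False``.
    """
    s_bsh = forward_score(hmm_bsh, candidate)
    s_pva = forward_score(hmm_pva, candidate)
    e_bsh = evalue(s_bsh, calib_bsh, db_size)
    e_pva = evalue(s_pva, calib_pva, db_size)
    best = min(e_bsh, e_pva)
    if retain_strong:
        removed = not (best < retention_evalue)
    else:
        removed = best < retention_evalue
    ambiguous = e_bsh == e_pva
    if removed or ambiguous:
        label = "removed"
    else:
        label = "BSH" if e_bsh < e_pva else "PVA"
    return ClassificationResult(
        candidate_id=candidate.id,
        score_bsh=s_bsh,
        score_pva=s_pva,
        evalue_bsh=e_bsh,
        evalue_pva=e_pva,
        label=label,
        ambiguous=ambiguous and not removed,
    )


def classify_all(
    candidates: Sequence[ProteinRecord],
    hmm_bsh: ProfileHmm,
    hmm_pva: ProfileHmm,
    calib_bsh: EvalueCalibration,
    calib_pva: EvalueCalibration,
    retention_evalue: float = 1e-99,
    retain_strong: bool = True,
) -> list[ClassificationResult]:
    """Classify a whole candidate set, with db_size = len(candidates)."""
    n = max(1, len(candidates))
    return [
        classify(
            c, hmm_bsh, hmm_pva, calib_bsh, calib_pva,
            retention_evalue=retention_evalue, db_size=n,
            retain_strong=retain_strong,
        )
        for c in candidates
    ]


# ---------------------------------------------------------------------------
# Plain-text model serialization

def write_profile(hmm: ProfileHmm, path) -> None:
    """Serialize a profile to a documented plain-text format."""
    with open(path, "w") as fh:
        fh.write(f"# bshscan profile 1\nname\t{hmm.name}\n")
        fh.write(f"n_match\t{hmm.n_match}\nalphabet\t{AA20}\n")
        fh.write("background\t" + "\t".join(f"{p:.10g}" for p in hmm.background) + "\n")
        for j in range(hmm.n_match):
            fh.write(f"match\t{j + 1}\t"
                     + "\t".join(f"{p:.10g}" for p in hmm.match_emissions[j]) + "\n")
        for j in range(hmm.n_match + 1):
            fh.write(f"insert\t{j}\t"
                     + "\t".join(f"{p:.10g}" for p in hmm.insert_emissions[j]) + "\n")
        for j in range(hmm.n_match + 1):
            flat = hmm.transitions[j].reshape(-1)
            fh.write(f"trans\t{j}\t" + "\t".join(f"{p:.10g}" for p in flat) + "\n")


def read_profile(path) -> ProfileHmm:
    name = "profile"
    n_match = None
    background = None
    match_rows = {}
    insert_rows = {}
    trans_rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            key = parts[0]
            if key == "name":
                name = parts[1]
            elif key == "n_match":
                n_match = int(parts[1])
            elif key == "alphabet":
                if parts[1] != AA20:
                    raise ConstructionError("profile uses an unexpected alphabet")
            elif key == "background":
                background = np.array([float(v) for v in parts[1:]])
            elif key == "match":
                match_rows[int(parts[1])] = [float(v) for v in parts[2:]]
            elif key == "insert":
                insert_rows[int(parts[1])] = [float(v) for v in parts[2:]]
            elif key == "trans":
                trans_rows[int(parts[1])] = np.array(
                    [float(v) for v in parts[2:]]
                ).reshape(3, 3)
    if n_match is None or background is None:
        raise ConstructionError(f"{path}: incomplete profile file")
    return ProfileHmm(
        name=name,
        match_emissions=np.array([match_rows[j + 1] for j in range(n_match)]),
        insert_emissions=np.array([insert_rows[j] for j in range(n_match + 1)]),
        transitions=np.array([trans_rows[j] for j in range(n_match + 1)]),
        background=background,
    )
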