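"""Six-frame translation, ORF boundary semantics, and the alignment screen."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bshscan import orfscreen, simulate
from bshscan.errors import ConfigError
from bshscan.seqio import AA20, GenomeRecord, ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_CODON = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _CODON[_c1 + _c2 + _c3] = None
# Independent per-codon lookup built from the standard genetic code string.
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate(sorted(_CODON, key=lambda c: ["TCAG".index(x) for x in c])):
    _CODON[_codon] = _AA_ORDER[_i]


def naive_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _CODON:
            out.append(_CODON[codon])
        else:
            # Ambiguous codon: resolve when every substitution of N agrees.
            options = {
                _CODON["".join(c)]
                for c in __import__("itertools").product(
                    *[("ACGT" if ch == "N" else ch) for ch in codon]
                )
            }
            out.append(options.pop() if len(options) == 1 else "X")
    return "".join(out)


class TestSixFrameTranslate:
    def test_simple_codons(self):
        frames = orfscreen.six_frame_translate(GenomeRecord("g", "ATGGCTTAA"))
        assert frames.translations[1] == "MA*"

    def test_reverse_complement_consistency(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 60))))
            f = orfscreen.six_frame_translate(GenomeRecord("g", seq))
            g = orfscreen.six_frame_translate(GenomeRecord("g", simulate.revcomp(seq)))
            assert f.translations[-1] == g.translations[1]

    def test_matches_codon_lookup_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(3, 120))))
            frames = orfscreen.six_frame_translate(GenomeRecord("g", seq))
            rc = simulate.revcomp(seq)
            for k in (1, 2, 3):
                assert frames.translations[k] == naive_translate(seq[k - 1 :])
                assert frames.translations[-k] == naive_translate(rc[k - 1 :])

    def test_too_short_sequence_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            frames = orfscreen.six_frame_translate(GenomeRecord("g", "AT"))
        assert all(v == "" for v in frames.translations.values())


def _genome_with_orf(n_residues: int) -> GenomeRecord:
    """Forward-strand genome carrying one ATG-to-stop ORF of n residues."""
    body = "ATG" + "GCT" * (n_residues - 1) + "TAA"
    return GenomeRecord("g", "CCTAA" + body + "CCCCC")


class TestExtractOrfs:
    def test_99_residue_orf_removed_100_kept(self):
        for n, expected in ((99, 0), (100, 1)):
            frames = orfscreen.six_frame_translate(_genome_with_orf(n))
            orfs = orfscreen.extract_orfs(frames, min_orf_len=100)
            plus = [o for o in orfs if o.frame > 0]
            assert len(plus) == expected, f"{n}-aa ORF"

    def test_coordinates_and_protein(self):
        frames = orfscreen.six_frame_translate(_genome_with_orf(100))
        orf = orfscreen.extract_orfs(frames, 100)[0]
        assert (orf.end - orf.start) % 3 == 0
        assert len(orf.protein.sequence) == (orf.end - orf.start) // 3 - 1
        assert orf.protein.sequence == "M" + "A" * 99

    def test_recovers_planted_320aa_protein(self, family_pair):
        _, _, cons_b, _ = family_pair
        prot = ProteinRecord("p", cons_b)
        genome, truth = simulate.embed_in_genome([prot], 80, seed=3, genome_id="g")
        orfs = orfscreen.extract_orfs(orfscreen.six_frame_translate(genome), 100)
        row = truth.iloc[0]
        match = [o for o in orfs if (o.start, o.end) == (row.start, row.end)]
        assert len(match) == 1
        assert match[0].protein.sequence == cons_b


def sw_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Explicit 3-state affine-gap local DP (Gotoh), independent of the
    implementation under test."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)
    M[:, 0] = M[0, :] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0) + s
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestSmithWaterman:
    def test_self_alignment_full_identity(self):
        res = orfscreen.smith_waterman("MKVLAWCD", "MKVLAWCD")
        assert res.identity == 1.0
        assert res.aligned_a == "MKVLAWCD"

    def test_unrelated_short_sequences_no_alignment(self):
        res = orfscreen.smith_waterman("AAAA", "GGGG")
        assert res.score == 0.0 and res.identity == 0.0

    def test_score_matches_affine_dp_oracle(self):
        rng = np.random.default_rng(3)
        aa = list(AA20)
        for _ in range(120):
            a = "".join(rng.choice(aa, size=int(rng.integers(1, 30))))
            b = "".join(rng.choice(aa, size=int(rng.integers(1, 30))))
            expected = sw_oracle(a, b)
            got = orfscreen.smith_waterman(a, b).score
            assert got == pytest.approx(max(expected, 0.0))

    def test_cdhit_denominator(self):
        res = orfscreen.smith_waterman("MKVLAW", "MKVLAWCDCDCD", identity_mode="cdhit")
        assert res.identity == 1.0  # 6 matches / min length 6


def _orf_for(protein: ProteinRecord) -> orfscreen.Orf:
    n = len(protein.sequence)
    return orfscreen.Orf("g", 1, 0, 3 * (n + 1), protein)


def _mutant(ref: str, n_mut: int) -> str:
    """Evenly spaced conservative substitutions away from the ends.

    Each mutated residue becomes its best-scoring BLOSUM62 alternative,
    so the optimal local alignment stays full-span and gap-free and the
    identity is exactly (len - n_mut) / len.
    """
    out = list(ref)
    idx = np.linspace(2, len(ref) - 3, n_mut).astype(int)
    assert len(set(idx)) == n_mut
    for i in idx:
        orig = ref[i]
        out[i] = max(
            (aa for aa in AA20 if aa != orig), key=lambda aa: BLOSUM62[orig, aa]
        )
    return "".join(out)


class TestScreenCandidates:
    def test_identical_orf_hits_its_reference(self, family_pair):
        _, _, cons_b, _ = family_pair
        ref = ProteinRecord("ref1", cons_b)
        orf = _orf_for(ProteinRecord("o", cons_b))
        cands = orfscreen.screen_candidates([orf], [ref])
        assert len(cands) == 1
        assert cands[0].best_ref_id == "ref1"
        assert cands[0].best_identity == 1.0

    def test_identity_floor_boundary(self, family_pair):
        """Removal of <30% hits keeps a 30% hit and drops a 29% one."""
        _, _, cons_b, _ = family_pair
        ref = ProteinRecord("ref1", cons_b[:100])
        at_29 = _mutant(ref.sequence, 71)
        at_30 = _mutant(ref.sequence, 70)
        res29 = orfscreen.smith_waterman(at_29, ref.sequence)
        res30 = orfscreen.smith_waterman(at_30, ref.sequence)
        assert res29.identity == pytest.approx(0.29)
        assert res30.identity == pytest.approx(0.30)
        kept = orfscreen.screen_candidates(
            [_orf_for(ProteinRecord("a29", at_29)), _orf_for(ProteinRecord("a30", at_30))],
            [ref],
        )
        assert [c.orf.protein.id for c in kept] == ["a30"]

    def test_true_members_kept_decoys_dropped(self, family_pair, reference_profiles):
        spec_b, _, cons_b, _ = family_pair
        refs = reference_profiles["refs_bsh"]
        rng = np.random.default_rng(8)
        orfs = []
        for i in range(10):
            member = simulate.evolve_member(cons_b, 0.3, spec_b.motif_blocks, 600 + i)
            orfs.append(_orf_for(ProteinRecord(f"t{i}", member)))
        for i in range(10):
            decoy = "M" + simulate._random_protein(319, rng)
            orfs.append(_orf_for(ProteinRecord(f"d{i}", decoy)))
        # Give each ORF its own locus so collapse does not interfere.
        orfs = [
            orfscreen.Orf("g", 1, 2000 * k, 2000 * k + o.end, o.protein)
            for k, o in enumerate(orfs)
        ]
        kept = {c.orf.protein.id for c in orfscreen.screen_candidates(orfs, refs)}
        assert {f"t{i}" for i in range(10)} <= kept
        n_decoys_kept = sum(1 for pid in kept if pid.startswith("d"))
        assert n_decoys_kept <= 1  # >=90% of decoys excluded

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ConfigError):
            orfscreen.screen_candidates([], [])

    def test_threshold_monotonicity(self, family_pair, reference_profiles):
        spec_b, _, cons_b, _ = family_pair
        refs = reference_profiles["refs_bsh"][:5]
        orfs = [
            orfscreen.Orf(
                "g", 1, 3000 * i, 3000 * i + 963,
                ProteinRecord(
                    f"m{i}",
                    simulate.evolve_member(cons_b, 0.05 * i, spec_b.motif_blocks, i),
                ),
            )
            for i in range(8)
        ]
        counts = [
            len(orfscreen.screen_candidates(orfs, refs, min_ref_identity=t))
            for t in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry(self, family_pair, reference_profiles):
        """Screening a genome and its reverse complement yields the same
        candidate protein set."""
        _, _, cons_b, _ = family_pair
        genome, _ = simulate.embed_in_genome(
            [ProteinRecord("p", cons_b)], 60, seed=12, genome_id="g"
        )
        flipped = GenomeRecord("g", simulate.revcomp(genome.sequence))
        refs = reference_profiles["refs_bsh"][:5]

        def screen(g):
            orfs = orfscreen.extract_orfs(orfscreen.six_frame_translate(g), 100)
            return {
                c.orf.protein.sequence
                for c in orfscreen.screen_candidates(orfs, refs)
            }

        assert screen(genome) == screen(flipped)

    def test_retained_candidates_respect_min_orf_len(self, bundle):
        b, _ = bundle
        refs = b.refs_bsh
        orfs = []
        for genome in b.genomes[:2]:
            orfs.extend(
                orfscreen.extract_orfs(orfscreen.six_frame_translate(genome), 100)
            )
        for c in orfscreen.screen_candidates(orfs, refs):
            assert len(c.orf.protein.sequence) >= 100
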