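# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `bshscan`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Bile salt hydrolases (BSH) and penicillin-V acylases (PVA) are members
of the same linear amide C–N hydrolase family and are frequently
misannotated for one another. The pipeline answers, for a set of
genomes: which loci encode a family member at all, whether each member
is a BSH or a PVA, how the BSH complement distributes over species and
strains, which alignment regions are conserved, and how presence/absence
correlates with species lifestyle.

## Synthetic data generator

The generator is the study substrate: all pipeline-level claims are made
on data it produces, with truth labels.

**Families.** Two consensus sequences of 320 residues (the typical BSH
length) are constructed to share a target fraction of identical
positions (`shared_ancestry`, default 0.40 — the two real families are
homologous but separable). Motif anchor blocks are written first
(disjoint runs of ≥3 residues; the BSH-like family carries the six
canonical catalytic positions Cys2, Arg18, Asp21, Asn82, Asn175, Arg228;
both families share the N-terminal Met/Cys anchor), then exactly enough
free positions are made identical or forced to differ to land the
overall identity on target. Family members are evolved by independent
per-site substitution at rate `family_divergence` (default 0.30, chosen
so that within-family identities fall in the broad 30–95% range reported
for real BSH representatives), uniformly over the 19 alternative
residues, never touching anchors; no indels by default. Strain-level
copies add a further 2% divergence from their species founder, so
same-species copies cluster together at the 95% threshold while paralogs
and cross-species copies do not.

**Genomes.** Each protein is reverse-translated with uniform synonymous
codon choice (bacterial code; ATG is the only start used), wrapped as
`flank + TAA + CDS + stop + flank` and placed on a random strand. The
in-frame TAA directly upstream of the start codon guarantees that the
planted ATG opens the maximal ORF, so extraction recovers the exact
coordinates. Default copy-number probabilities mirror the published
survey shape (23% of species BSH-positive with a 64/28/8
single/two/three-copy split; 48% PVA-positive); 15% of strains of a
positive species drop the family (the survey reports 4.35–100%
within-species positivity); one random decoy protein (150–400 aa) per
genome exercises the screen. Lifestyle labels are sampled per species
with weights following the published niche association (BSH-positive
species predominantly vertebrate-adapted, and so on). One marker gene
per species is evolved along a random known species tree for the
species-tree stage.

**What the generator does not emulate:** codon-usage bias, indel-rich
evolution, phylogenetically correlated sampling, contig fragmentation,
and real within-family substitution structure (substitutions are uniform,
so BLOSUM-style residue similarity carries no signal between true family
members — which makes the classification task *harder* than on real
data, not easier). Passing tests therefore demonstrate the machinery is
correct and well calibrated on a controlled homology structure, not that
real-genome discovery rates are reproduced.

## ORF screen

ORFs are maximal ATG-to-stop segments per frame (first Met after the
previous stop; ORFs not closed by a stop are ignored). The 100-aa floor
keeps length-exactly-100 ORFs ("less than 100" removed). Alignment is
optimal local Smith–Waterman with affine gaps (BLOSUM62, open 11,
extend 1 — translated-search defaults), via Biopython's `PairwiseAligner`;
an independent hand-written Gotoh DP is the oracle in the tests.

Identity conventions: the screen reports identical pairs / aligned
columns (gap columns included — the translated-search convention);
clustering uses identical pairs / length of the shorter sequence (the
CD-HIT convention). Both are exposed on every alignment call.

Percent identity over a local alignment is meaningless when the
alignment is a 10-column island, and random ORFs routinely reach
30–100% identity on such islands. The screen therefore also requires
the best alignment to span at least 50% of the shorter sequence
(`min_coverage`). With it, every planted decoy in the default bundle is
excluded while genuinely homologous candidates (which align end to end
at these divergences) are untouched. Overlapping ORFs at one locus are
collapsed to the highest-identity candidate.

The full pipeline screens against the union of the BSH and PVA
reference sets: the classifier must see the PVA candidates, and
cross-family identity sits close to the shared-ancestry fraction
(~26–31% against a diverged reference), i.e. right at the 30% floor.

## Profile HMMs and classification

Architecture: match/insert/delete per node, insert states I_0..I_m for
terminal overhangs, all nine transition types per node, estimated from
the reference alignment's state paths with +1 Laplace smoothing (match
columns: gap fraction < 0.5; emissions `(count+1)/(total+20)`;
background: smoothed overall residue frequency). Scoring is the full
forward algorithm in log space; the delete-state chain within one
sequence position is a linear recurrence solved as a cumulative
log-sum-exp, so the whole recursion is vectorised over model nodes and
exact (verified against exhaustive path enumeration to ≤1e-9 on toy
models; observed agreement ~1e-15). Scores are log-odds bits against
the background; unknown residues ('X') contribute zero bits.

**E-values.** `E(S) = db_size × (1 − GumbelCDF(S; μ, λ))` with the
survival function evaluated in the far tail (no premature underflow to
zero until the exponent itself underflows). The default calibration
fixes `λ = ln 2` per bit — the conjugate/Chernoff tail slope that holds
universally for likelihood-ratio scores, `P(S > t) ≤ 2^{-t}`, and the
slope profile-search tools use for forward scores — and anchors `μ` at
the 36.8th percentile (the Gumbel CDF value at its location) of 150–200
decoy scores drawn i.i.d. from the background. This choice is forced by
arithmetic: decoy forward scores for a 320-state model are
near-Gaussian with a standard deviation of ~15 bits, so a
maximum-likelihood Gumbel fit (available as `method="mle"`) yields
λ ≈ 0.1/bit and can never produce E-values below ~1e-30 — yet the
pipeline's retention rule demands E < 1e-99 for genuine hits, which the
conjugate slope delivers (true members score 600–1000 bits above the
decoy location, E ≈ 1e-150 and below, while decoys stay at E ≳ 1e-7).

**Retention.** The filter phrase "remove false positives (E values less
than 1e-99)" is implemented as: *retain* only candidates whose
best-model E-value is below 1e-99 — the only direction under which the
filter removes weak hits. The literal inversion is available via
`retain_strong=False`. Labels: the smaller-E model wins; an exact tie is
removed and flagged ambiguous.

## Clustering, motifs, trees, summaries

**Clustering** is greedy and exact: longest-first (ties by id), each
sequence joins the first representative it matches at ≥ the threshold,
else founds a cluster — no k-mer prefilter, correctness over speed at
desk scale. Guarantees verified by brute force in the tests: every
member ≥ threshold to its representative, no representative pair ≥
threshold. Cluster names join the sorted species abbreviations (last
binomial token) with `_and_`, plus a per-name ordinal.

**Conservation** is the modal-residue fraction with gaps in the
denominator (simplest score on [0,1] matching a 0.75 threshold; a
Shannon-entropy variant sits behind a flag; modal ties break
alphabetically). Motifs are maximal runs of ≥ `min_motif_len` (3)
columns at ≥ `conservation_threshold` (0.75), reported in 1-based
alignment columns with a mapping to each representative's ungapped
coordinates. The active-site audit defaults to the Cys2 anchor only;
further site/column pairs are caller-supplied.

**Trees**: p-distance (pairwise gap deletion) or Poisson-corrected
distances; Saitou–Nei neighbor joining with two pinned details — Q-ties
break on the smallest (i, j) index pair, and a negative branch estimate
is clamped to zero with the deficit moved to its sister edge, preserving
path lengths — making the method exact on additive matrices (asserted
to 1e-9) and deterministic everywhere. Bootstrap resamples alignment
columns, rebuilds the tree per replicate, and scores each internal
bipartition of the full-data tree; supports are written as internal
Newick labels. Containers and Newick I/O come from scikit-bio;
scikit-bio's own NJ serves as an independent cross-check in the tests,
never as the implementation.

**Summaries** follow the published table semantics: per-species rows
only for species with ≥1 BSH-positive strain (a companion full table
includes the zeros), percentages rounded half-up to 2 dp (whole percent
for the copy-number multiplicity split), and inclusive counting — the
BSH and PVA species sets both include the species encoding both, the
only reading under which `pva + bsh − both + neither = total` holds for
the published counts (82 + 39 − 8 + 57 = 170). The abstract-level "28%"
figure corresponds to (BSH + both)/total = 47/170 ≈ 27.6% and is
derivable from the emitted tables; the per-class tables report the
22.94% reading.

**Representative alignment.** The default generator produces no indels,
so equal-length representative sets are stacked column for column;
unequal-length sets are aligned with mafft (`--auto`), and a precomputed
Stockholm alignment can be supplied instead.

## Determinism and manifests

One seed drives everything: dataset generation, decoy calibration
(`rng_seed*2+1` / `*2+2` for the two models), and bootstrap resampling.
All file output uses fixed float formats, so a rerun is byte-identical;
the run manifest records config, input/output SHA-256 digests and stage
order, with wall-clock timings under a separate key that reproducibility
comparisons ignore.

## Problem sizes

The shipped analyses and checks run at desk scale, chosen to finish in
seconds to minutes on one CPU while still exercising every code path:
12 species × 3 strains (36 genomes, ~5 kb each) for the narrative
survey; 4 × 2 for the pipeline determinism checks; 400 members for the
classifier recovery figure; 150–200 decoys per calibration; 50 random
datasets for the clustering audit; 100 bootstrap replicates.

## Known limitations

- The headline discovery counts of the real survey (490 BSH / 1,149 PVA
  proteins, 57 clusters, 12 motifs, the 170-species tree) depend on a
  historical genome snapshot and are not recomputed here; the summary
  arithmetic over the printed counts is.
- The E-value calibration anchors only the location on decoys; the tail
  slope is theoretical. Absolute E-values are therefore comparable
  across models but should be read as orders of magnitude.
- The greedy clustering is order-dependent by design (longest-first);
  it reproduces the convention of the tool it stands in for rather than
  an optimal partition.
- Frameshift-tolerant alignment, GenBank/GFF input, and HMMER file
  compatibility are explicitly out of scope.
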