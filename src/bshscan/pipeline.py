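"""End-to-end orchestration: screen -> classify -> cluster -> align ->
motifs -> trees -> repertoire summaries.

``run_all`` drives the whole flow on a bundle directory (as produced by
:func:`bshscan.simulate.generate_dataset` or assembled by hand from the
documented formats), persists every stage's output under a run
directory, and returns a manifest with input/output digests.  Outputs
are a pure function of (inputs, config), so a rerun reproduces them
byte for byte; wall-clock stage timings are stored under a separate
manifest key that reproducibility comparisons ignore.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
import tempfile
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import BshScanError, ConfigError
from . import cluster as _cluster
from . import hmmclass, motifscan, orfscreen, phylo, repertoire
from .seqio import (
    GenomeRecord,
    Msa,
    PipelineConfig,
    ProteinRecord,
    read_fasta,
    read_metadata,
    read_stockholm,
    write_fasta,
)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    rng_seed: int
    inputs: dict[str, str]
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def comparable(self) -> dict:
        """Manifest content that must be identical across reruns."""
        d = {k: v for k, v in asdict(self).items() if k != "timings"}
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None and not isinstance(exc, BshScanError):
                raise BshScanError(f"stage {name!r} failed: {exc}") from exc
            manifest.stages.append(name)
            return False

    return _Timer()


def align_proteins(records: list[ProteinRecord]) -> Msa:
    """Align representative proteins.

    The default generator introduces no indels, so equal-length inputs
    are stacked column for column.  Unequal lengths are aligned with
    mafft (``--auto``); a precomputed Stockholm alignment can always be
    supplied to ``run_all`` instead.
    """
    if not records:
        raise ConfigError("align_proteins needs at least one sequence")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) == 1:
        return Msa(rows=tuple((r.id, r.sequence) for r in records))
    if shutil.which("mafft") is None:
        raise ConfigError(
            "sequences have unequal lengths and mafft is not on PATH; "
            "supply a precomputed Stockholm alignment instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        write_fasta(records, fin)
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fin)],
            capture_output=True, text=True, check=True,
        )
    rows = []
    rid, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if rid is not None:
                rows.append((rid, "".join(chunks).upper()))
            rid, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if rid is not None:
        rows.append((rid, "".join(chunks).upper()))
    return Msa(rows=tuple(rows))


def run_all(
    config: PipelineConfig,
    bundle_dir: str | Path,
    out_dir: str | Path,
    representative_msa: str | Path | None = None,
) -> RunManifest:
    """Run every pipeline stage on a bundle directory.

    Expects the bundle layout written by the simulator: ``genomes.fna``,
    ``refs_bsh.faa``/``refs_pva.faa``, ``refs_bsh.sto``/``refs_pva.sto``,
    ``metadata.tsv``, and optionally ``markers.fna``.  All artifacts are
    written under ``out_dir``; any stage failure aborts with an error
    naming the stage.
    """
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_names = {
        "genomes": "genomes.fna",
        "refs_bsh": "refs_bsh.faa",
        "refs_pva": "refs_pva.faa",
        "msa_bsh": "refs_bsh.sto",
        "msa_pva": "refs_pva.sto",
        "metadata": "metadata.tsv",
    }
    paths: dict[str, Path] = {}
    for key, name in input_names.items():
        p = bundle / name
        if not p.exists():
            raise ConfigError(f"missing input file: {p}")
        paths[key] = p
    markers_path = bundle / "markers.fna"

    manifest = RunManifest(
        config=asdict(config),
        rng_seed=config.rng_seed,
        inputs={k: _digest(p) for k, p in sorted(paths.items())},
    )
    if markers_path.exists():
        manifest.inputs["markers"] = _digest(markers_path)

    genomes = read_fasta(paths["genomes"], "nucleotide")
    refs_bsh = read_fasta(paths["refs_bsh"], "protein")
    refs_pva = read_fasta(paths["refs_pva"], "protein")
    msa_bsh = read_stockholm(paths["msa_bsh"])
    msa_pva = read_stockholm(paths["msa_pva"])
    metadata = read_metadata(paths["metadata"])
    genome_by_id: dict[str, GenomeRecord] = {g.id: g for g in genomes}

    # ---- screen: six-frame ORFs filtered by length and reference identity
    with _stage(manifest, "screen"):
        orfs = []
        for genome in genomes:
            frames = orfscreen.six_frame_translate(genome)
            orfs.extend(orfscreen.extract_orfs(frames, config.min_orf_len))
        # Screen against both reference sets: the classifier needs the PVA
        # candidates in hand, and cross-family identity can sit right at
        # the 30% floor.
        candidates = orfscreen.screen_candidates(
            orfs, refs_bsh + refs_pva, min_ref_identity=config.min_ref_identity
        )
        cand_path = out / "candidates.tsv"
        with open(cand_path, "w") as fh:
            fh.write("genome_id\tframe\tstart\tend\tprotein_id\tbest_ref\tidentity\tscore\n")
            for c in candidates:
                fh.write(
                    f"{c.orf.genome_id}\t{c.orf.frame:+d}\t{c.orf.start}\t{c.orf.end}\t"
                    f"{c.orf.protein.id}\t{c.best_ref_id}\t{c.best_identity:.4f}\t"
                    f"{c.score:.1f}\n"
                )
        cand_proteins = [
            ProteinRecord(
                id=c.orf.protein.id,
                sequence=c.orf.protein.sequence,
                species=genome_by_id[c.orf.genome_id].species,
                strain=genome_by_id[c.orf.genome_id].strain,
            )
            for c in candidates
        ]
        write_fasta(cand_proteins, out / "candidates.faa")

    # ---- classify: dual profile HMMs with decoy-calibrated E-values
    with _stage(manifest, "classify"):
        hmm_bsh = hmmclass.build_profile(msa_bsh, name="BSH")
        hmm_pva = hmmclass.build_profile(msa_pva, name="PVA")
        calib_bsh = hmmclass.calibrate_evalues(hmm_bsh, seed=config.rng_seed * 2 + 1)
        calib_pva = hmmclass.calibrate_evalues(hmm_pva, seed=config.rng_seed * 2 + 2)
        results = hmmclass.classify_all(
            cand_proteins, hmm_bsh, hmm_pva, calib_bsh, calib_pva,
            retention_evalue=config.retention_evalue,
            retain_strong=config.retain_strong,
        )
        with open(out / "classification.tsv", "w") as fh:
            fh.write("candidate_id\tscore_bsh\tscore_pva\tevalue_bsh\tevalue_pva\tlabel\n")
            for r in results:
                fh.write(
                    f"{r.candidate_id}\t{r.score_bsh:.2f}\t{r.score_pva:.2f}\t"
                    f"{r.evalue_bsh:.6g}\t{r.evalue_pva:.6g}\t{r.label}\n"
                )
        hmmclass.write_profile(hmm_bsh, out / "profile_bsh.txt")
        hmmclass.write_profile(hmm_pva, out / "profile_pva.txt")

    # ---- cluster the BSH-labelled proteins
    with _stage(manifest, "cluster"):
        by_id = {p.id: p for p in cand_proteins}
        bsh_proteins = [by_id[r.candidate_id] for r in results if r.label == "BSH"]
        if bsh_proteins:
            clusters = _cluster.greedy_cluster(
                bsh_proteins, threshold=config.cluster_identity
            )
            clusters = _cluster.name_clusters(clusters)
            _cluster.write_clstr(clusters, out / "bsh_clusters.clstr")
            _cluster.write_cluster_tsv(clusters, out / "bsh_clusters.tsv")
            representatives = [cl.representative for cl in clusters]
            if len(representatives) >= 2:
                _cluster.write_identity_matrix(
                    _cluster.identity_matrix(representatives),
                    out / "bsh_identity_matrix.tsv",
                )
        else:
            clusters = []
            representatives = []
            (out / "bsh_clusters.tsv").write_text(
                "cluster\tname\trepresentative\tmember\tspecies\tstrain\tidentity_pct\n"
            )

    # ---- align representatives, then motifs
    with _stage(manifest, "motifs"):
        if representative_msa is not None:
            rep_msa = read_stockholm(representative_msa)
        elif representatives:
            rep_msa = align_proteins(representatives)
        else:
            rep_msa = Msa(rows=())
        if rep_msa.n_rows:
            profile = motifscan.column_conservation(rep_msa)
            motifs = motifscan.find_motifs(
                profile,
                threshold=config.conservation_threshold,
                min_len=config.min_motif_len,
            )
            motifscan.write_profile_tsv(profile, out / "conservation.tsv")
            motifscan.write_motifs_tsv(motifs, out / "motifs.tsv")
            motifscan.logo_matrix(rep_msa).to_csv(
                out / "logo_matrix.tsv", sep="\t", float_format="%.6f"
            )
            sites = motifscan.audit_active_sites(
                rep_msa, motifs, threshold=config.conservation_threshold
            )
            with open(out / "active_sites.tsv", "w") as fh:
                fh.write("residue\tcolumn\tconserved\tin_motif\tconsensus\tmatches\n")
                for s in sites:
                    fh.write(
                        f"{s.residue}\t{s.column}\t{s.conserved}\t{s.in_motif}\t"
                        f"{s.consensus_residue}\t{s.matches_expected}\n"
                    )

    # ---- trees: representative BSH tree + marker species tree
    with _stage(manifest, "tree"):
        if rep_msa.n_rows >= 3:
            tree = phylo.bootstrap_support(
                rep_msa, n_reps=config.bootstrap_reps, seed=config.rng_seed
            )
            phylo.write_newick(tree, out / "bsh_tree.nwk")
        if markers_path.exists():
            markers = read_fasta(markers_path, "nucleotide")
            if len(markers) >= 3:
                marker_msa = Msa(
                    rows=tuple(
                        (m.species.replace(" ", "_") or m.id, m.sequence)
                        for m in markers
                    )
                )
                sp_tree = phylo.neighbor_joining(
                    phylo.pairwise_distance(marker_msa, model="p-distance")
                )
                phylo.write_newick(sp_tree, out / "species_tree.nwk")

    # ---- repertoire summaries
    with _stage(manifest, "summarize"):
        labels = {r.candidate_id: r.label for r in results}
        provenance = {p.id: (p.species, p.strain) for p in cand_proteins}
        # Strains with no surviving candidate still count as zero rows.
        calls = {
            (c.species, c.strain): [0, 0]
            for c in (repertoire.StrainCallRecord(m.species, m.strain, 0, 0)
                      for m in metadata)
        }
        for pid, label in labels.items():
            key = provenance[pid]
            if key not in calls:
                calls[key] = [0, 0]
            if label == "BSH":
                calls[key][0] += 1
            elif label == "PVA":
                calls[key][1] += 1
        records = [
            repertoire.StrainCallRecord(sp, st, c[0], c[1])
            for (sp, st), c in sorted(calls.items())
        ]
        total_species = len({m.species for m in metadata}) or len(
            {r.species for r in records}
        )
        summaries = repertoire.summarize_species(records) if records else []
        if summaries:
            repertoire.write_species_table(summaries, out / "species_summary.tsv")
            mult = repertoire.bsh_multiplicity(summaries)
            rng_pct = repertoire.per_species_range(summaries)
        else:
            mult, rng_pct = {}, (0.0, 0.0)
        breakdown = repertoire.category_breakdown(records, total_species)
        crosstab = repertoire.lifestyle_crosstab(records, metadata)
        repertoire.full_species_table(records).to_csv(
            out / "presence_absence.tsv", sep="\t", index=False
        )
        report = {
            "category_breakdown": asdict(breakdown),
            "bsh_multiplicity_pct": mult,
            "pct_with_bsh_range": list(rng_pct),
            "lifestyle_crosstab": {
                "bsh_pct": crosstab.bsh_pct,
                "pva_pct": crosstab.pva_pct,
            },
            "n_candidates": len(cand_proteins),
            "n_bsh": sum(1 for r in results if r.label == "BSH"),
            "n_pva": sum(1 for r in results if r.label == "PVA"),
            "n_removed": sum(1 for r in results if r.label == "removed"),
            "n_clusters": len(clusters),
        }
        (out / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )

    manifest.outputs = {
        p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest
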