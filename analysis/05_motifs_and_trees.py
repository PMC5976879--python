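#!/usr/bin/env python
"""Inspect motif conservation and tree support from the pipeline run.

Reads the conservation profile, motif table, active-site audit and the
bootstrap-annotated representative tree produced by
02_run_discovery_pipeline.py and prints the findings: how many conserved
motifs were found, whether the catalytic Cys2 column is conserved, and
the support values on the representative-tree bipartitions.  Copies the
motif table to results/motifs.tsv.
"""

import shutil
from pathlib import Path

import pandas as pd

from bshscan import phylo

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis" / "run"


def main() -> None:
    motifs = pd.read_csv(RUN / "motifs.tsv", sep="\t")
    sites = pd.read_csv(RUN / "active_sites.tsv", sep="\t")
    print(f"{len(motifs)} conserved motifs (>=3 columns at >=0.75):")
    print(motifs.to_string(index=False))
    print("\nActive-site audit:")
    print(sites.to_string(index=False))

    tree_path = RUN / "bsh_tree.nwk"
    if tree_path.exists():
        tree = phylo.read_newick(tree_path)
        supports = [
            node.name
            for node in tree.traverse(include_self=False)
            if not node.is_tip() and node.name
        ]
        print(f"\nRepresentative tree: {len(list(tree.tips()))} leaves, "
              f"bootstrap supports at internal nodes: {supports}")
    else:
        print("\nNo representative tree (fewer than 3 BSH clusters).")

    shutil.copy(RUN / "motifs.tsv", ROOT / "results" / "motifs.tsv")
    print(f"\nCopied motif table to {ROOT / 'results' / 'motifs.tsv'}")


if __name__ == "__main__":
    main()
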