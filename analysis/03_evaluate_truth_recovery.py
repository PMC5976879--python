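#!/usr/bin/env python
"""Score the pipeline's calls against the simulation truth table.

Joins the classification output of 02_run_discovery_pipeline.py to the
generator's truth table by genome coordinates and reports, per family,
how many planted proteins received their true label (decoys are correct
when removed).  Writes results/truth_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "analysis" / "bundle"
RUN = ROOT / "scratch" / "analysis" / "run"
EXPECTED = {"BSH": "BSH", "PVA": "PVA", "decoy": "removed"}


def main() -> None:
    truth = pd.read_csv(BUNDLE / "truth.tsv", sep="\t")
    cand = pd.read_csv(RUN / "candidates.tsv", sep="\t")
    cls = pd.read_csv(RUN / "classification.tsv", sep="\t")
    merged = cand.merge(cls, left_on="protein_id", right_on="candidate_id")
    got = {
        (r.genome_id, r.start, r.end): r.label for r in merged.itertuples()
    }
    truth["called"] = [
        got.get((r.genome_id, r.start, r.end), "removed") for r in truth.itertuples()
    ]
    truth["correct"] = [
        r.called == EXPECTED[r.family] for r in truth.itertuples()
    ]
    table = (
        truth.groupby("family")
        .agg(n=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    table["recovery_pct"] = (100 * table.n_correct / table.n).round(2)
    out = ROOT / "results" / "truth_recovery.tsv"
    table.to_csv(out, sep="\t", index=False)
    overall = 100 * truth.correct.mean()
    print(table.to_string(index=False))
    print(f"Overall truth-label recovery: {overall:.1f}% ({truth.correct.sum()}/{len(truth)})")
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
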