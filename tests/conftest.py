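"""Shared fixtures: synthetic bundles, reference profiles, pipeline runs.

Heavy objects (the 320-state profile pair with calibrations, the
double pipeline run used by the determinism checks) are session-scoped
so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from bshscan import hmmclass, simulate
from bshscan.pipeline import run_all
from bshscan.seqio import Msa, PipelineConfig, ProteinRecord


@pytest.fixture(scope="session")
def family_pair():
    """Default BSH-like / PVA-like consensus pair (divergence study design)."""
    spec_b = simulate.default_bsh_spec()
    spec_p = simulate.default_pva_spec()
    cons_b, cons_p = simulate.make_consensus_pair(spec_b, spec_p, seed=42)
    return spec_b, spec_p, cons_b, cons_p


@pytest.fixture(scope="session")
def reference_profiles(family_pair):
    """26-member BSH and 8-member PVA reference profiles with calibrations."""
    spec_b, spec_p, cons_b, cons_p = family_pair
    rng = np.random.default_rng(5)

    def refs(tag, cons, blocks, n):
        return [
            ProteinRecord(
                f"{tag}_ref_{i:02d}",
                simulate.evolve_member(cons, 0.12, blocks, int(rng.integers(2**31))),
            )
            for i in range(n)
        ]

    refs_b = refs("bsh", cons_b, spec_b.motif_blocks, 26)
    refs_p = refs("pva", cons_p, spec_p.motif_blocks, 8)
    hmm_b = hmmclass.build_profile(
        Msa(rows=tuple((r.id, r.sequence) for r in refs_b)), name="BSH"
    )
    hmm_p = hmmclass.build_profile(
        Msa(rows=tuple((r.id, r.sequence) for r in refs_p)), name="PVA"
    )
    calib_b = hmmclass.calibrate_evalues(hmm_b, n_decoys=150, seed=101)
    calib_p = hmmclass.calibrate_evalues(hmm_p, n_decoys=150, seed=102)
    return {
        "refs_bsh": refs_b,
        "refs_pva": refs_p,
        "hmm_bsh": hmm_b,
        "hmm_pva": hmm_p,
        "calib_bsh": calib_b,
        "calib_pva": calib_p,
    }


@pytest.fixture(scope="session")
def small_profile():
    """A 60-column single-family profile for fast calibration experiments."""
    rng = np.random.default_rng(9)
    consensus = simulate._random_protein(60, rng)
    rows = tuple(
        (f"r{i}", simulate.evolve_member(consensus, 0.10, (), int(rng.integers(2**31))))
        for i in range(12)
    )
    return hmmclass.build_profile(Msa(rows=rows), name="small"), consensus


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Small written survey bundle with explicit copy numbers."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = simulate.SimulationConfig(
        n_species=4,
        strains_per_species=2,
        bsh_copies=(1, 2, 0, 1),
        pva_copies=(0, 1, 1, 0),
        strain_dropout=0.0,
        seed=11,
    )
    return simulate.generate_dataset(cfg, out_dir=out), out


@pytest.fixture(scope="session")
def double_run(bundle, tmp_path_factory):
    """The full pipeline run twice on the same bundle/config."""
    _, bundle_dir = bundle
    cfg = PipelineConfig(rng_seed=11, bootstrap_reps=10)
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    m1 = run_all(cfg, bundle_dir, out1)
    m2 = run_all(cfg, bundle_dir, out2)
    return m1, m2, out1, out2
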