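"""Shared fixtures: full simulate -> close pipeline runs reused across tests.

Both runs use the reference study conditions (2 Mb genome, ten gaps per
nominal size class, mean read length 6528 bp): one with error-free reads at
5x depth, one with 3%/1%/1% sub/ins/del errors at 8x depth.
"""

from __future__ import annotations

import edlib
import pytest

from spanfill import (
    close_all_gaps,
    find_gaps,
    gather_evidence,
    patch_assembly,
    read_alignments,
    read_fasta,
)
from spanfill.simulate import SimConfig, make_fixture


def run_pipeline(cfg: SimConfig, out_dir) -> dict:
    """Simulate a fixture and close its gaps; return all intermediates."""
    paths = make_fixture(cfg, out_dir)
    truth = read_fasta(paths["truth.fa"])
    gapped = read_fasta(paths["gapped.fa"])
    gaps = [g for sc in gapped for g in find_gaps(sc)]
    alns = read_alignments(paths["reads.sam"])
    evidence = gather_evidence(alns, gaps)
    actions = close_all_gaps(gapped, evidence, gaps)
    patched, report = patch_assembly(gapped, actions)
    return {
        "cfg": cfg,
        "paths": paths,
        "truth": truth,
        "gapped": gapped,
        "gaps": gaps,
        "alignments": alns,
        "evidence": evidence,
        "actions": actions,
        "patched": patched,
        "report": report,
    }


def closed_region_identities(run: dict) -> list[float]:
    """Identity of each closed replacement vs the truth genome interval."""
    truth_seq = {sc.id: sc.seq for sc in run["truth"]}
    out = []
    for act in run["actions"]:
        if act.status != "closed":
            continue
        want = truth_seq[act.scaffold_id][act.replace_start : act.replace_end]
        d = edlib.align(act.replacement_seq, want)["editDistance"]
        out.append(1.0 - d / max(len(want), len(act.replacement_seq)))
    return out


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory) -> dict:
    cfg = SimConfig(seed=42)  # defaults: 2 Mb, 60 gaps, depth 5, no errors
    return run_pipeline(cfg, tmp_path_factory.mktemp("clean_fixture"))


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> dict:
    cfg = SimConfig(seed=42, depth=8.0, err_sub=0.03, err_ins=0.01, err_del=0.01)
    return run_pipeline(cfg, tmp_path_factory.mktemp("noisy_fixture"))
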