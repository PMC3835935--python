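"""Shared simulated fixtures: a small two-species world with truth labels."""

import pytest

from xenosplit import (
    SimulationConfig,
    emit_alignments,
    generate_reference_set,
    simulate_reads,
)


@pytest.fixture(scope="session")
def mixed_world(tmp_path_factory):
    """A 90/10 human/mouse xenograft-like sample with dual-genome SAMs."""
    cfg = SimulationConfig(
        n_genes=30,
        gene_length_range=(400, 1200),
        divergence=0.12,
        error_rate=0.01,
        species_mix=(0.9, 0.1),
        paired=True,
        seed=42,
    )
    refs = generate_reference_set(cfg)
    reads = simulate_reads(refs, cfg, 4000)
    d = tmp_path_factory.mktemp("mixed_world")
    paths = refs.write(d)
    sam_h, sam_m = d / "human.sam", d / "mouse.sam"
    emit_alignments(reads, refs, sam_h, sam_m)
    return {
        "config": cfg,
        "refs": refs,
        "reads": reads,
        "dir": d,
        "paths": paths,
        "sam_human": sam_h,
        "sam_mouse": sam_m,
    }
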