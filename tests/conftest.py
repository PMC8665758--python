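from __future__ import annotations

import pytest

from splicechain.index import IndexConfig, build_index, read_annotation, read_transcripts
from splicechain.pipeline import Aligner
from splicechain.simulate import SimConfig, generate_genome_and_annotation, generate_reads


def build_sim_index(sim, tmp_path_factory, name="idx"):
    d = tmp_path_factory.mktemp(name)
    gtf = d / "a.gtf"
    gtf.write_text(sim.gtf_text)
    return build_index(
        sim.genome,
        read_annotation(gtf),
        IndexConfig(),
        read_transcripts(gtf),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Five-gene, error-free simulation used across modules."""
    cfg = SimConfig(
        seed=11,
        n_genes=5,
        genome_length=40_000,
        reads_per_transcript=2,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
    )
    sim = generate_genome_and_annotation(cfg)
    generate_reads(sim)
    return sim


@pytest.fixture(scope="session")
def small_index(small_sim, tmp_path_factory):
    return build_sim_index(small_sim, tmp_path_factory, "small_idx")


@pytest.fixture(scope="session")
def small_aligner(small_index):
    return Aligner(small_index)
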