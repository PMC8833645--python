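import pathlib

import pytest

from tdscan import (
    AlignmentStore,
    RunConfig,
    SimGeneSpec,
    SimTDSpec,
    call_td_regions,
    make_genome_and_annotation,
    pten_like_gene_spec,
    simulate_sample,
)


@pytest.fixture(scope="session")
def pten_genome():
    """Simulated genome with the PTEN-like 9-exon gene (session-cached)."""
    return make_genome_and_annotation([pten_like_gene_spec()], seed=101)


@pytest.fixture(scope="session")
def three_exon_genome():
    """A small plus-strand gene with exons of 100, 101 and 99 bp."""
    spec = SimGeneSpec(
        name="TRI", strand="+", exon_lengths=(100, 101, 99),
        intron_lengths=(400, 350), offset=300, chrom="chrT",
    )
    return make_genome_and_annotation([spec], seed=202)


@pytest.fixture
def run_detection(tmp_path):
    """Simulate a sample from TD specs and run the full detection pipeline."""

    def _run(genome, td_specs, sample_id="t", config=None):
        sam, _ = simulate_sample(genome, td_specs, sample_id=sample_id)
        path = tmp_path / f"{sample_id}.sam"
        path.write_text(sam)
        store = AlignmentStore.from_path(path)
        return call_td_regions(
            sample_id, store, genome.genes, genome.reference, config or RunConfig()
        )

    return _run


@pytest.fixture
def write_sam(tmp_path):
    def _write(text: str, name: str = "sample.sam") -> pathlib.Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def td_spec(first=3, last=5, outside=0, inside=0, background=0, **kw):
    return SimTDSpec(
        gene="PTENL", first_exon=first, last_exon=last,
        n_junction_pairs_outside=outside, n_junction_pairs_inside=inside,
        n_background_pairs=background, **kw,
    )
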