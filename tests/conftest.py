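"""Shared fixtures: simulated datasets built once per session."""

import pytest

from ribostamp.alignment_io import (
    ReadFilterConfig,
    load_snp_mask,
    load_transcript_models,
    load_whitelist,
)
from ribostamp.edit_caller import GeneIndex, SiteFilterConfig
from ribostamp.simulate import AlignmentSimSpec, simulate_alignments


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Short-read alignment simulation with planted edits, SNPs and decoys."""
    out = tmp_path_factory.mktemp("sim_short")
    return simulate_alignments(AlignmentSimSpec(seed=1), out)


@pytest.fixture(scope="session")
def sim_long_bundle(tmp_path_factory):
    """Long-read (isoform-tagged, full-transcript) simulation."""
    out = tmp_path_factory.mktemp("sim_long")
    spec = AlignmentSimSpec(seed=3, long_read=True, n_cells=20, n_genes=4)
    return simulate_alignments(spec, out)


@pytest.fixture(scope="session")
def read_config(sim_bundle):
    return ReadFilterConfig(barcode_whitelist=load_whitelist(sim_bundle.whitelist))


@pytest.fixture(scope="session")
def site_config(sim_bundle):
    return SiteFilterConfig(
        snp_mask=frozenset(load_snp_mask(sim_bundle.vcf)),
        require_sense_strand=True,
    )


@pytest.fixture(scope="session")
def gene_index(sim_bundle):
    return GeneIndex(load_transcript_models(sim_bundle.gtf))
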