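import pytest

from varcohort.gene_model import TranscriptModel
from varcohort.report import RunConfig, run_pipeline
from varcohort.synthetic_data import gen_transcript, write_fixtures

SEED = 11  # fixed session seed; every planted quantity is exact by construction


@pytest.fixture(scope="session")
def toy_model():
    """Three exons, 21 bp CDS (ATG AAA CCC GGG TTT ACG TAA) on a tiny axis."""
    return TranscriptModel(
        gene_symbol="TOY",
        exons=((101, 109), (201, 206), (301, 306)),
        coding_sequence="ATGAAACCCGGGTTTACGTAA",
    )


@pytest.fixture(scope="session")
def big_model():
    """Default synthetic transcript: 27 exons, 1480 codons, 4443 bp CDS."""
    return gen_transcript(SEED)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Full default fixture set (transcript, cohort, snapshots, evidence, truth)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(outdir, seed=SEED)


@pytest.fixture(scope="session")
def pipeline_report(fixture_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = RunConfig.from_json(fixture_paths["config_json"], outdir=outdir)
    return run_pipeline(config)
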