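import pytest

from secirc.pipeline import RunConfig, run_pipeline
from secirc.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic study: 500 typical peaks, 25 planted SE
    clusters (signal multiplier 20), 200 circRNAs, noiseless RPM, seed 42."""
    out = tmp_path_factory.mktemp("synth_default")
    config = SynthConfig()
    paths, ledger = generate_dataset(config, out)
    return config, paths, ledger


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    """One full pipeline run over the default synthetic dataset."""
    _, paths, ledger = default_dataset
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = RunConfig(
        peaks=str(paths["peaks"]),
        circs=str(paths["circs"]),
        expression=str(paths["expression"]),
        orthologs=str(paths["orthologs"]),
        circ_fasta=str(paths["circ_fasta"]),
        mirna_fasta=str(paths["mirna_fasta"]),
        out_dir=str(out),
    )
    report = run_pipeline(cfg)
    return cfg, report, ledger
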