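import pandas as pd
import pytest
from hypothesis import settings

from crpkm import pipeline, synthetic
from crpkm.synthetic import GeneratorParams

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    """The default-size generator run: 5,000 genes, default noise, seed 1."""
    return synthetic.generate_dataset(GeneratorParams(n_genes=5000, seed=1))


@pytest.fixture(scope="session")
def default_report(default_dataset) -> pipeline.RunReport:
    return pipeline.run_on_dataset(default_dataset)


@pytest.fixture(scope="session")
def default_master(default_dataset, default_report) -> pd.DataFrame:
    """Pipeline calls joined with generator truth on gene_id."""
    return default_report.master.merge(
        default_dataset.truth.table, on="gene_id", suffixes=("", "_true")
    )


@pytest.fixture(scope="session")
def zero_noise_run():
    """Noise-free fixture and its pipeline report (deterministic limit)."""
    ds = synthetic.generate_dataset(GeneratorParams(n_genes=600, seed=5, noise_scale=0.0))
    return ds, pipeline.run_on_dataset(ds)


@pytest.fixture()
def tiny_params() -> GeneratorParams:
    """Scaled-down generator (small genome and depths) for I/O round trips."""
    return GeneratorParams(
        n_genes=200,
        seed=7,
        genome_bp=20_000_000,
        chip_depth_pro=20_000,
        gro_depth=200_000,
    )
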