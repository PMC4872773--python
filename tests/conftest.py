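import pytest

from lncbreadth.pipeline import PipelineConfig, run
from lncbreadth.synthetic import GeneratorConfig, generate, worked_micro_example


@pytest.fixture(scope="session")
def micro():
    return worked_micro_example()


@pytest.fixture(scope="session")
def small_config():
    # scaled-down generator: same planted structure, fast to build and analyze
    return GeneratorConfig(
        seed=7,
        n_tissues=8,
        n_lnc=200,
        n_pc=120,
        n_ue_lnc=30,
        n_ts_lnc=40,
        n_background=1000,
        genes_per_chrom=100,
        n_redundant_duplicates=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle_small")
    return generate(small_config, out)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The generator's default conditions (seed 42, 2,000 lncRNAs)."""
    out = tmp_path_factory.mktemp("bundle_default")
    return generate(GeneratorConfig(seed=42), out)


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("run_default")
    manifest = run(PipelineConfig(bundle_dir=str(default_bundle), out_dir=str(out), seed=0))
    return out, manifest
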