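import pytest

from tfcensus import synthetic as syn
from tfcensus.io_model import DomainHit, FamilyCatalog


def make_hit(
    protein_id="P1",
    model_id="SF0001",
    start=1,
    end=100,
    e_value=1e-20,
    genome_id="G1",
    family_id=None,
    family_e_value=None,
    coverage=None,
    **kwargs,
):
    return DomainHit(
        genome_id=genome_id,
        protein_id=protein_id,
        model_id=model_id,
        start=start,
        end=end,
        e_value=e_value,
        family_id=family_id,
        family_e_value=family_e_value,
        coverage=coverage,
        **kwargs,
    )


@pytest.fixture
def catalog3():
    return FamilyCatalog(
        {
            "LysR": {"DBD_LysR"},
            "TetR/AcrR": {"DBD_TetR_AcrR"},
            "AraC/XylS": {"DBD_AraC_XylS"},
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic genomes with the 19 canonical families."""
    cfg = syn.SyntheticConfig(
        n_genomes=12, seed=42, families=syn.default_families()
    )
    return syn.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    syn.write_dataset(small_dataset, outdir)
    return outdir
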