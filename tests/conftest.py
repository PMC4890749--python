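import pytest

from hdx_allomap.fixture import make_hsp90_fixture
from hdx_allomap.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def hsp90():
    return make_hsp90_fixture()


@pytest.fixture(scope="session")
def hsp90_dir(hsp90, tmp_path_factory):
    out = tmp_path_factory.mktemp("hsp90")
    hsp90.write(out)
    return out


@pytest.fixture(scope="session")
def hsp90_pipeline(hsp90, hsp90_dir, tmp_path_factory):
    """Full pipeline run over the Hsp90 fixture (apo vs all four ligands)."""
    out = tmp_path_factory.mktemp("pipeline_out")
    config = RunConfig(
        apo_path=str(hsp90_dir / "hsp90_apo.csv"),
        ligand_paths={name: str(hsp90_dir / f"hsp90_{name}.csv")
                      for name in hsp90.bound},
        structure_path=str(hsp90_dir / "hsp90_synthetic.pdb"),
        ligand_selector=hsp90.ligand_selector,
        out_dir=str(out),
    )
    return run_pipeline(config)
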