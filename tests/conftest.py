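import pytest

from intronevo.synthetic_data import eight_species_tree, generate_fixture_suite
from intronevo.trees import SpeciesTree


@pytest.fixture
def quartet_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A:1,B:1)AB:1,(C:1,D:1)CD:1)R;")


@pytest.fixture
def triplet_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A:1,B:1)AB:1,C:1)R;")


@pytest.fixture
def eight_sp_tree() -> SpeciesTree:
    return eight_species_tree()


@pytest.fixture(scope="session")
def panel_study(tmp_path_factory):
    """The 6 constructed edge-case families on a 4-tip tree, on disk."""
    outdir = tmp_path_factory.mktemp("panel")
    manifest = generate_fixture_suite("panel", outdir, seed=11)
    return manifest


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """Three simulated families on the 8-tip tree, on disk."""
    outdir = tmp_path_factory.mktemp("demo8")
    manifest = generate_fixture_suite("eight-species", outdir, seed=7)
    return manifest
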