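import pathlib

import pytest

from phylogeodiv.io import parse_newick
from phylogeodiv.simulate import ScenarioConfig, generate_dataset


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def asym3():
    return parse_newick("((A:1,B:2):1,C:3);")


@pytest.fixture(scope="session")
def small_expansion(tmp_path_factory) -> dict:
    """A small expansion-scenario dataset, generated once per session."""
    from phylogeodiv import io

    cfg = ScenarioConfig(
        n_haplotypes=32, seq_length=377, n_sites=6,
        latitudes=[30, 36, 42, 48, 54, 60], strains_per_site=20,
        founder_fraction=0.4, seed=11)
    outdir = tmp_path_factory.mktemp("expansion")
    paths = generate_dataset(cfg, outdir)
    return {
        "config": cfg,
        "paths": paths,
        "dir": pathlib.Path(outdir),
        "alignment": io.read_fasta(paths["alignment"]),
        "tree": io.read_newick(paths["tree"]),
        "sites": io.read_site_table(paths["sites"]),
        "strains": io.read_strain_map(paths["strains"]),
        "community": io.read_community(paths["community"]),
    }
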