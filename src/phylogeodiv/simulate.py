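"""Synthetic haplotype datasets with known ground truth.

The generator emulates the data model of a continental strain-survey:
a rooted ultrametric genealogy over haplotypes (Yule process), equal-length
aligned sequences evolved along it (Jukes-Cantor), and a set of latitude-
ordered sites populated with strains under one of three occupancy scenarios:

``panmixia``
    every site draws strains from the full haplotype pool — the null world
    in which no geographic or phylogenetic structure exists;
``expansion``
    a founder-style range expansion: the lowest-latitude site draws from the
    full pool, and each higher-latitude site draws from a phylogenetically
    coherent founder subset of the next site below it, recursively.  This
    produces the qualitative signatures of post-glacial colonization —
    phylogenetic diversity falling with latitude, phylogenetic clustering at
    high-latitude sites, higher mean root distance, distance decay of
    community similarity, and identical haplotypes shared between distant
    sites;
``clustered``
    each site draws from the tips of one randomly chosen subtree —
    phylogenetic clustering without any latitudinal ordering.

Every output is a pure function of the :class:`ScenarioConfig`, so a config
plus its seed is a complete description of a dataset.
"""

from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import discrete as _discrete
from dendropy.simulate import treesim

from . import io as _io
from ._tree import patristic_matrix, tip_labels

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "evolve_sequences",
    "assign_sites",
    "generate_dataset",
]


def _default_latitudes() -> list[float]:
    return [round(x, 2) for x in np.linspace(28.0, 64.0, 12)]


@dataclasses.dataclass
class ScenarioConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the shape of a 12-site continental survey with 77
    strains characterized per site over ~200 haplotypes of a 377 bp
    protein-coding marker.  ``substitution_rate`` scales the ultrametric
    Yule branch lengths (time units) into expected substitutions per site;
    the default keeps typical pairwise divergence within a few percent, so
    that a 0.01 patristic OTU threshold yields a non-trivial clustering and
    some tips collapse to identical sequences.
    """

    n_haplotypes: int = 208
    seq_length: int = 377
    birth_rate: float = 1.0
    substitution_rate: float = 0.008
    n_sites: int = 12
    latitudes: list[float] = dataclasses.field(default_factory=_default_latitudes)
    longitude: float = -95.0
    scenario: str = "expansion"
    founder_fraction: float = 0.8
    strains_per_site: int = 77
    glaciation_cutoff_latitude: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in {"panmixia", "expansion", "clustered"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.founder_fraction <= 1.0:
            raise ValueError("founder_fraction must be in (0, 1]")
        if min(self.n_haplotypes, self.n_sites, self.strains_per_site,
               self.seq_length) < 1:
            raise ValueError("all counts must be positive")
        if len(self.latitudes) != self.n_sites:
            raise ValueError(
                f"{len(self.latitudes)} latitudes given for "
                f"{self.n_sites} sites")

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int = 0) -> dendropy.Tree:
    """Simulate a rooted ultrametric Yule (pure-birth) tree.

    Branch lengths are in time units; tips are relabelled ``h001 ...``
    in a deterministic order, so identical seeds give identical Newick
    strings.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_tips, rng=random.Random(seed))
    width = max(3, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"h{i:0{width}d}"
    return tree


def evolve_sequences(tree: dendropy.Tree, seq_length: int = 377,
                     substitution_rate: float = 0.008,
                     seed: int = 0) -> dict[str, str]:
    """Evolve one aligned sequence per tip under Jukes-Cantor.

    ``substitution_rate`` converts the tree's branch lengths into expected
    substitutions per site.  Near-zero branches can and do yield identical
    sequences at different tips — the haplotype-deduplication step depends
    on this.
    """
    if substitution_rate < 0:
        raise ValueError("substitution_rate must be non-negative")
    scaled = tree.clone(depth=1)
    for node in scaled.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= substitution_rate
    chars = _discrete.simulate_discrete_chars(
        seq_length, scaled, _discrete.Jc69(), rng=random.Random(seed))
    out = {taxon.label: str(seq).upper() for taxon, seq in chars.items()}
    return {lab: out[lab] for lab in sorted(out)}


def _founder_pool(parent_pool: list[str], size: int, dist: pd.DataFrame,
                  rng: np.random.Generator) -> list[str]:
    """A phylogenetically coherent founder subset of a parent pool.

    A colonization event carries a lineage, not a random sample: a seed
    haplotype is drawn uniformly and the founder pool is the ``size``
    haplotypes of the parent pool patristically closest to it (ties broken
    by label).  With ``size == len(parent_pool)`` this is the parent pool
    itself.
    """
    seed_hap = parent_pool[rng.integers(len(parent_pool))]
    order = sorted(parent_pool,
                   key=lambda h: (dist.at[seed_hap, h], h))
    return sorted(order[:size])


def assign_sites(tree: dendropy.Tree, config: ScenarioConfig,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Populate sites with strains under the configured scenario.

    Returns ``(strain_map, community, site_table)``.  Sites are ordered by
    ascending latitude; ``time_rank`` 1 is the lowest-latitude site (longest
    time available for colonization) and the ``glaciated`` flag is set above
    the cutoff latitude.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tips = sorted(tip_labels(tree))
    order = np.argsort(config.latitudes, kind="stable")
    site_ids = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    lat_sorted = [config.latitudes[i] for i in order]

    pools: dict[str, list[str]] = {}
    if config.scenario == "panmixia":
        for sid in site_ids:
            pools[sid] = tips
    elif config.scenario == "expansion":
        dist = patristic_matrix(tree)
        pools[site_ids[0]] = tips
        for prev, sid in zip(site_ids, site_ids[1:]):
            parent = pools[prev]
            size = int(np.ceil(config.founder_fraction * len(parent)))
            if size < 1:
                raise ValueError(f"founder subset for site {sid} is empty")
            size = max(2, min(size, len(parent)))
            pools[sid] = _founder_pool(parent, size, dist, rng)
    else:  # clustered
        clades = []
        for node in tree.preorder_internal_node_iter():
            clade = sorted(leaf.taxon.label
                           for leaf in node.leaf_iter())
            if 2 <= len(clade) < len(tips):
                clades.append(clade)
        for sid in site_ids:
            pools[sid] = clades[rng.integers(len(clades))]

    records = []
    counts = pd.DataFrame(0, index=site_ids, columns=tips, dtype=int)
    counts.index.name = "site_id"
    for sid in site_ids:
        pool = pools[sid]
        draws = rng.integers(len(pool), size=config.strains_per_site)
        for k, d in enumerate(draws, start=1):
            hap = pool[d]
            records.append((f"{sid}_{k:03d}", sid, hap))
            counts.at[sid, hap] += 1
    strain_map = pd.DataFrame(records, columns=_io.STRAIN_COLUMNS)
    counts = counts.loc[:, counts.sum(axis=0) > 0]

    env = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    site_table = pd.DataFrame({
        "site_id": site_ids,
        "latitude": lat_sorted,
        "longitude": [config.longitude] * config.n_sites,
        "pH": np.round(env.normal(6.0, 0.5, config.n_sites), 2),
        "som": np.round(env.normal(5.0, 1.0, config.n_sites), 2),
        "temp": np.round(env.normal(10.0, 5.0, config.n_sites), 2),
        "ppt": np.round(env.normal(800.0, 150.0, config.n_sites), 1),
        "glaciated": [lat > config.glaciation_cutoff_latitude
                      for lat in lat_sorted],
        "time_rank": np.arange(1, config.n_sites + 1),
    }).set_index("site_id")
    assign_sites.last_pools = pools  # inspectable ground truth
    return strain_map, counts, site_table


def generate_dataset(config: ScenarioConfig, outdir) -> dict[str, Path]:
    """Write a complete cross-consistent dataset plus its ground truth.

    Files: ``haplotypes.fasta`` (one aligned sequence per tree tip),
    ``tree.nwk``, ``sites.tsv``, ``strains.tsv``, ``community.tsv`` and
    ``truth.json`` recording the scenario, seed and per-site founder pools.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_haplotypes, config.birth_rate,
                         seed=_subseed(config.seed, 0))
    alignment = evolve_sequences(tree, config.seq_length,
                                 config.substitution_rate,
                                 seed=_subseed(config.seed, 1))
    strain_map, community, site_table = assign_sites(tree, config)
    pools = assign_sites.last_pools
    # the emitted gene tree carries branch lengths in expected
    # substitutions/site, the scale on which patristic OTU thresholds and
    # phylodiversity are defined
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= config.substitution_rate

    paths = {
        "alignment": outdir / "haplotypes.fasta",
        "tree": outdir / "tree.nwk",
        "sites": outdir / "sites.tsv",
        "strains": outdir / "strains.tsv",
        "community": outdir / "community.tsv",
        "truth": outdir / "truth.json",
    }
    _io.write_fasta(alignment, paths["alignment"])
    _io.write_newick(tree, paths["tree"])
    _io.write_site_table(site_table, paths["sites"])
    _io.write_strain_map(strain_map, paths["strains"])
    _io.write_community(community, paths["community"])
    truth = {
        "config": config.to_dict(),
        "scenario": config.scenario,
        "seed": config.seed,
        "founder_pools": {sid: pool for sid, pool in pools.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    _io.validate_dataset(alignment, site_table, strain_map)
    return paths


def _subseed(seed: int, stream: int) -> int:
    """A reproducible derived seed, kept within 31 bits."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2 ** 31))
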