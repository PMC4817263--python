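"""End-to-end orchestration: one config in, every table-shaped output out.

A run consumes either a directory of input files (alignment, tree, site
table, strain map) or a synthetic :class:`~phylogeodiv.simulate.ScenarioConfig`,
and emits the full battery of analysis products: the OTU assignment,
per-site alpha diversity, beta-diversity and geographic/environmental
distance matrices, Mantel and PERMANOVA results, the site-statistics
correlation matrix, the glaciation-partitioned OTU-sharing network,
statistical-parsimony haplotype networks with nested-clade statistics and
inferences, a rarefaction table, and a manifest recording the exact config,
seeds and a config hash.  Everything is a pure function of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__, alpha, beta, haplonet, io, otu, sharing
from .simulate import ScenarioConfig, generate_dataset

log = logging.getLogger("phylogeodiv")

__all__ = ["RunConfig", "run_all", "with_and_without"]

ENV_VARIABLES = ["pH", "som", "temp", "ppt"]


@dataclasses.dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    # either a synthetic scenario ...
    scenario: ScenarioConfig | None = None
    # ... or explicit input paths
    alignment: str | None = None
    tree: str | None = None
    sites: str | None = None
    strains: str | None = None

    otu_threshold: float = 0.01
    otu_method: str = "node_depth"
    n_perm_alpha: int = 999
    n_perm_mantel: int = 1000
    n_perm_adonis: int = 999
    n_perm_nca: int = 1000
    confidence: float = 0.95
    seed: int = 0
    exclude_sites: list[str] = dataclasses.field(default_factory=list)
    focal_site: str | None = None
    min_network_size: int = 3

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if isinstance(data.get("scenario"), dict):
            data["scenario"] = ScenarioConfig.from_dict(data["scenario"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(config: RunConfig, outdir: Path):
    if config.scenario is not None:
        paths = generate_dataset(config.scenario, outdir / "synthetic")
        log.info("stage=simulate wrote %d files", len(paths))
    else:
        for field in ("alignment", "tree", "sites", "strains"):
            value = getattr(config, field)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(
                    f"input {field!r} missing or not found: {value}")
        paths = {k: Path(getattr(config, k))
                 for k in ("alignment", "tree", "sites", "strains")}
    alignment = io.read_fasta(paths["alignment"])
    tree = io.read_newick(paths["tree"])
    sites = io.read_site_table(paths["sites"])
    strains = io.read_strain_map(paths["strains"])
    io.validate_dataset(alignment, sites, strains)
    return alignment, tree, sites, strains


def _apply_exclusion(sites: pd.DataFrame, strains: pd.DataFrame,
                     exclude: list[str]):
    if not exclude:
        return sites, strains
    unknown = [s for s in exclude if s not in sites.index]
    if unknown:
        warnings.warn(f"exclusion set contains unsampled site(s) {unknown}",
                      stacklevel=2)
    keep = [s for s in sites.index if s not in set(exclude)]
    if len(keep) < 4:
        raise ValueError("exclusion leaves fewer than 4 sites")
    return (sites.loc[keep],
            strains[strains["site_id"].isin(keep)].reset_index(drop=True))


def run_all(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignment, tree, sites, strains = _load_inputs(config, outdir)
    sites, strains = _apply_exclusion(sites, strains, config.exclude_sites)
    log.info("stage=load sites=%d strains=%d haplotypes=%d",
             len(sites), len(strains), len(alignment))

    # --- OTUs and communities -------------------------------------------
    assignment = otu.cluster_otus(tree, config.otu_threshold,
                                  config.otu_method)
    assignment.as_series().to_csv(outdir / "otu_table.tsv", sep="\t")
    hap_to_otu = assignment.mapping
    dedup_map, dedup_table = otu.dedup_haplotypes(alignment)

    community_w = otu.build_community(strains, taxon_of=hap_to_otu)
    # unweighted view: one sequence per unique haplotype per OTU per site
    uniq = strains.copy()
    uniq["haplotype_id"] = uniq["haplotype_id"].map(dedup_map)
    uniq = uniq.drop_duplicates(["site_id", "haplotype_id"])
    community_u = otu.build_community(uniq, taxon_of=hap_to_otu)
    community_u = community_u.reindex(index=community_w.index,
                                      columns=community_w.columns,
                                      fill_value=0)
    io.write_community(community_w, outdir / "community_weighted.tsv")
    io.write_community(community_u, outdir / "community_unweighted.tsv")
    log.info("stage=otu n_otus=%d", assignment.n_otus)

    # --- alpha diversity -------------------------------------------------
    rep_of_otu = assignment.representatives()
    rep_tip = {hap: rep_of_otu[o] for hap, o in hap_to_otu.items()}
    community_alpha = otu.build_community(strains, taxon_of=rep_tip)
    diversity = alpha.site_diversity(tree, community_alpha,
                                     n_perm=config.n_perm_alpha,
                                     seed=config.seed)
    diversity = diversity.join(sites)
    diversity.to_csv(outdir / "site_diversity.tsv", sep="\t")
    log.info("stage=alpha sites_scored=%d", diversity["nri"].notna().sum())

    # --- distances and decay tests --------------------------------------
    geo = beta.haversine_matrix(sites)
    env = beta.env_distance(sites, ENV_VARIABLES)
    matrices = {
        "unifrac_weighted": beta.unifrac(tree, community_alpha,
                                         "abundance_weighted"),
        "unifrac_unweighted": beta.unifrac(tree, community_alpha,
                                           "unweighted"),
        "braycurtis_weighted": beta.bray_curtis(community_w, "weighted"),
        "braycurtis_unweighted": beta.bray_curtis(community_u, "unweighted"),
    }
    for name, mat in {**matrices, "geographic": geo,
                      "environmental": env}.items():
        mat.to_csv(outdir / f"dist_{name}.tsv", sep="\t")

    tests = []
    for name, mat in matrices.items():
        res = beta.mantel(mat, geo, n_perm=config.n_perm_mantel,
                          seed=config.seed)
        tests.append({"analysis": f"mantel_{name}_vs_geographic",
                      **res.to_dict()})
        res = beta.mantel(mat, env, n_perm=config.n_perm_mantel,
                          seed=config.seed + 1)
        tests.append({"analysis": f"mantel_{name}_vs_environmental",
                      **res.to_dict()})
        for var in ["latitude"] + ENV_VARIABLES:
            res = beta.permanova(mat, sites[var],
                                 n_perm=config.n_perm_adonis,
                                 seed=config.seed)
            tests.append({"analysis": f"adonis_{name}_by_{var}",
                          **res.to_dict()})
    (outdir / "decay_tests.json").write_text(
        json.dumps(tests, indent=2, default=float))
    log.info("stage=beta tests=%d", len(tests))

    # --- correlation matrix ----------------------------------------------
    stats_table = diversity[["pd", "nri", "mrd", "latitude", "longitude",
                             "temp", "som", "ppt", "pH"]]
    corr = beta.correlation_table(stats_table)
    corr["r"].to_csv(outdir / "correlation_r.tsv", sep="\t")
    corr["p"].to_csv(outdir / "correlation_p.tsv", sep="\t")
    corr["stars"].to_csv(outdir / "correlation_stars.tsv", sep="\t")

    # --- sharing network --------------------------------------------------
    share_graph = sharing.build_bipartite(community_w, sites["glaciated"])
    classes = sharing.classify_otus(share_graph)
    summary = sharing.sharing_summary(share_graph,
                                      focal_site=config.focal_site)
    io.export_graphml(share_graph, outdir / "sharing_network.graphml")
    classes.to_csv(outdir / "otu_classes.tsv", sep="\t")
    (outdir / "sharing_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    log.info("stage=sharing otus_retained=%d", len(classes))

    # --- haplotype networks and NCA --------------------------------------
    nca_out = _run_nca(config, alignment, strains, sites, dedup_map,
                       dedup_table, outdir)
    log.info("stage=nca networks=%d", nca_out["n_networks"])

    # --- rarefaction ------------------------------------------------------
    strain_otus = strains["haplotype_id"].map(hap_to_otu)
    counts = strain_otus.value_counts().values
    depths = np.unique(np.linspace(
        1, counts.sum(), min(20, counts.sum())).astype(int))
    rare = otu.rarefaction_curve(counts, depths, n_reps=50,
                                 seed=config.seed)
    rare.to_csv(outdir / "rarefaction_otu.tsv", sep="\t", index=False)
    coverage = {
        "goods_coverage_haplotypes": otu.goods_coverage(
            strains["haplotype_id"].map(dedup_map).value_counts().values),
        "goods_coverage_otus": otu.goods_coverage(counts),
    }
    (outdir / "coverage.json").write_text(json.dumps(coverage, indent=2))

    # --- manifest ---------------------------------------------------------
    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_sites": len(sites),
        "n_strains": len(strains),
        "n_haplotypes_unique": len(dedup_table),
        "n_otus": assignment.n_otus,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _run_nca(config: RunConfig, alignment, strains, sites, dedup_map,
             dedup_table, outdir: Path) -> dict:
    """Build per-component haplotype networks and run nested clade analysis."""
    strain_unique = strains.copy()
    strain_unique["haplotype_id"] = strain_unique["haplotype_id"].map(
        dedup_map)
    counts = strain_unique["haplotype_id"].value_counts().to_dict()
    observed = {rep: dedup_table.at[rep, "sequence"]
                for rep in dedup_table.index if rep in counts}
    limit = haplonet.parsimony_limit(
        len(next(iter(alignment.values()))), config.confidence)
    network = haplonet.build_network(observed, counts, limit=limit)
    coords = strain_unique.merge(
        sites[["latitude", "longitude"]], left_on="site_id",
        right_index=True)[["haplotype_id", "latitude", "longitude"]]
    annotated = haplonet.annotate_network(network, strain_unique, sites)
    io.export_graphml(annotated, outdir / "haplotype_network.graphml")

    components = sorted(nx.connected_components(network),
                        key=lambda c: (-len(c), sorted(c)[0]))
    all_tables = []
    all_contrasts = []
    inferences = []
    n_networks = 0
    largest_strains = 0
    for comp in components:
        observed_in = [n for n in comp
                       if network.nodes[n]["kind"] == "observed"]
        strains_in = int(sum(counts.get(n, 0) for n in observed_in))
        largest_strains = max(largest_strains, strains_in)
        if len(observed_in) < config.min_network_size:
            continue
        sub = haplonet.resolve_loops(network.subgraph(comp).copy())
        design = haplonet.nest_clades(sub)
        comp_coords = coords[coords["haplotype_id"].isin(observed_in)]
        result = haplonet.nca_permutation(
            design, comp_coords, n_perm=config.n_perm_nca,
            seed=config.seed)
        result["network"] = sorted(observed_in)[0]
        contrasts = result.attrs["interior_tip_contrasts"].copy()
        contrasts["network"] = sorted(observed_in)[0]
        all_contrasts.append(contrasts)
        flat = result.copy()
        flat.attrs = {}
        all_tables.append(flat)
        for parent in sorted(set(result["parent"])):
            nested = result[result["parent"] == parent]
            if len(nested) < 2:
                continue
            label = haplonet.interpret(result, parent)
            inferences.append({
                "network": sorted(observed_in)[0],
                "nesting_clade": parent or "<network>",
                "n_strains": int(nested["n_strains"].sum()),
                "inference": label,
            })
        n_networks += 1
    if all_tables:
        pd.concat(all_tables, ignore_index=True).to_csv(
            outdir / "nca_table.tsv", sep="\t", index=False)
        pd.concat(all_contrasts, ignore_index=True).to_csv(
            outdir / "nca_interior_tip.tsv", sep="\t", index=False)
    (outdir / "nca_inferences.json").write_text(
        json.dumps(inferences, indent=2))
    summary = {"n_networks": n_networks,
               "largest_network_strains": largest_strains,
               "parsimony_limit": limit}
    (outdir / "nca_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def with_and_without(config: RunConfig, exclusion: list[str],
                     outdir) -> pd.DataFrame:
    """Run the pipeline with and without an exclusion set, side by side.

    Returns the decay-test table with paired p-values and a flag for every
    conclusion (at α = 0.05) that changes when the sites are excluded.
    """
    outdir = Path(outdir)
    base = run_all(config, outdir / "all_sites")
    reduced_cfg = dataclasses.replace(
        config, exclude_sites=sorted(set(config.exclude_sites) | set(exclusion)))
    reduced = run_all(reduced_cfg, outdir / "excluded")
    with_tests = json.loads((base / "decay_tests.json").read_text())
    without_tests = json.loads((reduced / "decay_tests.json").read_text())
    rows = []
    by_name = {t["analysis"]: t for t in without_tests}
    for t in with_tests:
        other = by_name.get(t["analysis"])
        if other is None:
            continue
        changed = (t["p_value"] <= 0.05) != (other["p_value"] <= 0.05)
        rows.append({
            "analysis": t["analysis"],
            "r_squared_all": t["r_squared"],
            "p_all": t["p_value"],
            "r_squared_excluded": other["r_squared"],
            "p_excluded": other["p_value"],
            "conclusion_changed": changed,
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "with_and_without.tsv", sep="\t", index=False)
    return table
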