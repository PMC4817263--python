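"""Site-OTU sharing networks partitioned by glaciation history.

A bipartite graph links sites to the OTUs found in them (edge weight =
strain count), restricted to OTUs observed in at least ``min_sites`` sites
— an OTU confined to one site says nothing about sharing.  OTUs are then
classified as glacial or nonglacial when >90% of their strains come from
one site class *and* a two-sided Fisher exact test rejects random
assortment of the OTU's strains across the classes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "build_bipartite",
    "classify_otus",
    "sharing_summary",
]

GLACIAL_COLOR = "blue"
NONGLACIAL_COLOR = "red"
UNCLASSIFIED_COLOR = "gray"


def build_bipartite(community: pd.DataFrame, glaciated: pd.Series,
                    min_sites: int = 2) -> nx.Graph:
    """Bipartite site-OTU graph from a community matrix.

    Site nodes carry the ``glaciated`` flag; OTU nodes their total strain
    count and the fraction of strains from glaciated sites.  OTUs present
    in fewer than *min_sites* sites are dropped.
    """
    if community.size == 0 or community.values.sum() == 0:
        raise ValueError("community matrix is empty")
    glaciated = glaciated.loc[community.index].astype(bool)
    g = nx.Graph()
    for site in community.index:
        g.add_node(site, bipartite="site", glaciated=bool(glaciated[site]))
    for otu in community.columns:
        col = community[otu]
        present = col[col > 0]
        if len(present) < min_sites:
            continue
        total = int(col.sum())
        from_glacial = int(col[glaciated].sum())
        g.add_node(otu, bipartite="otu", total_strains=total,
                   glacial_fraction=from_glacial / total)
        for site, count in present.items():
            g.add_edge(site, otu, weight=int(count))
    return g


def classify_otus(graph: nx.Graph, threshold: float = 0.90,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Label shared OTUs glacial/nonglacial by the >threshold + Fisher rule.

    For each OTU the 2x2 table splits strains (this OTU vs all other
    retained OTUs) by site class (glaciated vs not); the test is two-sided
    Fisher exact.  An OTU is labelled only when the strain fraction from
    one class exceeds *threshold* AND p < *alpha*; otherwise it stays
    unclassified.  Labels and a matching display color are written back
    onto the graph nodes.
    """
    otus = sorted(n for n, d in graph.nodes(data=True)
                  if d.get("bipartite") == "otu")
    sites = {n: d["glaciated"] for n, d in graph.nodes(data=True)
             if d.get("bipartite") == "site"}
    if len(set(sites.values())) < 2:
        raise ValueError("both glaciated and nonglaciated sites are required")
    strain_counts = {}
    for otu in otus:
        glacial = sum(graph.edges[site, otu]["weight"]
                      for site in graph.neighbors(otu) if sites[site])
        nonglacial = sum(graph.edges[site, otu]["weight"]
                         for site in graph.neighbors(otu) if not sites[site])
        strain_counts[otu] = (glacial, nonglacial)
    tot_g = sum(g for g, _ in strain_counts.values())
    tot_n = sum(n for _, n in strain_counts.values())
    rows = []
    for otu in otus:
        g_count, n_count = strain_counts[otu]
        total = g_count + n_count
        table = [[g_count, n_count],
                 [tot_g - g_count, tot_n - n_count]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        frac_glacial = g_count / total
        if frac_glacial > threshold and p < alpha:
            label = "glacial"
        elif (1 - frac_glacial) > threshold and p < alpha:
            label = "nonglacial"
        else:
            label = "unclassified"
        color = {"glacial": GLACIAL_COLOR, "nonglacial": NONGLACIAL_COLOR,
                 "unclassified": UNCLASSIFIED_COLOR}[label]
        graph.nodes[otu]["class"] = label
        graph.nodes[otu]["color"] = color
        rows.append((otu, g_count, n_count, frac_glacial, p, label))
    return pd.DataFrame(rows, columns=[
        "otu_id", "strains_glacial", "strains_nonglacial",
        "glacial_fraction", "fisher_p", "class"]).set_index("otu_id")


def sharing_summary(graph: nx.Graph, focal_site: str | None = None) -> dict:
    """Counts of OTU sharing across the glaciation divide.

    Reports how many retained (shared) OTUs touch a glaciated site, how
    many of those also touch a nonglaciated site, how many are common to a
    focal site (e.g. a candidate refugium), and the per-site connectivity
    ranking.
    """
    otus = [n for n, d in graph.nodes(data=True)
            if d.get("bipartite") == "otu"]
    sites = {n: d["glaciated"] for n, d in graph.nodes(data=True)
             if d.get("bipartite") == "site"}
    in_glacial = [o for o in otus
                  if any(sites[s] for s in graph.neighbors(o))]
    also_nonglacial = [o for o in in_glacial
                       if any(not sites[s] for s in graph.neighbors(o))]
    degree = {s: sum(1 for _ in graph.neighbors(s)) for s in sites}
    ranking = sorted(degree, key=lambda s: (-degree[s], s))
    summary = {
        "n_shared_otus": len(otus),
        "n_shared_in_glaciated": len(in_glacial),
        "n_also_in_nonglaciated": len(also_nonglacial),
        "fraction_also_in_nonglaciated": (
            len(also_nonglacial) / len(in_glacial) if in_glacial else None),
        "site_degree": degree,
        "most_connected_site": ranking[0] if ranking else None,
    }
    if focal_site is not None:
        summary["n_common_to_focal"] = sum(
            1 for o in in_glacial if graph.has_edge(focal_site, o))
        summary["focal_site"] = focal_site
    return summary
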