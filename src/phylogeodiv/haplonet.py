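"""Statistical-parsimony haplotype networks and nested clade analysis.

The pipeline here mirrors the classic phylogeographic workflow: connect
haplotypes into a network of single mutational steps up to a
parsimony-justified connection limit, break ambiguous loops with
frequency/topology/geography preference rules, nest the network into a
clade hierarchy, compute the geographic clade statistics Dc and Dn with a
permutation null, and read the significance pattern through a pluggable,
machine-readable inference table.

Only the inference chains relevant to range-expansion and
isolation-by-distance signatures ship by default; the table is editable
JSON, so other chains of the published key can be added without touching
code.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .beta import EARTH_RADIUS_KM

__all__ = [
    "parsimony_limit",
    "parsimony_probability",
    "hamming",
    "build_network",
    "resolve_loops",
    "nest_clades",
    "NestedDesign",
    "clade_distances",
    "nca_permutation",
    "interpret",
    "DEFAULT_INFERENCE_TABLE",
    "annotate_network",
]


# ---------------------------------------------------------------------------
# Connection limit

def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that *steps* mutations hit *steps* distinct sites.

    Under uniform placement of mutations over ``seq_length`` sites, the
    chance that j changes produced exactly j observed differences — i.e.
    that parsimony holds, with no superimposed change — is the product
    ``prod_{i=1}^{j-1} (1 - i/L)``.  This is the no-multiple-hit criterion
    that underlies statistical-parsimony network building.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be positive")
    if steps < 1:
        return 1.0
    p = 1.0
    for i in range(1, steps):
        p *= max(0.0, 1.0 - i / seq_length)
    return p


def parsimony_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps whose parsimony probability exceeds *confidence*.

    Haplotype pairs separated by more steps than this are left
    unconnected; the limit is non-decreasing in sequence length and
    collapses to single steps as the confidence approaches 1.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while parsimony_probability(j + 1, seq_length) > confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# Network construction

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def build_network(haplotypes: dict[str, str],
                  counts: dict[str, int] | None = None,
                  limit: int | None = None,
                  confidence: float = 0.95) -> nx.Graph:
    """Connect haplotypes into a statistical-parsimony network.

    Pairs are joined in increasing order of Hamming distance; a pair at
    distance d > 1 is bridged by d−1 inferred (unsampled) intermediate
    nodes so every edge spans exactly one mutational step.  A pair is only
    joined when it adds information — when the two haplotypes are in
    different components or farther apart in the current network than their
    mutational distance.  Equally parsimonious alternative connections
    discovered in the same distance round are all retained, which is what
    produces ambiguity loops.  Joining stops at the connection *limit*
    (derived from the sequence length at *confidence* when not given).
    """
    labels = sorted(haplotypes)
    if limit is None:
        limit = parsimony_limit(len(haplotypes[labels[0]]), confidence)
    counts = counts or {}
    g = nx.Graph()
    for lab in labels:
        g.add_node(lab, kind="observed", count=int(counts.get(lab, 1)))
    dists: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(labels, 2):
        dists[(a, b)] = hamming(haplotypes[a], haplotypes[b])
    inferred = itertools.count(1)
    for d in range(1, limit + 1):
        snapshot = g.copy()
        for (a, b), hd in sorted(dists.items()):
            if hd != d:
                continue
            if _graph_distance(snapshot, a, b) <= d:
                continue  # already parsimoniously connected
            prev = a
            for _ in range(d - 1):
                mid = f"inf{next(inferred):03d}"
                g.add_node(mid, kind="inferred", count=0)
                g.add_edge(prev, mid)
                prev = mid
            g.add_edge(prev, b)
    return g


def _graph_distance(g: nx.Graph, a: str, b: str) -> float:
    try:
        return nx.shortest_path_length(g, a, b)
    except nx.NetworkXNoPath:
        return math.inf


def resolve_loops(g: nx.Graph,
                  coords: pd.DataFrame | None = None) -> nx.Graph:
    """Break every ambiguity loop, returning an acyclic network.

    Within each cycle the edge removed is chosen by the standard
    preference order — keep connections to higher-frequency haplotypes,
    then to interior (higher-degree) nodes, then to geographically closer
    ones — with a deterministic label tie-break.  *coords* optionally gives
    per-haplotype occurrence centroids (columns ``latitude, longitude``)
    for the geographic criterion.  Connected components are unchanged.
    """
    out = g.copy()
    while True:
        cycles = sorted(nx.cycle_basis(out), key=lambda c: sorted(c))
        if not cycles:
            return out
        cycle = cycles[0]
        edges = list(zip(cycle, cycle[1:] + cycle[:1]))

        def removal_key(edge):
            u, v = sorted(edge)
            freq = out.nodes[u].get("count", 0) + out.nodes[v].get("count", 0)
            interior = out.degree(u) + out.degree(v)
            geo = 0.0
            if coords is not None and u in coords.index and v in coords.index:
                geo = great_circle_km(
                    coords.at[u, "latitude"], coords.at[u, "longitude"],
                    coords.at[v, "latitude"], coords.at[v, "longitude"])
            # lowest frequency first, least interior, farthest apart
            return (freq, interior, -geo, (u, v))

        out.remove_edge(*min(edges, key=removal_key))


def annotate_network(g: nx.Graph, strain_map: pd.DataFrame,
                     sites: pd.DataFrame) -> nx.Graph:
    """Attach strain counts, per-site composition and glacial fraction.

    Node attributes become GraphML-safe scalars; the per-site composition
    is serialized as a JSON string.
    """
    out = g.copy()
    per_site = strain_map.groupby(["haplotype_id", "site_id"]).size()
    for node in out.nodes:
        if out.nodes[node].get("kind") != "observed":
            out.nodes[node]["glacial_fraction"] = 0.0
            out.nodes[node]["site_counts"] = "{}"
            continue
        site_counts = (per_site.loc[node].to_dict()
                       if node in per_site.index.get_level_values(0) else {})
        total = sum(site_counts.values())
        glacial = sum(c for s, c in site_counts.items()
                      if sites.at[s, "glaciated"])
        out.nodes[node]["count"] = int(total)
        out.nodes[node]["glacial_fraction"] = (
            glacial / total if total else 0.0)
        out.nodes[node]["site_counts"] = json.dumps(
            site_counts, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Nesting

@dataclasses.dataclass
class NestedDesign:
    """Hierarchical nesting of a loop-free haplotype network.

    ``levels[k]`` maps each level-(k+1) clade id to the ids it nests
    (level-0 units are the network nodes themselves).  ``tip_status`` marks
    whether a clade was a tip (degree ≤ 1) of the clade graph at its own
    level, and ``parent`` links every unit to its nesting clade.
    """

    network: nx.Graph
    levels: list[dict[str, list[str]]]
    tip_status: dict[str, bool]
    parent: dict[str, str]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def members(self, clade_id: str) -> set[str]:
        """Network node labels contained in a clade (any level)."""
        if self.network.has_node(clade_id):
            return {clade_id}
        for level in self.levels:
            if clade_id in level:
                out: set[str] = set()
                for child in level[clade_id]:
                    out |= self.members(child)
                return out
        raise KeyError(f"unknown clade {clade_id!r}")

    def haplotypes(self, clade_id: str) -> set[str]:
        return {n for n in self.members(clade_id)
                if self.network.nodes[n].get("kind") == "observed"}

    def clades_at(self, level: int) -> list[str]:
        if level == 0:
            return sorted(self.network.nodes)
        return sorted(self.levels[level - 1])


def nest_clades(network: nx.Graph) -> NestedDesign:
    """Agglomerate a loop-free network into nested clades.

    Tip-first, label-ordered processing: at each level, every ungrouped
    tip unit absorbs its ungrouped neighbors within one step, interior
    units follow, and a unit stranded amid already-grouped neighbors joins
    its smallest adjacent clade.  The procedure repeats on the clade graph
    until each connected component is a single clade, so every haplotype
    belongs to exactly one clade per level.
    """
    if len(nx.cycle_basis(network)) > 0:
        raise ValueError("network contains loops; resolve them first")
    design = NestedDesign(network=network, levels=[], tip_status={},
                          parent={})
    graph = network.copy()
    for node in graph.nodes:
        design.tip_status[node] = graph.degree(node) <= 1
    level = 0
    while graph.number_of_nodes() > nx.number_connected_components(graph):
        level += 1
        grouping = _one_step_grouping(graph)
        new_level = {}
        new_graph = nx.Graph()
        for k, members in enumerate(grouping, start=1):
            cid = f"C{level}.{k}"
            new_level[cid] = sorted(members)
            for m in members:
                design.parent[m] = cid
            new_graph.add_node(cid)
        owner = {m: cid for cid, ms in new_level.items() for m in ms}
        for u, v in graph.edges:
            if owner[u] != owner[v]:
                new_graph.add_edge(owner[u], owner[v])
        for cid in new_graph.nodes:
            design.tip_status[cid] = new_graph.degree(cid) <= 1
        design.levels.append(new_level)
        graph = new_graph
    for cid in graph.nodes:
        design.parent.setdefault(cid, "")
    return design


def _one_step_grouping(graph: nx.Graph) -> list[list[str]]:
    tips = sorted(n for n in graph.nodes if graph.degree(n) <= 1)
    interiors = sorted(n for n in graph.nodes if graph.degree(n) > 1)
    grouped: set[str] = set()
    groups: list[list[str]] = []
    for u in tips + interiors:
        if u in grouped:
            continue
        members = [u] + [v for v in sorted(graph.neighbors(u))
                         if v not in grouped]
        grouped.update(members)
        groups.append(sorted(members))
    return groups


# ---------------------------------------------------------------------------
# Geographic clade statistics

def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (math.sin((p2 - p1) / 2) ** 2
         + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _centroid(lats: np.ndarray, lons: np.ndarray,
              weights: np.ndarray) -> tuple[float, float]:
    """Weighted spherical centroid via the mean of unit vectors."""
    phi = np.radians(lats)
    lam = np.radians(lons)
    w = weights / weights.sum()
    x = (w * np.cos(phi) * np.cos(lam)).sum()
    y = (w * np.cos(phi) * np.sin(lam)).sum()
    z = (w * np.sin(phi)).sum()
    norm = math.sqrt(x * x + y * y + z * z)
    if norm < 1e-12:  # pathological antipodal balance
        return float(lats.mean()), float(lons.mean())
    return (math.degrees(math.asin(z / norm)),
            math.degrees(math.atan2(y, x)))


def _gc_many(lats: np.ndarray, lons: np.ndarray, center) -> np.ndarray:
    phi = np.radians(np.asarray(lats, dtype=float))
    lam = np.radians(np.asarray(lons, dtype=float))
    cphi, clam = math.radians(center[0]), math.radians(center[1])
    h = (np.sin((cphi - phi) / 2) ** 2
         + np.cos(phi) * math.cos(cphi) * np.sin((clam - lam) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _mean_distance_to(lats, lons, weights, center) -> float:
    w = np.asarray(weights, dtype=float)
    d = _gc_many(np.asarray(lats, dtype=float),
                 np.asarray(lons, dtype=float), center)
    return float((d * w).sum() / w.sum())


def _observations(design: NestedDesign,
                  strain_coords: pd.DataFrame) -> pd.DataFrame:
    required = {"haplotype_id", "latitude", "longitude"}
    if not required <= set(strain_coords.columns):
        raise ValueError(f"strain_coords needs columns {sorted(required)}")
    known = {n for n in design.network.nodes
             if design.network.nodes[n].get("kind") == "observed"}
    return strain_coords[strain_coords["haplotype_id"].isin(known)].copy()


def clade_distances(design: NestedDesign,
                    strain_coords: pd.DataFrame) -> pd.DataFrame:
    """Dc and Dn (km) for every clade at every nesting level.

    One row of *strain_coords* is one strain observation (so abundance
    weighting is implicit).  Dc measures each clade's members about the
    clade's own spherical centroid; Dn measures them about the centroid of
    the nesting (parent) clade, the outermost clades being referred to the
    whole-network centroid.
    """
    obs = _observations(design, strain_coords)
    all_center = _centroid(obs["latitude"].values, obs["longitude"].values,
                           np.ones(len(obs)))
    rows = []
    for level in range(design.n_levels + 1):
        for cid in design.clades_at(level):
            haps = design.haplotypes(cid)
            sub = obs[obs["haplotype_id"].isin(haps)]
            if sub.empty:
                continue
            center = _centroid(sub["latitude"].values,
                               sub["longitude"].values,
                               np.ones(len(sub)))
            dc = _mean_distance_to(sub["latitude"], sub["longitude"],
                                   np.ones(len(sub)), center)
            parent = design.parent.get(cid, "")
            if parent:
                par_haps = design.haplotypes(parent)
                par = obs[obs["haplotype_id"].isin(par_haps)]
                par_center = _centroid(par["latitude"].values,
                                       par["longitude"].values,
                                       np.ones(len(par)))
            else:
                par_center = all_center
            dn = _mean_distance_to(sub["latitude"], sub["longitude"],
                                   np.ones(len(sub)), par_center)
            rows.append((level, cid, parent, len(sub),
                         design.tip_status.get(cid, True), dc, dn))
    return pd.DataFrame(rows, columns=[
        "level", "clade", "parent", "n_strains", "is_tip", "dc", "dn"])


def nca_permutation(design: NestedDesign, strain_coords: pd.DataFrame,
                    n_perm: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Permutation significance of Dc/Dn within each nesting clade.

    Within every nesting clade containing at least two sampled subclades,
    strain observations are shuffled among the parent's observations
    (subclade sample sizes preserved) and Dc/Dn recomputed; a clade is
    flagged ``dc_small``/``dc_large`` (likewise ``dn``) when the smoothed
    one-sided permutation probability is ≤ *alpha*.  The interior-vs-tip
    Dc and Dn contrasts within each nesting clade are tested the same way.
    """
    obs = _observations(design, strain_coords)
    table = clade_distances(design, strain_coords)
    rng = np.random.default_rng(seed)
    table = table.set_index("clade")
    cols = {c: [] for c in ["p_dc_small", "p_dc_large", "p_dn_small",
                            "p_dn_large", "dc_small", "dc_large",
                            "dn_small", "dn_large"]}
    contrasts = []
    for parent in sorted(set(table["parent"]) - {""}):
        children = [c for c in table.index if table.at[c, "parent"] == parent]
        _test_nesting(design, obs, table, parent, children, n_perm, rng,
                      alpha, cols, contrasts)
    # top-level clades are tested against the whole network
    top = [c for c in table.index if table.at[c, "parent"] == ""]
    if len(top) > 1:
        _test_nesting(design, obs, table, None, top, n_perm, rng,
                      alpha, cols, contrasts)
    result = table.reset_index()
    for name, values in cols.items():
        lookup = dict(values)
        if name.startswith("p_"):
            result[name] = [lookup.get(c, np.nan) for c in result["clade"]]
        else:
            result[name] = [lookup.get(c, False) for c in result["clade"]]
    result.attrs["interior_tip_contrasts"] = pd.DataFrame(
        contrasts, columns=["parent", "it_dc", "it_dn", "p_it_dc_small",
                            "p_it_dc_large", "p_it_dn_small",
                            "p_it_dn_large"])
    result.attrs["alpha"] = alpha
    result.attrs["n_perm"] = n_perm
    result.attrs["seed"] = seed
    return result


def _clade_stats(groups: list[tuple[np.ndarray, np.ndarray]], parent_center,
                 tips: list[bool]) -> tuple[np.ndarray, np.ndarray,
                                            float, float]:
    dcs, dns = [], []
    for lats, lons in groups:
        ones = np.ones(len(lats))
        center = _centroid(lats, lons, ones)
        dcs.append(float(_gc_many(lats, lons, center).mean()))
        dns.append(float(_gc_many(lats, lons, parent_center).mean()))
    dcs, dns = np.array(dcs), np.array(dns)
    tips_arr = np.array(tips)
    it_dc = it_dn = np.nan
    if tips_arr.any() and (~tips_arr).any():
        it_dc = dcs[~tips_arr].mean() - dcs[tips_arr].mean()
        it_dn = dns[~tips_arr].mean() - dns[tips_arr].mean()
    return dcs, dns, it_dc, it_dn


def _test_nesting(design, obs, table, parent, children, n_perm, rng,
                  alpha, cols, contrasts) -> None:
    child_obs = []
    kept = []
    for c in children:
        haps = design.haplotypes(c)
        sub = obs[obs["haplotype_id"].isin(haps)]
        if not sub.empty:
            child_obs.append((sub["latitude"].values.astype(float),
                              sub["longitude"].values.astype(float)))
            kept.append(c)
    if len(kept) < 2:
        return
    all_lat = np.concatenate([g[0] for g in child_obs])
    all_lon = np.concatenate([g[1] for g in child_obs])
    parent_center = _centroid(all_lat, all_lon, np.ones(len(all_lat)))
    tips = [bool(table.at[c, "is_tip"]) for c in kept]
    sizes = [len(g[0]) for g in child_obs]
    dc_obs, dn_obs, it_dc_obs, it_dn_obs = _clade_stats(
        child_obs, parent_center, tips)
    le_dc = np.zeros(len(kept))
    ge_dc = np.zeros(len(kept))
    le_dn = np.zeros(len(kept))
    ge_dn = np.zeros(len(kept))
    it_counts = np.zeros(4)
    for _ in range(n_perm):
        perm = rng.permutation(len(all_lat))
        start = 0
        groups = []
        for size in sizes:
            idx = perm[start:start + size]
            groups.append((all_lat[idx], all_lon[idx]))
            start += size
        dc_p, dn_p, it_dc_p, it_dn_p = _clade_stats(
            groups, parent_center, tips)
        le_dc += dc_p <= dc_obs + 1e-9
        ge_dc += dc_p >= dc_obs - 1e-9
        le_dn += dn_p <= dn_obs + 1e-9
        ge_dn += dn_p >= dn_obs - 1e-9
        if not math.isnan(it_dc_obs):
            it_counts += [it_dc_p <= it_dc_obs + 1e-9,
                          it_dc_p >= it_dc_obs - 1e-9,
                          it_dn_p <= it_dn_obs + 1e-9,
                          it_dn_p >= it_dn_obs - 1e-9]
    smooth = lambda b: (1 + b) / (n_perm + 1)  # noqa: E731
    for i, c in enumerate(kept):
        p_dc_s, p_dc_l = smooth(le_dc[i]), smooth(ge_dc[i])
        p_dn_s, p_dn_l = smooth(le_dn[i]), smooth(ge_dn[i])
        cols["p_dc_small"].append((c, p_dc_s))
        cols["p_dc_large"].append((c, p_dc_l))
        cols["p_dn_small"].append((c, p_dn_s))
        cols["p_dn_large"].append((c, p_dn_l))
        cols["dc_small"].append((c, p_dc_s <= alpha))
        cols["dc_large"].append((c, p_dc_l <= alpha))
        cols["dn_small"].append((c, p_dn_s <= alpha))
        cols["dn_large"].append((c, p_dn_l <= alpha))
    if not math.isnan(it_dc_obs):
        contrasts.append((parent or "<network>", it_dc_obs, it_dn_obs,
                          smooth(it_counts[0]), smooth(it_counts[1]),
                          smooth(it_counts[2]), smooth(it_counts[3])))


# ---------------------------------------------------------------------------
# Inference

DEFAULT_INFERENCE_TABLE = [
    {
        "label": "restricted gene flow with isolation by distance",
        "all_of": ["tip_dc_small"],
        "any_of": ["interior_dc_large", "it_dc_large", "interior_dn_large"],
    },
    {
        "label": "contiguous range expansion",
        "any_of": ["tip_dc_large", "tip_dn_large", "it_dc_small",
                   "it_dn_small", "interior_dc_small"],
    },
]


def interpret(nca_result: pd.DataFrame, parent: str,
              inference_table: list[dict] | str | Path | None = None) -> str:
    """Classify one nesting clade's significance pattern.

    The flag pattern of *parent*'s subclades (and the interior-tip
    contrasts) is condensed into named features and looked up through the
    decision table: the first rule whose ``all_of`` features are all
    present and at least one ``any_of`` feature (when given) matches wins.
    No significant flags → ``"no significant association"``; no matching
    rule → ``"inconclusive"``.
    """
    table = _load_table(inference_table)
    rows = nca_result[nca_result["parent"] == parent]
    if rows.empty:
        raise KeyError(f"no subclades nested in {parent!r}")
    features = set()
    for _, row in rows.iterrows():
        role = "tip" if row["is_tip"] else "interior"
        for stat in ("dc", "dn"):
            for side in ("small", "large"):
                if bool(row.get(f"{stat}_{side}", False)):
                    features.add(f"{role}_{stat}_{side}")
    contrasts = nca_result.attrs.get("interior_tip_contrasts")
    alpha = nca_result.attrs.get("alpha", 0.05)
    if contrasts is not None and len(contrasts):
        crow = contrasts[contrasts["parent"] == (parent or "<network>")]
        if len(crow):
            crow = crow.iloc[0]
            for stat in ("dc", "dn"):
                if crow[f"p_it_{stat}_small"] <= alpha:
                    features.add(f"it_{stat}_small")
                if crow[f"p_it_{stat}_large"] <= alpha:
                    features.add(f"it_{stat}_large")
    if not features:
        return "no significant association"
    for rule in table:
        if not isinstance(rule, dict) or "label" not in rule:
            raise ValueError("malformed inference table entry")
        all_of = set(rule.get("all_of", []))
        any_of = set(rule.get("any_of", []))
        if all_of <= features and (not any_of or any_of & features):
            return rule["label"]
    return "inconclusive"


def _load_table(source) -> list[dict]:
    if source is None:
        return DEFAULT_INFERENCE_TABLE
    if isinstance(source, (str, Path)):
        table = json.loads(Path(source).read_text())
    else:
        table = source
    if not isinstance(table, list):
        raise ValueError("inference table must be a list of rules")
    return table
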