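"""OTU definition on patristic distances, deduplication, coverage, rarefaction.

Taxonomic units are defined on the tree, not on pairwise sequence identity:
an OTU is a group of tips whose patristic (path-length) divergence stays
within a threshold, by default 0.01 substitutions/site — a cutoff that
roughly tracks species boundaries for *Streptomyces*.  Two clustering rules
are provided because tree-based OTU callers differ in where they apply the
threshold:

``node_depth`` (default)
    OTUs are maximal clades in which every tip lies within ``threshold/2``
    of the clade root, so any two members are within ``threshold`` of each
    other through that node; monophyletic by construction.
``max_pairwise``
    complete-linkage agglomeration on the patristic matrix cut at
    ``threshold`` — clusters whose maximum pairwise distance is bounded,
    not necessarily monophyletic.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from ._tree import patristic_matrix, tip_labels

__all__ = [
    "OTUAssignment",
    "patristic_matrix",
    "cluster_otus",
    "dedup_haplotypes",
    "goods_coverage",
    "rarefaction_curve",
    "build_community",
]


@dataclasses.dataclass
class OTUAssignment:
    """A partition of tip labels into OTUs.

    ``mapping`` sends every haplotype/tip label to its OTU id.  OTU ids are
    assigned in order of each OTU's lexicographically smallest member, so
    the labelling is deterministic for a given tree and threshold.
    """

    mapping: dict[str, str]
    threshold: float
    method: str

    def otus(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for hap, otu in self.mapping.items():
            groups.setdefault(otu, []).append(hap)
        return {otu: sorted(members) for otu, members in sorted(groups.items())}

    def representatives(self) -> dict[str, str]:
        """Lexicographically smallest member of each OTU."""
        return {otu: members[0] for otu, members in self.otus().items()}

    @property
    def n_otus(self) -> int:
        return len(set(self.mapping.values()))

    def as_series(self) -> pd.Series:
        s = pd.Series(self.mapping, name="otu_id").sort_index()
        s.index.name = "haplotype_id"
        return s


def _label_groups(groups: list[list[str]], threshold: float,
                  method: str) -> OTUAssignment:
    groups = sorted([sorted(g) for g in groups], key=lambda g: g[0])
    width = max(3, len(str(len(groups))))
    mapping = {hap: f"OTU{i + 1:0{width}d}"
               for i, g in enumerate(groups) for hap in g}
    return OTUAssignment(mapping=mapping, threshold=threshold, method=method)


def cluster_otus(tree: dendropy.Tree, threshold: float = 0.01,
                 method: str = "node_depth") -> OTUAssignment:
    """Partition the tree's tips into OTUs at a patristic threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if method == "node_depth":
        groups = _node_depth_groups(tree, threshold)
    elif method == "max_pairwise":
        groups = _max_pairwise_groups(tree, threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _label_groups(groups, threshold, method)


def _node_depth_groups(tree: dendropy.Tree, threshold: float) -> list[list[str]]:
    # max distance from each node down to its own tips, by postorder sweep
    max_depth: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            max_depth[id(node)] = 0.0
        else:
            max_depth[id(node)] = max(
                max_depth[id(c)] + c.edge.length for c in node.child_nodes())
    groups: list[list[str]] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if max_depth[id(node)] <= threshold / 2.0:
            groups.append([leaf.taxon.label for leaf in node.leaf_iter()])
        else:
            stack.extend(node.child_nodes())
    return groups


def _max_pairwise_groups(tree: dendropy.Tree, threshold: float) -> list[list[str]]:
    dist = patristic_matrix(tree)
    labels = list(dist.index)
    if len(labels) == 1:
        return [labels]
    z = linkage(squareform(dist.values, checks=False), method="complete")
    flat = fcluster(z, t=threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for lab, k in zip(labels, flat):
        groups.setdefault(int(k), []).append(lab)
    return list(groups.values())


def dedup_haplotypes(alignment: dict[str, str],
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Collapse exact-identity duplicate sequences.

    Returns ``(mapping, table)``: *mapping* sends every record id to the
    lexicographically smallest id sharing its sequence; *table*, indexed by
    representative, carries the sequence and the number of collapsed records.
    """
    by_seq: dict[str, list[str]] = {}
    for rec_id in sorted(alignment):
        by_seq.setdefault(alignment[rec_id], []).append(rec_id)
    mapping = {}
    rows = []
    for seq, members in by_seq.items():
        rep = members[0]
        for m in members:
            mapping[m] = rep
        rows.append((rep, seq, len(members)))
    table = (pd.DataFrame(rows, columns=["representative", "sequence", "count"])
             .set_index("representative").sort_index())
    s = pd.Series(mapping, name="representative").sort_index()
    s.index.name = "haplotype_id"
    return s, table


def goods_coverage(counts) -> float:
    """Good's coverage estimator ``C = 1 - f1/N``.

    ``f1`` is the number of classes observed exactly once and ``N`` the
    total number of observations; an estimate of the probability that the
    next observation belongs to an already-seen class.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n_total = counts.sum()
    if n_total == 0:
        raise ValueError("total count is zero")
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / n_total


def rarefaction_curve(counts, depths, n_reps: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Expected richness at subsampling depths, Monte-Carlo and exact.

    For each depth ``d`` the table reports the mean and SD of distinct
    classes over ``n_reps`` subsamples drawn without replacement, alongside
    the exact hypergeometric expectation
    ``E[S_d] = sum_i 1 - C(N - n_i, d) / C(N, d)``.
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    depths = np.asarray(depths, dtype=int)
    if (depths < 1).any() or (depths > n_total).any():
        raise ValueError(f"depths must lie in [1, {n_total}]")
    rng = np.random.default_rng(seed)
    individuals = np.repeat(np.arange(len(counts)), counts)
    rows = []
    for d in depths:
        richness = np.empty(n_reps)
        for r in range(n_reps):
            sub = rng.choice(individuals, size=d, replace=False)
            richness[r] = len(np.unique(sub))
        exact = _expected_richness(counts, n_total, int(d))
        rows.append((int(d), richness.mean(), richness.std(ddof=1),
                     exact))
    return pd.DataFrame(rows, columns=["depth", "mean", "sd", "expected"])


def _expected_richness(counts: np.ndarray, n_total: int, depth: int) -> float:
    # 1 - C(N - n_i, d)/C(N, d) in log space; the ratio is 0 when n_i > N - d
    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for n_i in counts:
        if n_total - n_i < depth:
            total += 1.0
        else:
            total += 1.0 - np.exp(
                log_comb(n_total - n_i, depth) - log_comb(n_total, depth))
    return total


def build_community(strain_map: pd.DataFrame,
                    taxon_of: dict[str, str] | pd.Series | None = None,
                    ) -> pd.DataFrame:
    """Tabulate strains into a sites x taxa count matrix.

    ``taxon_of`` maps ``haplotype_id`` to the analysis taxon (an OTU id or a
    deduplicated representative); by default each haplotype is its own
    taxon.  When the strain map carries an ``aggregate`` column, sub-site
    samples are pooled under the aggregate label before tabulation.
    """
    df = strain_map.copy()
    if "aggregate" in df.columns:
        df["site_id"] = df["aggregate"].where(
            df["aggregate"].notna() & (df["aggregate"] != ""), df["site_id"])
    if taxon_of is not None:
        lookup = dict(taxon_of) if not isinstance(taxon_of, dict) else taxon_of
        unknown = set(df["haplotype_id"]) - set(lookup)
        if unknown:
            raise KeyError(
                f"haplotypes missing from taxon mapping: {sorted(unknown)[:5]}")
        df["taxon"] = df["haplotype_id"].map(lookup)
    else:
        df["taxon"] = df["haplotype_id"]
    table = (df.groupby(["site_id", "taxon"]).size().unstack(fill_value=0))
    table.index.name = "site_id"
    table.columns.name = None
    return table.astype(int)
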