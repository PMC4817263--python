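"""Readers and writers for every external representation the pipeline touches.

All readers validate eagerly and raise :class:`ValidationError` naming the
offending record, line or column — malformed input is never silently coerced.
Formats are deliberately plain: FASTA for alignments, Newick for trees,
tab-delimited UTF-8 tables with a header row for site metadata, strain maps
and community matrices, and GraphML for networks.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "prune_outgroup",
    "read_site_table",
    "write_site_table",
    "read_strain_map",
    "write_strain_map",
    "read_community",
    "write_community",
    "export_graphml",
    "read_graphml",
]

DNA_ALPHABET = set("ACGTN-")

SITE_COLUMNS = [
    "site_id", "latitude", "longitude", "pH", "som", "temp", "ppt",
    "glaciated", "time_rank",
]
STRAIN_COLUMNS = ["strain_id", "site_id", "haplotype_id"]


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased.  All records must share one length (the pipeline
    operates on a fixed-length alignment), ids must be unique, and only the
    characters ``A C G T N -`` are accepted.
    """
    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValidationError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
                " (alignment must be uniform length)")
        records[rec.id] = seq
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with mandatory branch lengths.

    Tip labels must be unique.  A missing branch length on any non-root edge
    is an error.  A basal polytomy is accepted but recorded as a warning,
    since the tree is treated as rooted exactly as written.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return _validate_tree(tree, source=str(path))


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValidationError(f"cannot parse newick: {exc}") from exc
    return _validate_tree(tree, source="<string>")


def _validate_tree(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate tip label {lab!r} in {source}")
        seen.add(lab)
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue  # a root edge length is optional
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "an internal node"
            raise ValidationError(
                f"missing branch length above {who} in {source}")
    if len(root.child_nodes()) > 2:
        warnings.warn(
            f"root of {source} has degree {len(root.child_nodes())}; "
            "tree accepted as rooted as written", stacklevel=3)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True))


def prune_outgroup(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Return a copy of *tree* with the outgroup tip *label* removed."""
    pruned = tree.clone(depth=1)
    taxon = pruned.taxon_namespace.get_taxon(label)
    if taxon is None:
        raise ValidationError(f"outgroup tip {label!r} not found in tree")
    pruned.prune_taxa([taxon])
    pruned.taxon_namespace.remove_taxon(taxon)
    return pruned


# ---------------------------------------------------------------------------
# Tabular inputs

def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_site_table(path) -> pd.DataFrame:
    """Read per-site metadata, indexed by ``site_id``.

    Columns: latitude/longitude (decimal degrees), pH, som (% organic
    matter), temp (mean annual °C), ppt (annual mm), glaciated (boolean),
    time_rank (1 = longest time available for colonization; unique ranks).
    """
    df = _read_tsv(path, SITE_COLUMNS)
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"duplicate site_id {dup!r}")
    for col in ("latitude", "longitude", "pH", "som", "temp", "ppt"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna(),
                         "site_id"]
            raise ValidationError(
                f"non-numeric {col} for site(s) {list(bad)}")
    out_lat = df.loc[~df["latitude"].between(-90, 90), "site_id"]
    if len(out_lat):
        raise ValidationError(
            f"latitude out of [-90, 90] for site(s) {list(out_lat)}")
    out_lon = df.loc[~df["longitude"].between(-180, 180), "site_id"]
    if len(out_lon):
        raise ValidationError(
            f"longitude out of [-180, 180] for site(s) {list(out_lon)}")
    if df["time_rank"].duplicated().any():
        raise ValidationError("time_rank values must be unique per table")
    if (df["time_rank"] < 1).any():
        raise ValidationError("time_rank must be a positive integer rank")
    df["glaciated"] = df["glaciated"].map(_parse_bool)
    df["time_rank"] = df["time_rank"].astype(int)
    return df.set_index("site_id")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.reset_index().to_csv(path, sep="\t", index=False)


def read_strain_map(path) -> pd.DataFrame:
    """Read the strain → (site, haplotype) mapping.

    An optional ``aggregate`` column names a pooled region for sub-site
    samples; downstream site-level analyses group on it when present.
    """
    df = _read_tsv(path, STRAIN_COLUMNS)
    if df["strain_id"].duplicated().any():
        dup = df.loc[df["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise ValidationError(f"duplicate strain_id {dup!r}")
    return df.astype({c: str for c in STRAIN_COLUMNS})


def write_strain_map(strains: pd.DataFrame, path) -> None:
    strains.to_csv(path, sep="\t", index=False)


def validate_dataset(alignment: dict[str, str], sites: pd.DataFrame,
                     strains: pd.DataFrame) -> None:
    """Cross-file referential checks: every strain's site and haplotype exist."""
    bad_site = set(strains["site_id"]) - set(sites.index)
    if bad_site:
        raise ValidationError(
            f"strain map references unknown site(s) {sorted(bad_site)}")
    bad_hap = set(strains["haplotype_id"]) - set(alignment)
    if bad_hap:
        raise ValidationError(
            f"strain map references unknown haplotype(s) {sorted(bad_hap)}")


# ---------------------------------------------------------------------------
# Community matrices (sites x taxa, integer strain counts)

def read_community(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count: {exc}") from exc
    if (values.values < 0).any() or (values.values % 1 != 0).any():
        raise ValidationError(
            f"{path}: community counts must be non-negative integers")
    return values.astype(int)


def write_community(community: pd.DataFrame, path) -> None:
    community.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GraphML

_SCALAR = (str, int, float, bool)


def export_graphml(graph: nx.Graph, path) -> None:
    """Write a graph to GraphML, insisting on scalar node/edge attributes."""
    for node, attrs in graph.nodes(data=True):
        for key, value in attrs.items():
            if not isinstance(value, _SCALAR):
                raise ValidationError(
                    f"node {node!r} attribute {key!r} is not a scalar: "
                    f"{type(value).__name__}")
    for u, v, attrs in graph.edges(data=True):
        for key, value in attrs.items():
            if not isinstance(value, _SCALAR):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) attribute {key!r} is not a scalar")
    nx.write_graphml(graph, str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))
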