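"""Cross-cell-type DNase I hypersensitive site (DHS) analysis.

Peaks from many cell types are single-linkage clustered on the genomic
line: any >= 1 bp overlap links two DHSs, and connected components
become clusters spanning the union interval with the contributing cell
types as members.  Each cell type's binary on/off vector over clusters
feeds a Euclidean-distance agglomerative tree (average linkage,
deterministic lexicographic leaf order) which can be re-rooted on an
outgroup clade.  Clusters can also be classified as transcribed from
high-mapping-quality RNA read intervals and two cluster sets compared
with a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .intervals import GenomeIntervals


def cluster_dhs(atlas: Mapping[str, GenomeIntervals]) -> pd.DataFrame:
    """Single-linkage clusters of DHSs across cell types.

    Returns one row per cluster: chrom, start, end (the union interval),
    members (sorted tuple of cell types), k (member count), and a
    specificity class: ``cell_type_specific`` (k = 1), ``ubiquitous``
    (k = all), else ``shared``.
    """
    n_types = len(atlas)
    events: Dict[str, List[Tuple[int, int, str]]] = {}
    for cell_type, ivs in atlas.items():
        for chrom, start, end in ivs.records():
            events.setdefault(chrom, []).append((start, end, cell_type))
    rows = []
    for chrom in sorted(events):
        cur_start = cur_end = None
        members: set = set()
        for start, end, cell_type in sorted(events[chrom]):
            if cur_end is None or start >= cur_end:  # touching does not link
                if cur_end is not None:
                    rows.append((chrom, cur_start, cur_end,
                                 tuple(sorted(members)), len(members)))
                cur_start, cur_end, members = start, end, {cell_type}
            else:
                cur_end = max(cur_end, end)
                members.add(cell_type)
        if cur_end is not None:
            rows.append((chrom, cur_start, cur_end,
                         tuple(sorted(members)), len(members)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "members", "k"])
    df["specificity"] = np.select(
        [df["k"] == 1, df["k"] == n_types],
        ["cell_type_specific", "ubiquitous"], default="shared")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class ClusterTree:
    """Binary presence profile tree over DHS clusters."""

    labels: Tuple[str, ...]
    matrix: np.ndarray           # (n_types, n_clusters) 0/1
    linkage: np.ndarray          # scipy linkage matrix
    tree: dendropy.Tree

    @property
    def distances(self) -> np.ndarray:
        return squareform(pdist(self.matrix.astype(float), metric="euclidean"))

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def presence_matrix(cluster_table: pd.DataFrame,
                    cell_types: Sequence[str]) -> np.ndarray:
    """Binary (cell type x cluster) membership matrix."""
    labels = list(cell_types)
    m = np.zeros((len(labels), len(cluster_table)), dtype=np.int8)
    index = {ct: i for i, ct in enumerate(labels)}
    for j, members in enumerate(cluster_table["members"]):
        for ct in members:
            if ct in index:
                m[index[ct], j] = 1
    return m


def _linkage_to_dendropy(Z: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """scipy linkage -> dendropy tree with branch lengths from merge heights."""
    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = {}
    heights = {}
    for i, name in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[i] = node
        heights[i] = 0.0
    n = len(labels)
    for step, (a, b, h, _) in enumerate(Z):
        parent = dendropy.Node()
        for child in (int(a), int(b)):
            nodes[child].edge.length = float(h) - heights[child]
            parent.add_child(nodes[child])
        nodes[n + step] = parent
        heights[n + step] = float(h)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[n + len(Z) - 1] if len(Z) else nodes[0]
    tree.is_rooted = True
    return tree


def build_tree(
    cluster_table: pd.DataFrame,
    cell_types: Sequence[str],
    outgroup: Optional[Sequence[str]] = None,
    linkage_method: str = "average",
) -> ClusterTree:
    """Agglomerative tree of cell types from binary cluster profiles.

    Cell types are ordered lexicographically before linkage so ties
    break deterministically.  When ``outgroup`` labels are given the
    tree is re-rooted on the edge above their most recent common
    ancestor.
    """
    labels = tuple(sorted(cell_types))
    m = presence_matrix(cluster_table, labels)
    d = pdist(m.astype(float), metric="euclidean")
    Z = hierarchy.linkage(d, method=linkage_method)
    tree = _linkage_to_dendropy(Z, labels)
    if outgroup:
        missing = set(outgroup) - set(labels)
        if missing:
            raise ValueError(f"outgroup labels not in atlas: {sorted(missing)}")
        if set(outgroup) != set(labels):
            taxa = [tree.taxon_namespace.get_taxon(t) for t in outgroup]
            mrca = tree.mrca(taxa=taxa)
            if mrca is not tree.seed_node:
                tree.reroot_at_edge(mrca.edge,
                                    length1=(mrca.edge.length or 0.0) / 2,
                                    length2=(mrca.edge.length or 0.0) / 2,
                                    update_bipartitions=True)
    return ClusterTree(labels, m, Z, tree)


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def trees_equal(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Structural equality by symmetric (Robinson-Foulds) distance."""
    tns = dendropy.TaxonNamespace()
    a2 = dendropy.Tree.get(data=a.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    b2 = dendropy.Tree.get(data=b.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    a2.encode_bipartitions()
    b2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a2, b2) == 0


def combination_enrichment(
    cluster_table: pd.DataFrame,
    focal_cell_type: str,
    positions: Mapping[str, np.ndarray],
    territory,
    n_samplings: int = 1_000,
    seed: int = 0,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Mutational load versus the number of cell types sharing a DHS.

    For each k = 1..n, clusters active in exactly k cell types are split
    into those containing the focal type and those not, and each group
    is scored with the rotation-null enrichment statistic.  Groups with
    fewer than ``min_overlap`` observed overlaps are suppressed.
    """
    from .enrichment import Territory, enrichment

    if isinstance(territory, GenomeIntervals):
        territory = Territory(territory)
    max_k = int(cluster_table["k"].max()) if len(cluster_table) else 0
    rows = []
    for k in range(1, max_k + 1):
        at_k = cluster_table[cluster_table["k"] == k]
        for series, sub in (
            ("focal", at_k[[focal_cell_type in m for m in at_k["members"]]]),
            ("non_focal", at_k[[focal_cell_type not in m
                                for m in at_k["members"]]]),
        ):
            if len(sub) == 0:
                continue
            feats = GenomeIntervals.from_frame(sub)
            res = enrichment(
                positions, feats, territory, n_samplings=n_samplings,
                seed=np.random.default_rng(
                    [seed & 0x7FFFFFFF, k, 0 if series == "focal" else 1]),
                min_overlap=min_overlap, label=f"k={k}:{series}")
            row = res.to_row()
            row["k"] = k
            row["series"] = series
            row["n_clusters"] = len(sub)
            rows.append(row)
    return pd.DataFrame(rows)


def transcribed_dhs(
    cluster_table: pd.DataFrame,
    rna: pd.DataFrame,
    min_mapq: int = 30,
) -> pd.Series:
    """True where >= 1 RNA interval with mapq >= ``min_mapq`` overlaps."""
    good = rna[rna["mapq"] >= min_mapq]
    rna_iv = GenomeIntervals.from_frame(good) if len(good) else GenomeIntervals()
    flags = [
        rna_iv.overlaps_interval(row.chrom, row.start, row.end)
        for row in cluster_table.itertuples(index=False)
    ]
    return pd.Series(flags, index=cluster_table.index, name="transcribed")


def compare_transcription(
    flags_a: pd.Series,
    flags_b: pd.Series,
) -> Tuple[np.ndarray, float, float]:
    """Fisher 2x2 of (cluster set membership) x (transcribed).

    Returns (table, odds ratio, two-sided p-value); table rows are the
    two sets, columns transcribed / untranscribed.
    """
    table = np.array([
        [int(flags_a.sum()), int((~flags_a.astype(bool)).sum())],
        [int(flags_b.sum()), int((~flags_b.astype(bool)).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)
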