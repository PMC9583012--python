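"""Neighbor-joining trees and monophyly-based discrimination scoring.

Trees are :class:`dendropy.Tree` objects throughout, so externally inferred
trees (e.g. maximum-likelihood trees in Newick) plug into the same scoring
functions as the NJ trees built here.  Species discrimination follows the
strict criterion: a species is discriminated only when all of its
accessions form a single clade — on an unrooted tree, when its leaf set is
one side of some bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .distance import DistanceMatrix, distance_matrix
from .io import LocusAlignment

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "DiscriminationScore",
    "monophyly_rate",
    "section_clustering",
    "read_newick",
    "write_newick",
]


def nj_tree(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Saitou–Nei neighbor joining from a distance matrix.

    Uses the Studier–Keppler selection criterion
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; ties are broken
    by the lexicographically smallest index pair in the current node
    ordering, so the result is deterministic given the input order.
    Negative branch-length estimates are clamped to zero.  The returned
    tree is unrooted (trifurcating seed node).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs >=3 accessions")
    if np.isnan(dm.d).any():
        iu = np.triu_indices(n, k=1)
        bad = [
            (dm.accessions[i], dm.accessions[j])
            for i, j in zip(*iu)
            if math.isnan(dm.d[i, j])
        ]
        raise ValueError(f"undefined distances for pairs: {bad[:5]}")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(dm.accessions)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for acc in dm.accessions:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(acc))
        nodes.append(node)

    # working copy of distances over active node indices
    d = {i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    active = list(range(n))
    next_idx = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best: tuple[int, int] | None = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        assert best is not None
        i, j = best
        dij = d[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes.append(parent)
        d[next_idx] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i][k] + d[j][k] - dij)
            d[next_idx][k] = duk
            d[k][next_idx] = duk
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    # final three-point resolution around the unrooted seed node
    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    seed = tree.seed_node
    for k, lk in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def _internal_bipartitions(tree: dendropy.Tree) -> set[int]:
    """Normalized leafset bitmasks of the non-trivial bipartitions."""
    tree.encode_bipartitions()
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    out = set()
    for bp in tree.bipartition_encoding:
        mask = bp.leafset_bitmask
        size = bin(mask).count("1")
        if 1 < size < bin(all_mask).count("1") - 1:
            out.add(min(mask, mask ^ all_mask))
    return out


def bootstrap_support(
    aln: LocusAlignment,
    replicates: int = 100,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement; an NJ tree is rebuilt
    per replicate; the support of each internal edge of the original tree
    is the percentage of replicates containing the same bipartition.
    Supports are stored as internal node labels and in
    ``edge.head_node.support`` annotations.
    """
    if replicates < 1:
        raise ValueError("replicates must be >=1")
    rng = np.random.default_rng(seed)
    base_dm = distance_matrix(aln)
    tree = nj_tree(base_dm)
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    n_taxa = bin(all_mask).count("1")
    counts: dict[int, int] = {}

    done = 0
    attempts = 0
    while done < replicates:
        attempts += 1
        if attempts > 100 * replicates:
            raise RuntimeError("could not draw bootstrap replicates with defined distances")
        cols = rng.integers(0, aln.length, size=aln.length)
        seqs = ["".join(s[c] for c in cols) for s in aln.seqs]
        rep_aln = LocusAlignment(aln.locus_name, list(aln.accessions), dict(aln.species_of), seqs)
        rep_dm = distance_matrix(rep_aln)
        if np.isnan(rep_dm.d).any():
            continue  # saturated resample; redraw
        rep_tree = nj_tree(rep_dm, taxon_namespace=tree.taxon_namespace)
        for mask in _internal_bipartitions(rep_tree):
            counts[mask] = counts.get(mask, 0) + 1
        done += 1

    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or edge.bipartition is None:
            continue
        mask = edge.bipartition.leafset_bitmask
        size = bin(mask).count("1")
        if not (1 < size < n_taxa - 1):
            continue
        key = min(mask, mask ^ all_mask)
        support = 100.0 * counts.get(key, 0) / replicates
        node.label = f"{support:g}"
        node.support = support
    return tree


@dataclass
class DiscriminationScore:
    """Species-discrimination outcome of one tree.

    ``rate`` counts every species (singletons are monophyletic by
    convention); ``rate_multi_only`` restricts the denominator to species
    with >=2 accessions.  Both conventions are reported because published
    percentages do not always state which one they use.
    """

    species_total: int
    species_monophyletic: int
    rate: float
    per_species: dict[str, bool] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)

    @property
    def n_multi(self) -> int:
        return self.species_total - len(self.singletons)

    @property
    def rate_multi_only(self) -> float:
        multi = [sp for sp in self.per_species if sp not in self.singletons]
        if not multi:
            return math.nan
        good = sum(self.per_species[sp] for sp in multi)
        return 100.0 * good / len(multi)


def _group_leafsets(
    tree: dendropy.Tree, label_of: Mapping[str, str]
) -> dict[str, set[str]]:
    groups: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in label_of:
            raise KeyError(f"leaf {name!r} has no group label")
        groups.setdefault(label_of[name], set()).add(name)
    return groups


def monophyly_rate(tree: dendropy.Tree, species_of: Mapping[str, str]) -> DiscriminationScore:
    """Score which species form single clades on the (unrooted) tree.

    A species with >=2 accessions is monophyletic iff its leaf set is one
    side of some bipartition of the tree; a species with one accession
    counts as monophyletic by convention and is listed in ``singletons``.
    The result is invariant to rerooting.
    """
    groups = _group_leafsets(tree, species_of)
    tree.encode_bipartitions()
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    masks = set()
    for bp in tree.bipartition_encoding:
        m = bp.leafset_bitmask
        masks.add(min(m, m ^ all_mask))

    bit_of = {}
    for leaf in tree.leaf_node_iter():
        bit_of[leaf.taxon.label] = tree.taxon_namespace.taxon_bitmask(leaf.taxon)

    per_species: dict[str, bool] = {}
    singletons: list[str] = []
    for sp, members in groups.items():
        if len(members) == 1:
            per_species[sp] = True
            singletons.append(sp)
            continue
        if len(members) == n_leaves:
            per_species[sp] = True
            continue
        mask = 0
        for acc in members:
            mask |= bit_of[acc]
        per_species[sp] = min(mask, mask ^ all_mask) in masks

    total = len(per_species)
    mono = sum(per_species.values())
    return DiscriminationScore(
        species_total=total,
        species_monophyletic=mono,
        rate=100.0 * mono / total if total else math.nan,
        per_species=per_species,
        singletons=sorted(singletons),
    )


def section_clustering(tree: dendropy.Tree, section_of: Mapping[str, str]) -> DiscriminationScore:
    """Monophyly scoring with taxonomic-section labels instead of species."""
    return monophyly_rate(tree, section_of)


def read_newick(path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
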