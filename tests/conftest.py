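"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive each statistic with the
most naive code possible (column scans, explicit pair loops, exhaustive
enumeration) so they share no logic with the implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from barcodegap.io import LocusAlignment

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n: int,
    length: int,
    n_species: int = 1,
    mutation_rate: float = 0.05,
    missing_rate: float = 0.0,
    gap_rate: float = 0.0,
    name: str = "locus",
) -> LocusAlignment:
    """Random alignment: a reference string with iid substitutions per row."""
    ref = rng.choice(list(BASES), size=length)
    seqs = []
    accessions = []
    species_of = {}
    for i in range(n):
        row = ref.copy()
        mut = rng.random(length) < mutation_rate
        row[mut] = rng.choice(list(BASES), size=int(mut.sum()))
        row = row.astype("<U1")
        row[rng.random(length) < missing_rate] = "N"
        row[rng.random(length) < gap_rate] = "-"
        acc = f"acc{i}"
        accessions.append(acc)
        species_of[acc] = f"sp{i % n_species}"
        seqs.append("".join(row))
    return LocusAlignment(name, accessions, species_of, seqs)


# ---------------------------------------------------------------- oracles


def exact_tajima_d(n: int, S: int, big_pi) -> float:
    """Independent evaluation of Tajima's statistic with exact rational
    constants (Fraction arithmetic until the final square root)."""
    from fractions import Fraction

    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((big_pi - Fraction(S) / a1) / math.sqrt(float(var)))


def oracle_k2p(a: str, b: str) -> tuple[float, int]:
    """Straight-line K2P: explicit site loop, closed form at the end."""
    pur = set("AG")
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x in pur) == (y in pur):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan, 0
    P, Q = ts / n, tv / n
    try:
        return -0.5 * math.log1p(-(2 * P + Q)) - 0.25 * math.log1p(-2 * Q), n
    except ValueError:
        return math.nan, n


def oracle_p_distance(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x in BASES and y in BASES]
    if not pairs:
        return math.nan
    return sum(x != y for x, y in pairs) / len(pairs)


def oracle_segregating_sites(aln: LocusAlignment) -> int:
    s = 0
    for col in range(aln.length):
        chars = {seq[col] for seq in aln.seqs} & set(BASES)
        if len(chars) > 1:
            s += 1
    return s


def oracle_pi(aln: LocusAlignment) -> float:
    vals = []
    for a, b in itertools.combinations(aln.seqs, 2):
        d = oracle_p_distance(a, b)
        if not math.isnan(d):
            vals.append(d)
    return sum(vals) / len(vals)


def oracle_best_match_verdict(
    query: str, dmat: dict[tuple[str, str], float], species: dict[str, str]
) -> tuple[str, float]:
    """Exhaustive nearest-neighbour classification for one query."""
    others = sorted({a for pair in dmat for a in pair if a != query})
    dists = {o: dmat[tuple(sorted((query, o)))] for o in others}
    dists = {o: v for o, v in dists.items() if not math.isnan(v)}
    dmin = min(dists.values())
    tied_species = {species[o] for o, v in dists.items() if v == dmin}
    if tied_species == {species[query]}:
        return "correct", dmin
    if species[query] in tied_species or len(tied_species) > 1:
        return "ambiguous", dmin
    return "incorrect", dmin


def oracle_is_monophyletic(tree, members: set[str]) -> bool:
    """Enumerate every edge; check the leaf set on one side equals members."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if len(members) in (1, len(leaves)):
        return True
    for node in tree.preorder_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == members or (leaves - below) == members:
            return True
    return False


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with strictly positive branch lengths, plus its
    exact leaf-to-leaf path-distance matrix."""
    import dendropy

    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes = [dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa]
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(pool[i])
        parent.add_child(pool[j])
        pool[i].edge.length = float(rng.uniform(0.05, 0.5))
        pool[j].edge.length = float(rng.uniform(0.05, 0.5))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    for p in pool:
        tree.seed_node.add_child(p)
        p.edge.length = float(rng.uniform(0.05, 0.5))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(n_leaves):
            if a != b:
                d[a, b] = pdm.patristic_distance(
                    ns.get_taxon(taxa[a]), ns.get_taxon(taxa[b])
                )
    return tree, taxa, d


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
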