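"""Molecular evolution: NG86 Ka/Ks, gene concatenation with complete
deletion, Jukes-Cantor distances, Saitou-Nei neighbor joining with
bootstrap support, and outgroup rooting.

NG86 follows the classic 1986 counting scheme: per-codon synonymous site
fractions (changes to stop codons excluded and the denominator
renormalized), averaged over both sequences; between-codon differences are
resolved by averaging over all minimal mutation paths with equal weight,
skipping paths through stop codons; pS/pN are Jukes-Cantor corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .simulate import GENETIC_CODE

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# NG86


def _syn_fraction(codon: str) -> float:
    """Fraction of synonymous one-step changes, summed over the 3 positions."""
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts, path-averaged."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # every path passes a stop: fall back to all orderings
        for order in permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    gene: str
    ka: float | None
    ks: float | None
    ratio: float | None
    classification: str
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0


def classify_ratio(ratio: float | None, band=(0.85, 1.15)) -> str:
    if ratio is None:
        return "undefined"
    if band[0] <= ratio <= band[1]:
        return "near-neutral"
    return "purifying" if ratio < 1 else "positive"


def ng86(cds_a: str, cds_b: str, gene: str = "") -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("sequences must be aligned, equal length, multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = len(cds_a) // 3
    for i in range(n_codons):
        c1 = cds_a[i * 3 : i * 3 + 3]
        c2 = cds_b[i * 3 : i * 3 + 3]
        if "-" in c1 + c2 or "N" in c1 + c2:
            continue
        terminal = i == n_codons - 1
        if c1 in _STOPS or c2 in _STOPS:
            if terminal:
                continue
            raise ValueError(f"internal stop codon at codon {i + 1}")
        s1, s2 = _syn_fraction(c1), _syn_fraction(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    if ka is None or ks is None:
        ratio = None
    elif ks == 0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(gene, ka, ks, ratio, classify_ratio(ratio), S, N, Sd, Nd)


# ---------------------------------------------------------------------------
# concatenation and distances


@dataclass
class PhyloMatrix:
    taxa: list[str]
    alignment: dict  # taxon -> concatenated, column-filtered sequence
    distances: np.ndarray  # JC distance matrix over `taxa`


def complete_deletion(alignment: dict) -> dict:
    """Remove every column containing a gap/unknown in any taxon."""
    taxa = list(alignment)
    seqs = [alignment[t] for t in taxa]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment rows differ in length")
    keep = [
        j for j in range(length)
        if all(s[j] not in "-?Nn" for s in seqs)
    ]
    return {t: "".join(alignment[t][j] for j in keep) for t in taxa}


def p_distance(a: str, b: str) -> float:
    if not a:
        return 0.0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(x != y))


def _seq_matrix(alignment: dict) -> tuple[list[str], np.ndarray]:
    taxa = list(alignment)
    mat = np.vstack(
        [np.frombuffer(alignment[t].encode(), dtype=np.uint8) for t in taxa]
    )
    return taxa, mat


def _jc_from_matrix(mat: np.ndarray, taxa: list[str]) -> np.ndarray:
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jc = jukes_cantor(float(np.mean(mat[i] != mat[j])))
            if jc is None:
                raise ValueError(f"saturated distance between {taxa[i]} and {taxa[j]}")
            d[i, j] = d[j, i] = jc
    return d


def jc_matrix(alignment: dict) -> tuple[list[str], np.ndarray]:
    taxa, mat = _seq_matrix(alignment)
    return taxa, _jc_from_matrix(mat, taxa)


def concatenate(ortholog_sets: dict, gene_list: list[str]) -> PhyloMatrix:
    """Concatenate per-gene alignments over the taxa present in all genes."""
    taxa = None
    for gene in gene_list:
        present = set(ortholog_sets[gene])
        taxa = present if taxa is None else taxa & present
    all_taxa = set().union(*(set(ortholog_sets[g]) for g in gene_list))
    for missing in sorted(all_taxa - (taxa or set())):
        log.warning("taxon %s missing from some genes; dropped", missing)
    taxa = sorted(taxa or [])
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa common to all genes")
    concat = {t: "".join(ortholog_sets[g][t] for g in gene_list) for t in taxa}
    filtered = complete_deletion(concat)
    order, d = jc_matrix(filtered)
    return PhyloMatrix(order, filtered, d)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    """Minimal phylogenetic tree node: leaves carry names, internal nodes
    carry children as (child, branch_length) pairs and optional support."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name=None, children=None, support=None):
        self.name = name
        self.children = children or []  # list of (TreeNode, float)
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _bl in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._nwk(ws)}:{bl:.6f}" for c, bl in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonicalized leaf sets."""
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        parts = set()

        def walk(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for c, _bl in node.children:
                side = walk(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor in side else all_leaves - side
                    parts.add(canon)
                below |= side
            return below

        walk(self)
        return parts


def nj_tree(distances: np.ndarray, taxa: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining; ties broken by smallest index pair;
    negative branch lengths clamped to 0 with the excess moved to the sister."""
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=t) for t in taxa]
    active = list(range(n))
    d = d.copy()
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _q, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li  # transfer the excess to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow matrix by one row/col for the new node
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    branches = []
    for idx, bl in ((i, li), (j, lj), (k, lk)):
        branches.append((nodes[idx], max(0.0, bl)))
    return TreeNode(children=branches)


def bootstrap(alignment: dict, n: int = 1000, seed: int = 0,
              matrix_builder=jc_matrix) -> TreeNode:
    """NJ tree on the full alignment with site-resampled bootstrap support."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    taxa, d = matrix_builder(alignment)
    tree = nj_tree(d, taxa)
    target = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    length = len(next(iter(alignment.values())))
    fast = matrix_builder is jc_matrix
    if fast:
        _taxa, mat = _seq_matrix(alignment)
    for _ in range(n):
        cols = rng.integers(0, length, size=length)
        try:
            if fast:
                rd = _jc_from_matrix(mat[:, cols], taxa)
                rep = nj_tree(rd, taxa)
            else:
                resampled = {t: "".join(alignment[t][c] for c in cols) for t in taxa}
                rt, rd = matrix_builder(resampled)
                rep = nj_tree(rd, rt)
        except ValueError:
            continue
        reps = rep.bipartitions()
        for bp in target:
            if bp in reps:
                target[bp] += 1

    def annotate(node):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for c, _bl in node.children:
            below |= annotate(c)
        all_leaves = frozenset(tree.leaves())
        anchor = min(all_leaves)
        canon = below if anchor in below else all_leaves - below
        if canon in target:
            node.support = 100.0 * target[canon] / n
        return below

    annotate(tree)
    return tree


def root_with_outgroup(tree: TreeNode, taxon: str) -> TreeNode:
    """Root on the outgroup's pendant edge (midpoint of that edge)."""
    if taxon not in tree.leaves():
        raise ValueError(f"outgroup {taxon!r} not in tree")
    return _reroot(tree, taxon)


def _reroot(tree: TreeNode, taxon: str) -> TreeNode:
    """Re-root an unrooted tree on the pendant edge of `taxon`."""
    # build parent maps
    parent: dict[int, tuple[TreeNode, float]] = {}
    nodes: dict[int, TreeNode] = {id(tree): tree}

    def walk(node):
        for c, bl in node.children:
            parent[id(c)] = (node, bl)
            nodes[id(c)] = c
            walk(c)

    walk(tree)
    leaf = next(n for n in nodes.values() if n.is_leaf() and n.name == taxon)
    pnode, pbl = parent[id(leaf)]

    def hang(node, coming_from) -> TreeNode:
        """Subtree at `node` when approached from `coming_from`."""
        children = []
        for c, bl in node.children:
            if c is coming_from:
                continue
            children.append((hang(c, node), bl))
        if id(node) in parent:
            par, bl = parent[id(node)]
            if par is not coming_from:
                children.append((hang(par, node), bl))
        if not children:
            return TreeNode(name=node.name)
        if node.is_leaf():
            return TreeNode(name=node.name)
        return TreeNode(children=children, support=node.support)

    other_side = hang(pnode, leaf)
    half = pbl / 2.0
    return TreeNode(children=[(TreeNode(name=taxon), half), (other_side, half)])


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a root with two children into an unrooted multifurcation."""
    if len(tree.children) != 2:
        return tree
    (a, bla), (b, blb) = tree.children
    if a.is_leaf() and b.is_leaf():
        return tree
    if b.is_leaf():
        a, b, bla, blb = b, a, blb, bla
    merged = TreeNode(children=list(b.children) + [(a, bla + blb)])
    return merged
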