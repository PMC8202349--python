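"""Distance phylogeny of bioindicator sequences.

Given a fixed-width window of a multiple alignment (alignment itself is
performed upstream; this module consumes aligned, equal-length rows), a
tree is inferred by neighbor joining on Jukes-Cantor corrected distances
with column-bootstrap support, the classical recipe for functional-gene
trees (440-bp window, 500 bootstraps).

The Jukes-Cantor model assumes equal substitution rates among the four
nucleotides; the observed mismatch proportion p over pairwise-comparable
columns is corrected to d = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Iterable, Optional, Sequence

import numpy as np

_ALPHABET = set("ACGT-N")


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length rows of (taxon id, gapped sequence)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        self.rows = [(t, s.upper()) for t, s in self.rows]
        L = len(self.rows[0][1])
        for t, s in self.rows:
            if len(s) != L:
                raise ValueError(f"row {t} has length {len(s)} != {L}")
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"row {t}: invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]


def read_aligned_fasta(path) -> Alignment:
    rows: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        rows.append((name, "".join(chunks)))
    return Alignment(rows)


def select_window(aln: Alignment, start: int, width: int = 440) -> Alignment:
    """Column slice [start, start + width) of the alignment."""
    if start < 0 or width < 1 or start + width > aln.length:
        raise ValueError(
            f"window [{start}, {start + width}) outside alignment of length {aln.length}"
        )
    return Alignment([(t, s[start:start + width]) for t, s in aln.rows])


# --------------------------------------------------------------------------
# Jukes-Cantor distances
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance for an observed mismatch proportion p."""
    if p >= 0.75:
        raise ValueError(f"JC correction undefined for p = {p} >= 0.75")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise JC distances with pairwise deletion of gap/N columns."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 taxa")
    seqs = [np.frombuffer(s.encode(), dtype="S1") for _, s in aln.rows]
    valid = [np.isin(s, np.array([b"A", b"C", b"G", b"T"])) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = float((seqs[i][both] != seqs[j][both]).sum()) / m
            if p >= 0.75:
                raise ValueError(
                    f"JC correction undefined for pair ({aln.taxa[i]}, {aln.taxa[j]}): p = {p:.3f}"
                )
            D[i, j] = D[j, i] = jc_correct(p)
    return DistanceMatrix(aln.taxa, D)


# --------------------------------------------------------------------------
# Tree structure
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset([self.name])
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaf_names()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree written with a (trifurcating) basal node.

    ``supports`` maps internal bipartitions — canonicalized as the side of
    the split not containing the alphabetically first taxon — to bootstrap
    percentages in [0, 100].
    """

    root: TreeNode
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as its canonical side."""
        all_taxa = self.taxa
        anchor = min(all_taxa)
        splits: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaf_names()
                if 1 < len(side) < len(all_taxa) - 1:
                    canon = side if anchor not in side else all_taxa - side
                    splits.add(canon)
                walk(child)
        walk(self.root)
        return splits

    def to_newick(self, with_support: bool = False) -> str:
        all_taxa = self.taxa
        anchor = min(all_taxa)
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            label = ""
            if with_support:
                side = node.leaf_names()
                if 1 < len(side) < len(all_taxa) - 1:
                    canon = side if anchor not in side else all_taxa - side
                    if canon in self.supports:
                        label = f"{self.supports[canon]:.0f}"
            return f"({inner}){label}"
        return fmt(self.root) + ";"


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined (ties to the smallest active index pair); branch lengths follow
    the standard two-point formulas with negative lengths clamped to zero.
    The final three lineages are resolved by the three-point formulas into
    a trifurcating basal node.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    d = D.values.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix with the new node's distances
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    lj = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    lk = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root)


def bootstrap_support(
    aln: Alignment, n_replicates: int = 500, seed: Optional[int] = None
) -> PhyloTree:
    """NJ tree with column-bootstrap bipartition support.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate tree is rebuilt with JC + NJ, and the support of every
    internal split of the full-data tree is the percentage of replicates
    containing it.  Replicates whose resampled distances leave the JC
    domain are skipped (support is then out of the successful replicates).
    """
    tree = nj_tree(jc_distance_matrix(aln))
    target = tree.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    L = aln.length
    ok = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = Alignment([(t, "".join(s[c] for c in cols)) for t, s in aln.rows])
        try:
            rep_tree = nj_tree(jc_distance_matrix(rep))
        except ValueError:
            continue
        ok += 1
        found = rep_tree.bipartitions()
        for b in target:
            if b in found:
                counts[b] += 1
    denom = max(ok, 1)
    tree.supports = {b: 100.0 * c / denom for b, c in counts.items()}
    return tree
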