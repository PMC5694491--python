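"""Haplotype grouping and neighbor-joining trees.

Amino-acid haplotypes are equivalence classes of identical residues at the
polymorphic positions.  Trees use Jukes–Cantor distances with pairwise
deletion (the usual distance-tree default, unlike the complete deletion used
by the diversity statistics), Saitou–Nei neighbor joining, column-bootstrap
support, and contraction of branches below a support threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .alignments import MISSING, CodonAlignment
from .codonz import SaturationError

logger = logging.getLogger(__name__)

#: residues treated as missing when collapsing protein haplotypes
PROTEIN_MISSING = frozenset("X-*?")


@dataclass(frozen=True)
class HaplotypeGroup:
    label: str
    residues: tuple[str, ...]
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class HaplotypeTable:
    """Collapsed haplotype structure of a protein alignment."""

    positions: tuple[int, ...]  # 1-based residue coordinates
    groups: tuple[HaplotypeGroup, ...]

    @property
    def n_polymorphic_positions(self) -> int:
        return len(self.positions)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def collapse_aa_haplotypes(records: list[tuple[str, str]]) -> HaplotypeTable:
    """Collapse aligned protein sequences into haplotype groups.

    Polymorphic positions are columns with at least two distinct non-missing
    residues; groups are classes of identical strings restricted to those
    positions, ordered by descending size then first occurrence.
    """
    records = [(str(i), str(s)) for i, s in records]
    if not records:
        raise ValueError("empty protein alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError("protein sequences have unequal lengths")
    L = lengths.pop()
    positions = []
    for j in range(L):
        residues = {s[j] for _, s in records} - PROTEIN_MISSING
        if len(residues) >= 2:
            positions.append(j + 1)

    keys: dict[tuple[str, ...], list[str]] = {}
    order: list[tuple[str, ...]] = []
    for rid, seq in records:
        key = tuple(seq[p - 1] for p in positions)
        if key not in keys:
            keys[key] = []
            order.append(key)
        keys[key].append(rid)
    ranked = sorted(order, key=lambda k: (-len(keys[k]), order.index(k)))
    groups = tuple(
        HaplotypeGroup(label=f"H{i + 1}", residues=key, member_ids=tuple(keys[key]))
        for i, key in enumerate(ranked)
    )
    return HaplotypeTable(positions=tuple(positions), groups=groups)


def jc_distance_matrix(alignment: CodonAlignment | list[tuple[str, str]]) -> DistanceMatrix:
    """Jukes–Cantor distances with pairwise deletion of missing sites."""
    records = alignment.records if isinstance(alignment, CodonAlignment) else list(alignment)
    ids = [i for i, _ in records]
    seqs = [s for _, s in records]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, -1)
    missing = np.zeros(arr.shape, dtype=bool)
    for c in MISSING:
        missing |= arr == ord(c)
    D = np.zeros((n, n))
    for i in range(n - 1):
        ok = ~missing[i] & ~missing[i + 1 :]
        compared = ok.sum(axis=1)
        mismatches = ((arr[i] != arr[i + 1 :]) & ok).sum(axis=1)
        for off, (m, L) in enumerate(zip(mismatches, compared)):
            j = i + 1 + off
            if L == 0:
                raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            p = m / L
            if p >= 0.75:
                raise SaturationError(
                    f"pair ({ids[i]!r}, {ids[j]!r}) beyond Jukes–Cantor saturation (p={p:.3f})"
                )
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(D, ids=ids)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0."""
    if not np.all(np.isfinite(distances.data)):
        raise ValueError("non-finite distance entries")
    if len(distances.ids) < 3:
        raise ValueError("need at least 3 taxa")
    tree = _skbio_nj(distances)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.info("clamping negative branch length %.4g to 0", node.length)
            node.length = 0.0
    return tree


def _bipartitions(tree: TreeNode, leaves: frozenset[str]) -> set[frozenset[str]]:
    """Canonical internal bipartitions: the lexicographically smaller side."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return parts


def bootstrap_support(
    alignment: CodonAlignment,
    reps: int = 500,
    seed: int | np.random.Generator | None = None,
) -> TreeNode:
    """NJ tree with column-bootstrap support on internal branches.

    Support is the percentage of replicate trees (column resampling with
    replacement, distance + NJ rebuilt each time) containing each internal
    bipartition of the point-estimate tree.  Replicates hitting distance
    saturation are dropped; the effective replicate count is stored on the
    tree as ``effective_reps``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = nj_tree(jc_distance_matrix(alignment))
    leaves = frozenset(alignment.ids)
    counts: dict[frozenset[str], int] = {}
    effective = 0
    L = alignment.length
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        resampled = CodonAlignment(
            tuple((i, "".join(s[c] for c in cols)) for i, s in alignment.records),
            frame_offset=alignment.frame_offset,
            outgroup_id=alignment.outgroup_id,
        )
        try:
            rep_tree = nj_tree(jc_distance_matrix(resampled))
        except (SaturationError, ValueError):
            logger.warning("bootstrap replicate dropped (saturation)")
            continue
        effective += 1
        for part in _bipartitions(rep_tree, leaves):
            counts[part] = counts.get(part, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = 100.0 * counts.get(canon, 0) / effective if effective else 0.0
    tree.effective_reps = effective
    return tree


def collapse_low_support(tree: TreeNode, threshold: float = 70.0) -> TreeNode:
    """Contract internal branches with support below ``threshold`` into
    multifurcations; the leaf set is unchanged."""
    tree = tree.copy()
    to_collapse = [
        node
        for node in tree.non_tips(include_self=False)
        if getattr(node, "support", None) is not None and node.support < threshold
    ]
    for node in to_collapse:
        parent = node.parent
        parent.extend(node.children)
        parent.remove(node)
    return tree


def to_newick(tree: TreeNode) -> str:
    """Serialize with bootstrap supports as internal-node labels."""
    tree = tree.copy()
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = str(int(round(support)))
    return str(tree)
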