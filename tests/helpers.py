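"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in the most direct way possible
(explicit loops, enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

MISSING = {"N", "-"}


# ---------------------------------------------------------------------------
# diversity oracle


def brute_diversity(seqs: list[str]) -> dict:
    """All-pairs, all-columns recomputation of the diversity summary."""
    n = len(seqs)
    L_full = len(seqs[0])
    cols = [
        j for j in range(L_full) if all(s[j] not in MISSING for s in seqs)
    ]
    L = len(cols)
    S = 0
    eta = 0
    for j in cols:
        alleles = set(s[j] for s in seqs)
        if len(alleles) > 1:
            S += 1
            eta += len(alleles) - 1
    total = 0
    for a, b in itertools.combinations(range(n), 2):
        total += sum(1 for j in cols if seqs[a][j] != seqs[b][j])
    pairs = n * (n - 1) // 2
    k_hat = total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    haps = Counter("".join(s[j] for j in cols) for s in seqs)
    freqs = [c / n for c in haps.values()]
    hhe = (n / (n - 1)) * (1.0 - sum(f * f for f in freqs))
    return {
        "L": L,
        "S": S,
        "eta": eta,
        "k_hat": k_hat,
        "pi": k_hat / L if L else float("nan"),
        "theta_w": S / a1,
        "k_haps": len(haps),
        "HHe": hhe,
    }


# ---------------------------------------------------------------------------
# Fisher exact oracle (two-sided, by hypergeometric enumeration)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by direct enumeration."""

    def log_choose(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    row1, row2 = a + b, c + d
    col1 = a + c
    total = a + b + c + d

    def log_p(x):
        return (
            log_choose(row1, x)
            + log_choose(row2, col1 - x)
            - log_choose(total, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = log_p(a)
    return sum(
        math.exp(log_p(x)) for x in range(lo, hi + 1) if log_p(x) <= p_obs + 1e-9
    )


# ---------------------------------------------------------------------------
# Ewens sampling formula oracle (partition enumeration)


def partitions(n: int, max_part: int | None = None):
    """All integer partitions of n (non-increasing)."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in partitions(n - first, first):
            yield (first,) + rest


def ewens_partition_prob(part: tuple[int, ...], theta: float) -> float:
    """Ewens sampling formula probability of one allelic configuration."""
    n = sum(part)
    k = len(part)
    mult = Counter(part)
    num = math.factorial(n) * theta**k
    den = 1.0
    for size, a in mult.items():
        den *= size**a * math.factorial(a)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    return num / (den * rising)


def ewens_k_pmf(n: int, theta: float) -> dict[int, float]:
    """P(K = k) by summing the Ewens formula over all partitions."""
    pmf: dict[int, float] = {}
    for part in partitions(n):
        pmf[len(part)] = pmf.get(len(part), 0.0) + ewens_partition_prob(part, theta)
    return pmf


# ---------------------------------------------------------------------------
# additive trees for the NJ oracle


def random_additive_tree(n_taxa: int, rng) -> tuple[dict, list[str]]:
    """Random binary tree with branch lengths in [0.05, 1.0].

    Returns (edges adjacency {node: [(node, length)]}, leaf names).
    """
    leaves = [f"t{i}" for i in range(n_taxa)]
    nodes = list(leaves)
    adj: dict[str, list[tuple[str, float]]] = {x: [] for x in nodes}
    next_internal = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = f"i{next_internal}"
        next_internal += 1
        adj[new] = []
        for child in (a, b):
            w = 0.05 + 0.95 * rng.random()
            adj[new].append((child, w))
            adj[child].append((new, w))
        nodes = [x for x in nodes if x not in (a, b)] + [new]
    w = 0.05 + 0.95 * rng.random()
    a, b = nodes
    adj[a].append((b, w))
    adj[b].append((a, w))
    return adj, leaves


def tree_distances(adj: dict, leaves: list[str]) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths by BFS."""
    out = {}
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in leaves:
            out[(src, dst)] = dist[dst]
    # enforce exact symmetry (path sums can differ by rounding error)
    for a in leaves:
        for b in leaves:
            if a < b:
                d = out[(a, b)]
                out[(b, a)] = d
    return out


def tree_bipartitions(adj: dict, leaves: list[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted tree, canonical smaller side."""
    leafset = frozenset(leaves)
    parts = set()
    seen = set()
    for x in adj:
        for y, _ in adj[x]:
            if (y, x) in seen:
                continue
            seen.add((x, y))
            # leaves on the y-side of edge (x, y)
            side = set()
            stack = [y]
            visited = {x, y}
            while stack:
                z = stack.pop()
                if z in leafset:
                    side.add(z)
                for w, _ in adj[z]:
                    if w not in visited:
                        visited.add(w)
                        stack.append(w)
            side = frozenset(side)
            other = leafset - side
            if len(side) < 2 or len(other) < 2:
                continue
            parts.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return parts


def newick_bipartitions(tree, leaves: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits of an skbio TreeNode, canonical smaller side."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        parts.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return parts


# ---------------------------------------------------------------------------
# exhaustive global alignment with free end gaps (affine)


def brute_global_score(
    a: str, b: str, subst, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Best score over every global alignment, scored independently.

    An internal gap run of length k costs ``gap_open + (k - 1) * gap_extend``;
    runs touching either end of the alignment are free.  Only feasible for
    short sequences (all monotone alignments are enumerated).
    """

    def score(ga: str, gb: str) -> float:
        L = len(ga)

        def free_bounds(row: str) -> tuple[int, int]:
            # gap characters of this row before `lead` or at/after `trail`
            # are end gaps of the corresponding sequence and cost nothing
            lead = 0
            while lead < L and row[lead] == "-":
                lead += 1
            trail = L
            while trail > lead and row[trail - 1] == "-":
                trail -= 1
            return lead, trail

        lead_a, trail_a = free_bounds(ga)
        lead_b, trail_b = free_bounds(gb)
        total = 0.0
        in_gap_a = in_gap_b = False
        for idx in range(L):
            x, y = ga[idx], gb[idx]
            if x == "-":
                if lead_a <= idx < trail_a:
                    total -= gap_extend if in_gap_a else gap_open
                in_gap_a, in_gap_b = True, False
            elif y == "-":
                if lead_b <= idx < trail_b:
                    total -= gap_extend if in_gap_b else gap_open
                in_gap_b, in_gap_a = True, False
            else:
                total += float(subst[x, y])
                in_gap_a = in_gap_b = False
        return total

    best = -math.inf

    def rec(i: int, j: int, ga: list, gb: list):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score("".join(ga), "".join(gb)))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + [a[i]], gb + [b[j]])
        if i < len(a):
            rec(i + 1, j, ga + [a[i]], gb + ["-"])
        if j < len(b):
            rec(i, j + 1, ga + ["-"], gb + [b[j]])

    rec(0, 0, [], [])
    return best


# ---------------------------------------------------------------------------
# random alignment instances


def random_nucleotide_records(
    rng, n: int, L: int, missing_rate: float = 0.05, polymorphic_rate: float = 0.3
) -> list[tuple[str, str]]:
    """Random aligned records with shared variable columns and missing data."""
    bases = "ACGT"
    backbone = [bases[rng.integers(4)] for _ in range(L)]
    seqs = [backbone.copy() for _ in range(n)]
    for j in range(L):
        if rng.random() < polymorphic_rate:
            alt = bases[rng.integers(4)]
            for i in range(n):
                if rng.random() < 0.4:
                    seqs[i][j] = alt
    for i in range(n):
        for j in range(L):
            if rng.random() < missing_rate:
                seqs[i][j] = "N" if rng.random() < 0.5 else "-"
    return [(f"s{i}", "".join(s)) for i, s in enumerate(seqs)]
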