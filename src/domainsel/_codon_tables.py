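"""Genetic-code helpers and Nei–Gojobori codon lookup tables.

The standard genetic code is taken from Biopython.  Site counts follow the
classic convention: single-base changes that create a stop codon count as
non-synonymous sites in the denominator, while mutational pathways passing
through a stop codon are excluded from difference averaging.  The modified
variant weights the possible changes at each codon position by the
transition/transversion ratio ``R`` (``R = 1`` reproduces the classic equal
weighting).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODONS = ["".join(p) for p in product(BASES, repeat=3)]
STOPS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOPS]
AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def is_stop(codon: str) -> bool:
    return codon in STOPS


def codon_sites(codon: str, R: float = 1.0) -> tuple[float, float]:
    """Potential (synonymous, non-synonymous) sites of one codon.

    At each of the three positions, the possible single-base changes are
    weighted ``R`` for transitions and 1 for transversions; the synonymous
    site contribution is the weighted fraction of changes that preserve the
    amino acid.  Changes into stop codons are kept in the denominator and
    count as non-synonymous.  The two contributions sum to exactly 3.
    """
    if codon in STOPS:
        raise ValueError(f"stop codon {codon}")
    syn = 0.0
    for pos in range(3):
        w_total = 0.0
        w_syn = 0.0
        for b in BASES:
            if b == codon[pos]:
                continue
            w = R if is_transition(codon[pos], b) else 1.0
            w_total += w
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in STOPS and AA[mutant] == AA[codon]:
                w_syn += w
        syn += w_syn / w_total
    return syn, 3.0 - syn


def pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed (synonymous, non-synonymous) differences between two codons.

    Averaged over all orderings of the single-base changes separating the
    codons; orderings passing through a stop codon are excluded.  If every
    ordering is blocked by a stop, all orderings are used (classifying steps
    into/out of stops as non-synonymous) so that the totals stay defined.
    The two counts always sum to the nucleotide difference count.
    """
    if codon_a in STOPS or codon_b in STOPS:
        raise ValueError("stop codon input")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOPS and not allow_stops:
                return None
            if nxt in STOPS or cur in STOPS:
                nd += 1.0
            elif AA[nxt] == AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [p for p in (walk(o, False) for o in permutations(diff_pos)) if p is not None]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff_pos)]
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


@lru_cache(maxsize=8)
def ng_lookup(R: float = 1.0):
    """Vectorizable 64-codon lookup tables for Nei–Gojobori counting.

    Returns ``(codon_index, SS, NS, SD, ND, valid)`` where ``codon_index``
    maps a codon string to 0..63, ``SS``/``NS`` are per-codon potential
    synonymous / non-synonymous sites (nan for stops), ``SD``/``ND`` are
    64x64 pathway-averaged difference counts (nan where either codon is a
    stop) and ``valid`` marks sense codons.
    """
    index = {c: i for i, c in enumerate(CODONS)}
    SS = np.full(64, np.nan)
    NS = np.full(64, np.nan)
    valid = np.zeros(64, dtype=bool)
    for c in SENSE_CODONS:
        s, ns = codon_sites(c, R)
        SS[index[c]], NS[index[c]] = s, ns
        valid[index[c]] = True
    SD = np.full((64, 64), np.nan)
    ND = np.full((64, 64), np.nan)
    for a in SENSE_CODONS:
        for b in SENSE_CODONS:
            sd, nd = pathway_diffs(a, b)
            SD[index[a], index[b]] = sd
            ND[index[a], index[b]] = nd
    return index, SS, NS, SD, ND, valid


def codon_indices(seq: str, frame_offset: int = 0) -> np.ndarray:
    """Map a nucleotide string to codon indices (0..63); -1 marks codons that
    contain a gap/N or encode a stop."""
    index, _, _, _, _, valid = ng_lookup(1.0)
    n_codons = (len(seq) - frame_offset) // 3
    out = np.full(n_codons, -1, dtype=np.int64)
    for j in range(n_codons):
        codon = seq[frame_offset + 3 * j : frame_offset + 3 * j + 3]
        i = index.get(codon, -1)
        if i >= 0 and valid[i]:
            out[j] = i
    return out
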