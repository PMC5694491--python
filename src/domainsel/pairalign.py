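"""Global protein alignment with EMBOSS-needle conventions.

Affine-gap Needleman–Wunsch with end gaps unpenalized, BLOSUM62 scoring and
the needle defaults (gap open 10, gap extend 0.5).  Identity is the fraction
of identical columns over the full alignment length (gap columns included in
the denominator); similarity additionally counts columns whose substitution
score is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ")


@dataclass(frozen=True)
class GlobalAlignment:
    """A pairwise global alignment and its summary percentages."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gap position costs the opening penalty, each further one the extension
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 spells these differently
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> GlobalAlignment:
    """Globally align two protein sequences and report identity/similarity.

    End gaps are free (EMBOSS needle default).  Among co-optimal alignments
    the first in Biopython's deterministic traceback order is reported; the
    score is unique.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    for name, s in (("a", a), ("b", b)):
        bad = set(s) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} contains non-amino-acid characters {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    subst = aligner.substitution_matrix
    length = len(ga)
    ident = sim = gaps = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            ident += 1
            sim += 1
        elif subst[x, y] > 0:
            sim += 1
    return GlobalAlignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity_pct=100.0 * ident / length,
        similarity_pct=100.0 * sim / length,
        gaps_pct=100.0 * gaps / length,
    )


def round_half_up(x: float, digits: int = 1) -> float:
    """Round with ties away from zero, as alignment reports conventionally do."""
    import decimal

    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def pairwise_percent_matrix(
    records: list[tuple[str, str]], **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-against-all identity and similarity matrices (percent, one decimal)."""
    ids = [i for i, _ in records]
    seqs = dict(records)
    ident = pd.DataFrame(100.0, index=ids, columns=ids)
    sim = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            aln = needleman_wunsch(seqs[id_a], seqs[id_b], **kwargs)
            ident.loc[id_a, id_b] = ident.loc[id_b, id_a] = round_half_up(aln.identity_pct)
            sim.loc[id_a, id_b] = sim.loc[id_b, id_a] = round_half_up(aln.similarity_pct)
    return ident, sim


def emboss_pair_format(a_id: str, b_id: str, aln: GlobalAlignment) -> str:
    """A minimal EMBOSS-style pair report."""
    lines = [
        "########################################",
        f"# Aligned_sequences: 2",
        f"# 1: {a_id}",
        f"# 2: {b_id}",
        f"# Length: {aln.length}",
        f"# Identity: {aln.identity_pct:.1f}%",
        f"# Similarity: {aln.similarity_pct:.1f}%",
        f"# Gaps: {aln.gaps_pct:.1f}%",
        f"# Score: {aln.score:.1f}",
        "########################################",
    ]
    width = 60
    for start in range(0, aln.length, width):
        lines.append(f"{a_id[:13]:13} {aln.aligned_a[start:start + width]}")
        lines.append(f"{b_id[:13]:13} {aln.aligned_b[start:start + width]}")
        lines.append("")
    return "\n".join(lines)
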