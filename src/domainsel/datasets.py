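"""Published reference inputs for the pea/Medicago LysM-RLK first exons.

Two kinds of small tabulated inputs ship with the package:

* the amino-acid haplotype survey of the three pea LysM-RLK receptor domains
  (PsK1, PsSym37, PsLykX): for each gene, the polymorphic residue positions
  and the residue vector of every reported haplotype row, including the two
  rows that are identical at every tabulated position (a published collision
  that collapsing reproduces);
* the exon subregion maps (signal-peptide/upstream part, the three LysM
  modules and the two intermediate parts) for the six genes, as consecutive
  1-based intervals.

Ambiguity tokens such as ``"V/I"`` mark rows segregating at that position;
fixture building keeps the first residue.  Extra per-row substitutions
annotated outside the tabulated columns are stored separately and not
applied by default.
"""

from __future__ import annotations

from .alignments import Region, RegionMap
from .coalsim import make_haplotype_fixture

#: polymorphic residue positions (1-based) per gene
HAPLOTYPE_POSITIONS: dict[str, tuple[int, ...]] = {
    "PsK1": (13, 31, 38, 45, 46, 48, 49, 50, 55, 61, 65, 81, 90, 104, 105, 124, 181),
    "PsSym37": (43, 45, 56, 60, 83, 131, 141, 181, 184, 205),
    "PsLykX": (9, 13, 16, 18, 23, 42, 44, 45, 75, 76, 82, 86, 111, 134, 142, 184),
}

#: haplotype rows: label -> residue tokens (one per position above)
HAPLOTYPE_ROWS: dict[str, dict[str, tuple[str, ...]]] = {
    "PsK1": {
        "A1": tuple("F L V P T K N Y I D S F E T T S N".split()),
        "A2": tuple("F L I A T K N Y I D S F D T T T N".split()),
        "A3": tuple("F L V P T K N Y I D S F E T A T I".split()),
        "A4": ("F", "L", "V/I", "P", "T", "K", "N/S", "Y", "I", "N", "S", "F/S", "E", "I", "T", "S/T", "N"),
        "A5": tuple("F L V P T K N Y I D R F D T T S N".split()),
        "B1": tuple("L I V S N T T F L D R F E T T S N".split()),
        "B2": tuple("L I V S N T T F L D R F E T T S N".split()),
        "K1 005": tuple("F I I A T K S Y I D S F E T T T I".split()),
        "K1 019": tuple("F I V S N T T F I D R F E T T T K".split()),
        "K1 074": tuple("F L V P T K N Y I D S F E T T T N".split()),
        "K1 085": tuple("L I V S N T T F L D R F E T A S N".split()),
        "K1 1238": tuple("L I V S N T T F L D R F E T T T N".split()),
        "K1 2150": tuple("F L V P T K N Y I D S S E T T T N".split()),
    },
    "PsSym37": {
        "A0": tuple("E S L S I F A S K I".split()),
        "A1": tuple("E L V S I F A S K I".split()),
        "A2": tuple("E S L S I F A S K I".split()),
        "B0": ("Q", "S", "V", "F", "V", "Y", "V/A", "R", "K", "V"),
        "B1": tuple("Q S V F V Y V R N V".split()),
        "Sym37 005": tuple("Q S V S I F A R K V".split()),
    },
    "PsLykX": {
        "A": tuple("L L V F K L Q N R A F V T S A F".split()),
        "B": tuple("F V V F K K Q N R A F I T S I S".split()),
        "C": tuple("L L F S K K Q N R A S I S S I S".split()),
        "D": tuple("L V F F K K Q N R A F I T G A S".split()),
        "E": tuple("L L F S K K Q N R A S I S S A S".split()),
        "F": tuple("L L V F K K R Y R D F V T S I S".split()),
        "LykX 039": tuple("L L V F K K Q N P A F I T S A S".split()),
        "LykX 063": tuple("L L F S Q K Q N R A S I T S A S".split()),
        "LykX 074": tuple("L V F S K K Q N R A S I T S I S".split()),
        "LykX 082": tuple("L L F S Q K Q N R A S I T G A S".split()),
        "LykX 085": tuple("L L V F K K Q N P A F I T S I S".split()),
        "LykX 089": tuple("L L F S K K Q N R A S I S S I S".split()),
        "LykX 093": tuple("L L V F K L Q S R A F I T S A S".split()),
    },
}

#: additional substitutions reported for single rows outside the tabulated
#: columns (position, reference residue, variant residue); not applied by
#: default fixture building
HAPLOTYPE_EXTRAS: dict[str, dict[str, tuple[tuple[int, str, str], ...]]] = {
    "PsK1": {"K1 1238": ((158, "Q", "R"), (172, "S", "F"))},
    "PsSym37": {"Sym37 005": ((26, "V", "L"),)},
    "PsLykX": {
        "LykX 039": ((128, "V", "F"),),
        "LykX 074": ((135, "H", "D"),),
        "LykX 082": ((191, "I", "M"),),
        "LykX 093": ((5, "F", "L"), (183, "A", "T")),
    },
}

#: receptor-domain protein length per gene (first-exon codons)
PROTEIN_LENGTHS = {"PsK1": 211, "PsSym37": 211, "PsLykX": 212}

#: exon subregion lengths (bp), in order along the exon
REGION_LENGTHS: dict[str, tuple[int, ...]] = {
    "PsK1": (105, 159, 42, 141, 54, 126),
    "PsSym37": (105, 159, 42, 141, 54, 126),
    "PsLykX": (105, 165, 42, 141, 54, 126),
    "MtLYK2": (105, 165, 42, 141, 54, 126),
    "MtLYK3": (105, 162, 42, 141, 54, 126),
    "MtLYK4": (105, 162, 42, 141, 54, 126),
}

REGION_NAMES = ("Upstream LysM1", "LysM1", "Int. LysM1-2", "LysM2", "Int. LysM2-3", "LysM3")

#: first-exon alignment length (bp) per gene
EXON_LENGTHS = {
    "PsK1": 633, "PsSym37": 633, "PsLykX": 636,
    "MtLYK2": 639, "MtLYK3": 636, "MtLYK4": 639,
}


def standard_region_map(gene: str) -> RegionMap:
    """The gene's exon subregion map as consecutive 1-based intervals.

    The regions start at position 1 and may leave trailing exon bases that
    belong to the Overall analysis only.
    """
    lengths = REGION_LENGTHS[gene]
    regions = []
    start = 1
    for name, L in zip(REGION_NAMES, lengths):
        regions.append(Region(name=name, start=start, end=start + L - 1))
        start += L
    return RegionMap(gene=gene, regions=tuple(regions))


def haplotype_fixture(gene: str, counts: dict[str, int] | None = None):
    """Protein alignment built from the gene's published haplotype rows.

    Returns ``(records, truth)`` from
    :func:`domainsel.coalsim.make_haplotype_fixture`; each row is replicated
    ``counts[label]`` times (default 1).
    """
    positions = list(HAPLOTYPE_POSITIONS[gene])
    rows = HAPLOTYPE_ROWS[gene]
    counts = counts or {}
    groups = [(label, list(res), counts.get(label, 1)) for label, res in rows.items()]
    return make_haplotype_fixture(
        groups, positions, backbone_length=PROTEIN_LENGTHS[gene]
    )
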