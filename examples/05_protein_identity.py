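"""Global protein alignment with identity/similarity percentages.

Needleman–Wunsch with the classic defaults (BLOSUM62, gap open 10, extend
0.5, end gaps free). Percentages are over the full alignment length;
similarity counts positive-scoring substitutions.
"""

from domainsel import needleman_wunsch
from domainsel.datasets import haplotype_fixture

# two receptor-domain protein sequences from the bundled haplotype fixtures
# (record ids carry a per-copy suffix, e.g. "A1_1")
a = dict(haplotype_fixture("PsK1")[0])["A1_1"]
b = dict(haplotype_fixture("PsSym37")[0])["A1_1"]

result = needleman_wunsch(a, b)
print(f"score      {result.score:.1f}")
print(f"identity   {result.identity_pct:.1f}%")
print(f"similarity {result.similarity_pct:.1f}%")
print(result.aligned_a[:60])
print(result.aligned_b[:60])
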