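"""Collapse amino-acid haplotypes and build a bootstrapped NJ tree.

Part 1 collapses the bundled PsK1 receptor-domain haplotype rows: the 13
published rows fall into 12 groups over 17 polymorphic residue positions
(two rows are identical at every tabulated position).

Part 2 builds a neighbor-joining tree with column-bootstrap support from a
simulated nucleotide alignment and contracts branches below 70% support.
"""

from domainsel import bootstrap_support, collapse_aa_haplotypes, collapse_low_support
from domainsel.coalsim import ScenarioConfig, simulate
from domainsel.datasets import haplotype_fixture
from domainsel.phylo import to_newick

# --- Part 1: published haplotype table structure
records, _truth = haplotype_fixture("PsK1")
table = collapse_aa_haplotypes(records)
print(f"PsK1: {table.n_groups} groups over {table.n_polymorphic_positions} positions")
for g in table.groups:
    print(f"  {g.label:4s} size={g.size}  members={', '.join(g.member_ids)}")

# --- Part 2: NJ tree with bootstrap support
aln = simulate(ScenarioConfig(scenario="balanced_split", n=12, theta=12.0, L=633, seed=3))
tree = bootstrap_support(aln, reps=200, seed=3)
print("\nNJ tree (supports as internal labels):")
print(to_newick(tree))
print("after contracting branches with <70% support:")
print(to_newick(collapse_low_support(tree, threshold=70.0)))
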