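"""Neutral and scenario coalescent simulation with codon-aware mutations.

The generator produces codon alignments of the kind analyzed by the pipeline:
samples of n sequences, a few hundred base pairs of protein-coding exon, an
infinite-sites mutation model, and an emitted diverged outgroup for
polarization.  Time is measured in standard coalescent units (2N generations);
``theta`` is the population mutation rate per locus.

Four genealogy scenarios are supported:

``neutral``
    constant population size, exponential waiting times with rate k(k-1)/2;
``expansion``
    exponential growth (looking back, the population shrinks at
    ``growth_rate``), which compresses deep coalescences and yields an excess
    of rare variants (negative Tajima's D, strongly negative Fu's Fs);
``balanced_split``
    two demes of equal size, sampled evenly, that merge ``split_time``
    coalescent units in the past; the deep split (default 5 coalescent units,
    i.e. several times the neutral expected TMRCA, representing a
    long-maintained balanced polymorphism) keeps two allele classes at
    intermediate frequency (positive Tajima's D), mimicking balancing
    selection;
``star_sweep``
    a recent sweep: all but ``sweep_escape`` lineages coalesce simultaneously
    ``sweep_age`` units ago, and the survivors coalesce neutrally further
    back.  Mutations on the deep branch subtending the swept cluster
    segregate at high derived frequency, producing the negative Fay & Wu's H
    signature of hitchhiking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codon_tables import AA, SENSE_CODONS, STOPS
from .alignments import CodonAlignment
from .diversity import SiteFrequencySpectrum, harmonic

BASES = "ACGT"


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic dataset.

    Exactly one of ``theta`` (population mutation rate per locus) or
    ``fixed_S`` (exact number of segregating mutations) must be set.
    ``syn_fraction`` is the target fraction of mutations placed at positions
    where a synonymous change is possible.  ``outgroup_divergence`` is the
    expected number of substitutions per site separating the emitted outgroup
    from the ancestral sequence (0 gives a perfectly informative outgroup).
    """

    scenario: str = "neutral"
    n: int = 90
    theta: float | None = 10.0
    fixed_S: int | None = None
    L: int = 633
    growth_rate: float = 50.0
    split_time: float = 5.0
    sweep_age: float = 0.05
    sweep_escape: int = 1
    syn_fraction: float = 0.75
    outgroup_divergence: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in {"neutral", "expansion", "balanced_split", "star_sweep"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.theta is None) == (self.fixed_S is None):
            raise ValueError("set exactly one of theta / fixed_S")
        if self.n < 2 or self.L < 1:
            raise ValueError("n must be >= 2 and L >= 1")
        if not 0.0 <= self.syn_fraction <= 1.0:
            raise ValueError("syn_fraction must lie in [0, 1]")


@dataclass
class GenealogySample:
    """A sampled genealogy: branches with descendant-leaf bitmasks and lengths."""

    n: int
    masks: list[int]
    lengths: list[float]
    tmrca: float
    mutation_branches: list[int] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))

    def derived_counts(self) -> list[int]:
        """Number of ingroup carriers of each mutation's derived allele."""
        return [bin(self.masks[b]).count("1") for b in self.mutation_branches]

    def haplotype_counts(self) -> list[int]:
        """Sizes of the leaf equivalence classes under the placed mutations."""
        keys = [0] * self.n
        for j, b in enumerate(self.mutation_branches):
            mask = self.masks[b]
            while mask:
                low = mask & -mask
                keys[low.bit_length() - 1] |= 1 << j
                mask ^= low
        from collections import Counter

        return sorted(Counter(keys).values(), reverse=True)


def _merge(lineages: list[tuple[int, float]], i: int, j: int, t: float, masks, lengths):
    """Coalesce lineages i and j at time t, recording their finished branches."""
    (m1, b1), (m2, b2) = lineages[i], lineages[j]
    masks.append(m1)
    lengths.append(t - b1)
    masks.append(m2)
    lengths.append(t - b2)
    merged = (m1 | m2, t)
    hi, lo = max(i, j), min(i, j)
    lineages.pop(hi)
    lineages.pop(lo)
    lineages.append(merged)


def sample_genealogy(config: ScenarioConfig, rng: np.random.Generator) -> GenealogySample:
    """Draw one genealogy under the configured scenario."""
    n = config.n
    lineages: list[tuple[int, float]] = [(1 << i, 0.0) for i in range(n)]
    masks: list[int] = []
    lengths: list[float] = []
    t = 0.0

    def neutral_from(t: float) -> float:
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            _merge(lineages, int(i), int(j), t, masks, lengths)
        return t

    if config.scenario == "neutral":
        t = neutral_from(0.0)

    elif config.scenario == "expansion":
        g = config.growth_rate
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0
            # inverse-hazard sampling with backward-in-time shrinking population
            e = rng.exponential(1.0)
            t = np.logaddexp(g * t, np.log(g * e / rate)) / g
            i, j = rng.choice(k, size=2, replace=False)
            _merge(lineages, int(i), int(j), t, masks, lengths)

    elif config.scenario == "balanced_split":
        half = n // 2
        demes = [list(range(half)), list(range(half, n))]
        while True:
            rates = [len(d) * (len(d) - 1) / 2.0 for d in demes]
            total = sum(rates)
            if total == 0.0:
                t = config.split_time
                break
            t_next = t + rng.exponential(1.0 / total)
            if t_next >= config.split_time:
                t = config.split_time
                break
            t = t_next
            d = 0 if rng.random() < rates[0] / total else 1
            i_loc, j_loc = rng.choice(len(demes[d]), size=2, replace=False)
            i, j = demes[d][int(i_loc)], demes[d][int(j_loc)]
            _merge(lineages, max(i, j), min(i, j), t, masks, lengths)
            # rebuild deme index lists over the shrunk lineage list
            removed = sorted((i, j))
            for dd in range(2):
                demes[dd] = [x for x in demes[dd] if x not in removed]
                demes[dd] = [x - sum(1 for r in removed if r < x) for x in demes[dd]]
            demes[d].append(len(lineages) - 1)
        t = neutral_from(t)

    elif config.scenario == "star_sweep":
        t = config.sweep_age
        m = max(0, min(config.sweep_escape, n - 2))
        order = rng.permutation(n)
        swept = list(order[: n - m])
        # zero-duration pairwise merges emulate the simultaneous star join
        while len(swept) > 1:
            i, j = sorted(swept[-2:])
            _merge(lineages, j, i, t, masks, lengths)
            swept = [x if x < i else (x - 1 if x < j else x - 2) for x in swept[:-2]]
            swept.append(len(lineages) - 1)
        t = neutral_from(t)

    return GenealogySample(n=n, masks=masks, lengths=lengths, tmrca=t)


def place_mutations(
    gen: GenealogySample, config: ScenarioConfig, rng: np.random.Generator
) -> GenealogySample:
    """Assign mutations to branches (Poisson at theta/2, or exactly fixed_S)."""
    total = gen.total_length
    if config.fixed_S is not None:
        n_mut = config.fixed_S
    else:
        n_mut = int(rng.poisson(config.theta / 2.0 * total))
    if total == 0.0 or n_mut == 0:
        gen.mutation_branches = []
        return gen
    probs = np.asarray(gen.lengths) / total
    counts = rng.multinomial(n_mut, probs)
    branches: list[int] = []
    for b, c in enumerate(counts):
        branches.extend([b] * int(c))
    gen.mutation_branches = branches
    return gen


# ---------------------------------------------------------------------------
# sequence emission


def _random_backbone(L: int, rng: np.random.Generator) -> str:
    n_codons, rem = divmod(L, 3)
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    seq = "".join(SENSE_CODONS[i] for i in codons)
    seq += "".join(rng.choice(list(BASES)) for _ in range(rem))
    return seq


def _site_classes(backbone: str) -> tuple[list[int], list[int], dict[int, list[str]]]:
    """Split sites into synonymous-capable and the rest; list usable alt bases.

    A site is synonymous-capable when at least one alternative base preserves
    the amino acid of the backbone codon.  For such sites the listed
    alternatives are the synonymous ones; for the remaining (coding) sites
    they are the non-synonymous, non-stop alternatives.  Trailing bases
    outside a complete codon go to the non-synonymous pool with any
    alternative allowed.
    """
    syn_pool: list[int] = []
    nonsyn_pool: list[int] = []
    alts: dict[int, list[str]] = {}
    n_codons = len(backbone) // 3
    for j in range(len(backbone)):
        codon_idx = j // 3
        if codon_idx >= n_codons:
            nonsyn_pool.append(j)
            alts[j] = [b for b in BASES if b != backbone[j]]
            continue
        codon = backbone[3 * codon_idx : 3 * codon_idx + 3]
        pos = j % 3
        syn_alts, nonsyn_alts = [], []
        for b in BASES:
            if b == backbone[j]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOPS:
                continue
            (syn_alts if AA[mutant] == AA[codon] else nonsyn_alts).append(b)
        if syn_alts:
            syn_pool.append(j)
            alts[j] = syn_alts
        elif nonsyn_alts:
            nonsyn_pool.append(j)
            alts[j] = nonsyn_alts
    return syn_pool, nonsyn_pool, alts


def simulate_with_truth(config: ScenarioConfig) -> tuple[CodonAlignment, dict]:
    """Simulate one dataset and return it with its ground-truth sidecar.

    The alignment carries ``config.n`` ingroup sequences plus an ``outgroup``
    record derived from the ancestral sequence.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gen = place_mutations(sample_genealogy(config, rng), config, rng)
    S = len(gen.mutation_branches)

    backbone = _random_backbone(config.L, rng)
    syn_pool, nonsyn_pool, alts = _site_classes(backbone)
    syn_pool = list(rng.permutation(syn_pool)) if syn_pool else []
    nonsyn_pool = list(rng.permutation(nonsyn_pool)) if nonsyn_pool else []
    if S > len(syn_pool) + len(nonsyn_pool):
        raise ValueError(
            f"fixed_S={S} exceeds the {len(syn_pool) + len(nonsyn_pool)} mutable sites"
        )

    sites: list[int] = []
    classes: list[str] = []
    for _ in range(S):
        want_syn = rng.random() < config.syn_fraction
        pool, label = (syn_pool, "syn") if want_syn else (nonsyn_pool, "nonsyn")
        if not pool:
            pool, label = (nonsyn_pool, "nonsyn") if want_syn else (syn_pool, "syn")
        sites.append(int(pool.pop()))
        classes.append(label)

    seqs = [list(backbone) for _ in range(config.n)]
    derived_bases: list[str] = []
    for site, branch in zip(sites, gen.mutation_branches):
        alt = str(rng.choice(alts[site]))
        derived_bases.append(alt)
        mask = gen.masks[branch]
        while mask:
            low = mask & -mask
            seqs[low.bit_length() - 1][site] = alt
            mask ^= low

    out_seq = list(backbone)
    n_out = int(rng.poisson(config.outgroup_divergence * config.L))
    n_out = min(n_out, config.L)
    out_sites = rng.choice(config.L, size=n_out, replace=False) if n_out else []
    for j in out_sites:
        choices = [b for b in BASES if b != backbone[int(j)]]
        out_seq[int(j)] = str(rng.choice(choices))

    width = len(str(config.n))
    records = [(f"s{i + 1:0{width}d}", "".join(s)) for i, s in enumerate(seqs)]
    records.append(("outgroup", "".join(out_seq)))
    aln = CodonAlignment(tuple(records), frame_offset=0, outgroup_id="outgroup")
    truth = {
        "scenario": config.scenario,
        "seed": config.seed,
        "n": config.n,
        "L": config.L,
        "S": S,
        "tmrca": gen.tmrca,
        "sites": sites,
        "site_classes": classes,
        "derived_bases": derived_bases,
        "derived_counts": gen.derived_counts(),
        "outgroup_sites": [int(j) for j in out_sites],
    }
    return aln, truth


def simulate(config: ScenarioConfig) -> CodonAlignment:
    """Simulate one codon alignment (with outgroup record) under the scenario."""
    return simulate_with_truth(config)[0]


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# fast genealogy-level replicates (used for coalescent null distributions)


@dataclass(frozen=True)
class ReplicateSummary:
    """Summary statistics of one simulated replicate, without sequences."""

    n: int
    S: int
    sfs_counts: tuple[int, ...]
    eta_e: int
    k_hat: float
    k_haps: int

    @property
    def sfs(self) -> SiteFrequencySpectrum:
        return SiteFrequencySpectrum(n=self.n, counts=self.sfs_counts)


def replicate_summaries(
    config: ScenarioConfig, reps: int, rng: np.random.Generator, haplotypes: bool = False
) -> list[ReplicateSummary]:
    """Draw ``reps`` genealogy-level replicates and summarize each.

    The derived states are known exactly (the simulation is polarized by
    construction), so the summaries feed outgroup-based statistics directly.
    Haplotype counting is optional because it dominates the cost for large n.
    """
    out = []
    n = config.n
    pairs = n * (n - 1) / 2.0
    for _ in range(reps):
        gen = place_mutations(sample_genealogy(config, rng), config, rng)
        counts = [0] * (n - 1)
        eta_e = 0
        k_sum = 0.0
        for d in gen.derived_counts():
            if 0 < d < n:
                counts[d - 1] += 1
                k_sum += d * (n - d)
                if d == 1:
                    eta_e += 1
        k_haps = len(gen.haplotype_counts()) if haplotypes else 0
        out.append(
            ReplicateSummary(
                n=n,
                S=sum(counts),
                sfs_counts=tuple(counts),
                eta_e=eta_e,
                k_hat=k_sum / pairs,
                k_haps=k_haps,
            )
        )
    return out


def neutral_config_matching(n: int, mean_S: float, L: int = 633) -> ScenarioConfig:
    """Neutral configuration whose expected S matches an observed mean."""
    return ScenarioConfig(scenario="neutral", n=n, theta=mean_S / harmonic(n), L=L)


def neutral_syn_fraction() -> float:
    """``syn_fraction`` under which Nei–Gojobori dN/dS is 1 in expectation.

    The backbone draws codons uniformly from the 61 sense codons, so the
    expected fraction of Nei–Gojobori synonymous sites is the code-table
    average of per-codon synonymous potentials.  Placing that fraction of
    mutations in the synonymous class makes the expected per-site synonymous
    and non-synonymous rates equal: the selectively neutral condition for the
    codon Z-test.
    """
    from ._codon_tables import codon_sites

    total = sum(codon_sites(c, 1.0)[0] for c in SENSE_CODONS)
    return total / (3.0 * len(SENSE_CODONS))


# ---------------------------------------------------------------------------
# protein haplotype fixtures


def make_haplotype_fixture(
    groups: list[tuple[str, list[str], int]],
    positions: list[int],
    backbone_length: int | None = None,
    backbone_residue: str = "A",
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Build a protein alignment from tabulated haplotype rows.

    Each group is ``(label, residues, count)`` with one residue per entry of
    ``positions`` (1-based).  The emitted sequences are a constant backbone
    overwritten at the stated positions, replicated ``count`` times with
    unique ids.  Returns the records plus the ground-truth label → ids map.
    Ambiguity tokens like ``"V/I"`` keep their first residue.
    """
    if len({g[0] for g in groups}) != len(groups):
        raise ValueError("duplicate group labels")
    if backbone_length is None:
        backbone_length = max(positions) + 10
    records: list[tuple[str, str]] = []
    truth: dict[str, list[str]] = {}
    for label, residues, count in groups:
        if len(residues) != len(positions):
            raise ValueError(f"group {label!r}: residue vector length mismatch")
        if count < 1:
            raise ValueError(f"group {label!r}: count must be >= 1")
        seq = [backbone_residue] * backbone_length
        for pos, res in zip(positions, residues):
            seq[pos - 1] = res[0]
        ids = [f"{label}_{i + 1}" for i in range(count)]
        truth[label] = ids
        records.extend((rid, "".join(seq)) for rid in ids)
    return records, truth
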