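"""Core diversity statistics for codon alignments.

Nucleotide statistics (S, eta, k_hat, pi, Watterson's theta, haplotype counts
and diversity) use complete deletion: any column carrying a gap or ``N`` in
any ingroup sequence is excluded.  The synonymous / non-synonymous partition
(pi_s, pi_a) uses Nei–Gojobori codon counting with pairwise-complete codon
exclusion.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._codon_tables import codon_indices, codon_sites, ng_lookup, pathway_diffs
from .alignments import MISSING, CodonAlignment

logger = logging.getLogger(__name__)


def harmonic(n: int, power: int = 1) -> float:
    """``a1 = sum 1/i`` (power 1) or ``a2 = sum 1/i**2`` (power 2) for i = 1..n-1."""
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass(frozen=True)
class DiversitySummary:
    """Per-alignment (or per-region) diversity statistics.

    ``k_hat`` and ``theta_w`` are in count units (per locus); ``pi``, ``pi_s``
    and ``pi_a`` are per analyzed site.  ``pi_a_over_pi_s`` is ``None`` when
    ``pi_s`` is zero or undefined.
    """

    n: int
    L_analyzed: int
    S: int
    eta: int
    k_hat: float
    pi: float
    theta_w: float
    k_haps: int
    HHe: float
    pi_s: float | None = None
    pi_a: float | None = None

    @property
    def pi_a_over_pi_s(self) -> float | None:
        if self.pi_s is None or self.pi_a is None or self.pi_s == 0.0:
            return None
        return self.pi_a / self.pi_s


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Unfolded (derived-allele) site frequency spectrum.

    ``counts[i - 1]`` holds the number of polarized mutations observed in
    ``i`` of the ``n`` ingroup sequences, i = 1..n-1.
    """

    n: int
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != self.n - 1:
            raise ValueError("spectrum must have n-1 entries")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative spectrum entry")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def singletons(self) -> int:
        return int(self.counts[0]) if self.counts else 0

    def theta_pi(self) -> float:
        """Mean pairwise differences implied by the spectrum (count units)."""
        n = self.n
        pairs = n * (n - 1) / 2
        return sum(c * i * (n - i) for i, c in enumerate(self.counts, start=1)) / pairs

    def theta_h(self) -> float:
        """Fay & Wu's homozygosity-weighted estimator (count units)."""
        n = self.n
        return sum(2.0 * c * i * i for i, c in enumerate(self.counts, start=1)) / (n * (n - 1))

    def theta_l(self) -> float:
        """Zeng et al.'s linear-weighted estimator (count units)."""
        return sum(c * i for i, c in enumerate(self.counts, start=1)) / (self.n - 1)


def retained_columns(alignment: CodonAlignment) -> list[int]:
    """0-based indices of columns free of gaps/N in every ingroup sequence."""
    seqs = [s for _, s in alignment.ingroup()]
    return [
        j for j in range(alignment.length) if all(s[j] not in MISSING for s in seqs)
    ]


def summarize(alignment: CodonAlignment, ng_ratio: float = 1.0) -> DiversitySummary:
    """Compute the full diversity summary of an alignment.

    The outgroup (if set) is excluded.  ``pi_s``/``pi_a`` are computed when at
    least one complete codon survives the gap policy, otherwise left ``None``.
    """
    ingroup = alignment.ingroup()
    n = len(ingroup)
    if n < 2:
        raise ValueError("need at least two ingroup sequences")
    cols = retained_columns(alignment)
    L = len(cols)
    if L == 0:
        raise ValueError("no columns survive gap/missing exclusion")

    seqs = [s for _, s in ingroup]
    S = 0
    eta = 0
    for j in cols:
        alleles = {s[j] for s in seqs}
        if len(alleles) > 1:
            S += 1
            eta += len(alleles) - 1

    # mean pairwise differences over retained columns
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, -1)
    arr = arr[:, cols]
    total_diffs = 0
    for i in range(n - 1):
        total_diffs += int((arr[i + 1 :] != arr[i]).sum())
    pairs = n * (n - 1) // 2
    k_hat = total_diffs / pairs
    pi = k_hat / L
    theta_w = S / harmonic(n)

    haps = Counter("".join(s[j] for j in cols) for s in seqs)
    k_haps = len(haps)
    freqs = np.array(list(haps.values())) / n
    # clamp to [0, 1]: the unbiased factor can overshoot 1 by rounding error
    HHe = min(1.0, max(0.0, (n / (n - 1)) * (1.0 - float(np.sum(freqs**2)))))

    pi_s = pi_a = None
    if (alignment.length - alignment.frame_offset) >= 3:
        try:
            pi_s, pi_a = pi_syn_nonsyn(alignment, R=ng_ratio)
        except ValueError:
            pass
    return DiversitySummary(
        n=n, L_analyzed=L, S=S, eta=eta, k_hat=k_hat, pi=pi, theta_w=theta_w,
        k_haps=k_haps, HHe=HHe, pi_s=pi_s, pi_a=pi_a,
    )


def haplotype_counts(alignment: CodonAlignment) -> list[int]:
    """Sizes of the ingroup haplotype classes (descending), complete deletion."""
    cols = retained_columns(alignment)
    haps = Counter("".join(s[j] for j in cols) for _, s in alignment.ingroup())
    return sorted(haps.values(), reverse=True)


def sfs(alignment: CodonAlignment, outgroup_id: str | None = None) -> SiteFrequencySpectrum:
    """Polarize segregating sites against the outgroup.

    Only biallelic ingroup-polymorphic columns where the outgroup carries one
    of the two ingroup alleles contribute; columns where the outgroup is
    missing or carries a third allele are excluded (logged).
    """
    outgroup_id = outgroup_id or alignment.outgroup_id
    if outgroup_id is None:
        raise ValueError("no outgroup available for polarization")
    out_seq = alignment.sequence(outgroup_id)
    ingroup = [(i, s) for i, s in alignment.records if i != outgroup_id]
    n = len(ingroup)
    if n < 2:
        raise ValueError("need at least two ingroup sequences")
    seqs = [s for _, s in ingroup]
    counts = [0] * (n - 1)
    skipped = 0
    for j in range(alignment.length):
        column = [s[j] for s in seqs]
        if any(c in MISSING for c in column):
            continue
        alleles = sorted(set(column))
        if len(alleles) != 2:
            if len(alleles) > 2:
                skipped += 1
            continue
        anc = out_seq[j]
        if anc in MISSING or anc not in alleles:
            skipped += 1
            continue
        derived = alleles[0] if alleles[1] == anc else alleles[1]
        i = column.count(derived)
        counts[i - 1] += 1
    if skipped:
        logger.info("sfs: %d polymorphic columns not polarizable, excluded", skipped)
    return SiteFrequencySpectrum(n=n, counts=tuple(counts))


def ng_site_counts(
    codon_a: str, codon_b: str, R: float = 1.0
) -> tuple[float, float, float, float]:
    """Nei–Gojobori per-pair counts for a single codon position.

    Returns ``(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs)``.  Site
    counts are averages of the two codons' potentials (transition weight
    ``R``; ``R = 1`` is the classic equal weighting); differences are averaged
    over stop-free mutational pathways.
    """
    for c in (codon_a, codon_b):
        if len(c) != 3 or any(b not in "ACGT" for b in c):
            raise ValueError(f"invalid codon {c!r}")
    sa, na = codon_sites(codon_a, R)
    sb, nb = codon_sites(codon_b, R)
    sd, nd = pathway_diffs(codon_a, codon_b)
    return (sa + sb) / 2.0, (na + nb) / 2.0, sd, nd


def _codon_matrix(alignment: CodonAlignment) -> np.ndarray:
    """(n_records, n_codons) codon-index matrix; -1 marks unusable codons."""
    return np.stack(
        [codon_indices(s, alignment.frame_offset) for _, s in alignment.ingroup()]
    )


def pairwise_ng_arrays(alignment: CodonAlignment, R: float = 1.0):
    """Per-pair, per-codon Nei–Gojobori count arrays.

    Returns ``(SDp, NDp, SSp, NSp, mask)``, each of shape
    ``(n_pairs, n_codons)``; ``mask`` is True where both codons of the pair
    are complete sense codons (pairwise-complete exclusion elsewhere).
    Pair order is ``(0,1), (0,2), ..., (n-2, n-1)``.
    """
    _, SS, NS, SD, ND, _ = ng_lookup(R)
    M = _codon_matrix(alignment)
    n = M.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    A, B = M[ii], M[jj]
    mask = (A >= 0) & (B >= 0)
    Ac, Bc = np.where(mask, A, 0), np.where(mask, B, 0)
    SDp = np.where(mask, SD[Ac, Bc], 0.0)
    NDp = np.where(mask, ND[Ac, Bc], 0.0)
    SSp = np.where(mask, (SS[Ac] + SS[Bc]) / 2.0, 0.0)
    NSp = np.where(mask, (NS[Ac] + NS[Bc]) / 2.0, 0.0)
    return SDp, NDp, SSp, NSp, mask


def pi_syn_nonsyn(
    alignment: CodonAlignment, R: float = 1.0, jc: bool = False
) -> tuple[float | None, float]:
    """Per-site synonymous and non-synonymous diversity (pi_s, pi_a).

    For every sequence pair, synonymous/non-synonymous differences and site
    counts are summed over codons complete in both sequences; the per-pair
    proportions (optionally Jukes–Cantor corrected) are then averaged over
    all pairs.  ``pi_s`` is ``None`` when no pair has synonymous sites.
    """
    SDp, NDp, SSp, NSp, mask = pairwise_ng_arrays(alignment, R)
    if not mask.any():
        raise ValueError("no complete codon pairs available")
    sd, nd = SDp.sum(axis=1), NDp.sum(axis=1)
    ss, ns = SSp.sum(axis=1), NSp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(ss > 0, sd / np.maximum(ss, 1e-300), np.nan)
        pa = np.where(ns > 0, nd / np.maximum(ns, 1e-300), np.nan)
    if jc:
        from .codonz import jc_correct

        ps = np.array([jc_correct(p) if np.isfinite(p) else np.nan for p in ps])
        pa = np.array([jc_correct(p) if np.isfinite(p) else np.nan for p in pa])
    pi_s = float(np.nanmean(ps)) if np.isfinite(ps).any() else None
    pi_a = float(np.nanmean(pa)) if np.isfinite(pa).any() else 0.0
    return pi_s, pi_a
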