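"""Neutrality tests: Tajima's D, Fu & Li's D and F (outgroup versions),
Fu's Fs, Fay & Wu's H, normalized H, Ewens–Watterson, McDonald–Kreitman,
and coalescent-simulation significance.

Statistics follow the original publications' constants; empirical p-values
come from neutral coalescent replicates conditioned on the observed number of
segregating sites (constant population size, no recombination), with the
(r + 1)/(reps + 1) small-sample correction and a floor of 2/(reps + 1).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import fisher_exact

from .alignments import MISSING, CodonAlignment
from .coalsim import ReplicateSummary, ScenarioConfig, replicate_summaries
from .diversity import SiteFrequencySpectrum, harmonic

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass(frozen=True)
class NeutralityResult:
    """Value and significance of one neutrality statistic.

    ``value`` is ``None`` when the statistic is undefined on the input (e.g.
    no segregating sites); ``p_source`` records where the p-value came from.
    """

    statistic_name: str
    value: float | None
    p_value: float | None = None
    p_source: str | None = None
    n: int | None = None
    S_or_eta: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None and math.isfinite(self.value)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class MKTable:
    """Fixed (D) and polymorphic (P) synonymous/non-synonymous counts."""

    Dn: int
    Ds: int
    Pn: int
    Ps: int

    def __post_init__(self):
        if min(self.Dn, self.Ds, self.Pn, self.Ps) < 0:
            raise ValueError("MK counts must be non-negative")


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(n: int, S: int, k_hat: float) -> NeutralityResult:
    """Tajima's D with the original variance constants."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return NeutralityResult("TajimaD", None, n=n, S_or_eta=0)
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    d = (k_hat - S / a1) / math.sqrt(var)
    return NeutralityResult("TajimaD", d, n=n, S_or_eta=S)


# ---------------------------------------------------------------------------
# Fu & Li's D and F (outgroup versions)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    a = harmonic(n)
    b = harmonic(n, 2)
    a_np1 = a + 1.0 / n
    c = 1.0 if n == 2 else 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a**2 / (b + a**2)) * (c - (n + 1) / (n - 1))
    u_d = a - 1.0 - v_d
    v_f = (c + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a**2 + b)
    u_f = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (a_np1 - 2.0 * n / (n + 1))
    ) / a - v_f
    return u_d, v_d, u_f, v_f


def fu_li_d_f(
    n: int, eta: int, eta_e: int, k_hat: float
) -> tuple[NeutralityResult, NeutralityResult]:
    """Fu & Li's D and F using the outgroup formulations.

    ``eta`` is the total number of mutations and ``eta_e`` the number on
    external branches (derived singletons under infinite sites).
    """
    if n < 4:
        raise ValueError("Fu & Li's tests need n >= 4")
    if eta < 1:
        return (
            NeutralityResult("FuLiD", None, n=n, S_or_eta=0),
            NeutralityResult("FuLiF", None, n=n, S_or_eta=0),
        )
    a = harmonic(n)
    u_d, v_d, u_f, v_f = _fu_li_constants(n)
    d = (eta - a * eta_e) / math.sqrt(u_d * eta + v_d * eta**2)
    f = (k_hat - eta_e) / math.sqrt(u_f * eta + v_f * eta**2)
    return (
        NeutralityResult("FuLiD", d, n=n, S_or_eta=eta, extras={"eta_e": eta_e}),
        NeutralityResult("FuLiF", f, n=n, S_or_eta=eta, extras={"eta_e": eta_e}),
    )


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=16)
def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind, row n (k = 0..n)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # s(0,0) = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        if m == 1:
            new[1] = 0.0
        else:
            new[1 : m + 1] = np.logaddexp(row[0:m], math.log(m - 1) + row[1 : m + 1])
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula."""
    log_s = _log_stirling_first(n)
    ks = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = log_s + ks * math.log(theta) - log_rising
    p = np.exp(logp)
    p[0] = 0.0
    return p / p.sum()


def fus_fs(n: int, k_hat: float, k_haps: int) -> NeutralityResult:
    """Fu's Fs: log-odds of observing at least the sampled number of
    haplotypes under the Ewens formula at theta = k_hat."""
    if k_hat <= 0.0:
        return NeutralityResult("FuFs", None, n=n)
    pk = ewens_k_distribution(n, k_hat)
    # summing each tail separately keeps the log-odds accurate when one
    # tail is within rounding error of 1
    upper = float(pk[k_haps:].sum())
    lower = float(pk[:k_haps].sum())
    if upper <= 0.0 or lower <= 0.0:
        return NeutralityResult(
            "FuFs", None, n=n, extras={"S_prime": upper, "k_haps": k_haps}
        )
    fs = math.log(upper) - math.log(lower)
    return NeutralityResult("FuFs", fs, n=n, extras={"S_prime": upper, "k_haps": k_haps})


# ---------------------------------------------------------------------------
# Fay & Wu's H and its normalization


def fay_wu_h(sfs: SiteFrequencySpectrum, k_hat: float) -> NeutralityResult:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H, in count units."""
    if sfs.total == 0:
        return NeutralityResult(
            "FayWuH", 0.0, n=sfs.n, S_or_eta=0, extras={"monomorphic": True}
        )
    h = k_hat - sfs.theta_h()
    return NeutralityResult("FayWuH", h, n=sfs.n, S_or_eta=sfs.total)


def normalized_h(sfs: SiteFrequencySpectrum, S: int) -> NeutralityResult:
    """Zeng et al.'s normalized H: (theta_pi - theta_L) / sd under neutrality.

    The variance uses the Watterson moment estimators theta = S/a1 and
    theta^2 = S(S-1)/(a1^2 + a2).
    """
    n = sfs.n
    if S < 1 or sfs.total == 0:
        return NeutralityResult("nH", None, n=n, S_or_eta=S)
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b_np1 = a2 + 1.0 / n**2  # sum of 1/i^2 for i = 1..n
    theta = S / a1
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var = (
        theta * (n - 2) / (6.0 * (n - 1))
        + theta_sq
        * (18.0 * n**2 * (3.0 * n + 2.0) * b_np1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0))
        / (9.0 * n * (n - 1) ** 2)
    )
    if var <= 0.0:
        return NeutralityResult("nH", None, n=n, S_or_eta=S)
    value = (sfs.theta_pi() - sfs.theta_l()) / math.sqrt(var)
    return NeutralityResult("nH", value, n=n, S_or_eta=S)


# ---------------------------------------------------------------------------
# Ewens–Watterson


def _partitions(n: int, k: int, max_part: int | None = None):
    """Integer partitions of n into exactly k parts (non-increasing)."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for first in range(min(n - k + 1, max_part), 0, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


def ewens_conditional_exact(n: int, k: int) -> list[tuple[tuple[int, ...], float]]:
    """Exact allelic-configuration distribution given (n, k).

    Conditional on the number of haplotype classes the Ewens distribution is
    free of theta: P(partition) is proportional to the number of permutations
    of n elements with that cycle type.
    """
    configs = []
    for part in _partitions(n, k):
        mult = Counter(part)
        log_w = math.lgamma(n + 1)
        for size, a in mult.items():
            log_w -= a * math.log(size) + math.lgamma(a + 1)
        configs.append((part, log_w))
    m = max(w for _, w in configs)
    weights = [math.exp(w - m) for _, w in configs]
    total = sum(weights)
    return [(part, w / total) for (part, _), w in zip(configs, weights)]


def _watterson_moment_theta(n: int, k: int) -> float:
    """theta solving E[K] = sum theta/(theta+i) = k for the CRP null sampler."""
    if k <= 1:
        return 1e-6

    def ek(theta):
        return sum(theta / (theta + i) for i in range(n)) - k

    return float(brentq(ek, 1e-9, 1e9))


def sample_ewens_partition(
    n: int, theta: float, rng: np.random.Generator
) -> tuple[int, ...]:
    """One draw from the Ewens distribution via the Chinese restaurant process."""
    counts: list[int] = []
    total = 0
    for m in range(n):
        if rng.random() * (theta + m) < theta:
            counts.append(1)
        else:
            u = rng.random() * m
            acc = 0.0
            for idx, c in enumerate(counts):
                acc += c
                if u < acc:
                    counts[idx] += 1
                    break
        total += 1
    return tuple(sorted(counts, reverse=True))


def homozygosity(counts: list[int] | tuple[int, ...]) -> float:
    n = sum(counts)
    return float(sum((c / n) ** 2 for c in counts))


def ewens_watterson(
    hap_counts: list[int],
    reps: int = 10000,
    seed: int | np.random.Generator | None = None,
    exact_limit: int = 8,
) -> NeutralityResult:
    """Ewens–Watterson homozygosity test.

    ``F`` is the sum of squared haplotype frequencies; the null is the Ewens
    distribution conditional on (n, k), enumerated exactly for n <= 8 and
    otherwise sampled by a seeded Chinese-restaurant process (rejection on k)
    at the Watterson-moment theta.  The reported ``p_value`` is the lower
    tail P(F <= observed); the upper tail is in ``extras``.
    """
    counts = sorted(int(c) for c in hap_counts)
    n = sum(counts)
    k = len(counts)
    if n < 2:
        raise ValueError("need total count >= 2")
    F = homozygosity(counts)
    if k == 1 or k == n:
        # a single class, or all classes singletons: only one configuration
        # is compatible with (n, k), so the test carries no information
        return NeutralityResult(
            "EW", F, p_value=1.0, p_source="ewens_null", n=n,
            extras={"degenerate": True, "p_lower": 1.0, "p_upper": 1.0},
        )
    if n <= exact_limit:
        dist = ewens_conditional_exact(n, k)
        p_lower = sum(p for part, p in dist if homozygosity(part) <= F + 1e-12)
        p_upper = sum(p for part, p in dist if homozygosity(part) >= F - 1e-12)
        source = "ewens_exact"
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        theta = _watterson_moment_theta(n, k)
        lo = hi = 0
        accepted = 0
        attempts = 0
        max_attempts = reps * 1000
        while accepted < reps and attempts < max_attempts:
            attempts += 1
            part = sample_ewens_partition(n, theta, rng)
            if len(part) != k:
                continue
            accepted += 1
            f = homozygosity(part)
            if f <= F + 1e-12:
                lo += 1
            if f >= F - 1e-12:
                hi += 1
        if accepted == 0:
            raise RuntimeError("Ewens null sampler accepted no draws")
        p_lower = (lo + 1) / (accepted + 1)
        p_upper = (hi + 1) / (accepted + 1)
        source = "ewens_null"
    return NeutralityResult(
        "EW", F, p_value=min(p_lower, 1.0), p_source=source, n=n,
        extras={"p_lower": min(p_lower, 1.0), "p_upper": min(p_upper, 1.0), "k": k},
    )


# ---------------------------------------------------------------------------
# McDonald–Kreitman


def mk_test(table: MKTable) -> NeutralityResult:
    """Two-tailed Fisher exact test on the 2x2 MK table, plus the neutrality
    index NI = (Pn/Ps)/(Dn/Ds) when defined."""
    rows_ok = (table.Dn + table.Ds) > 0 and (table.Pn + table.Ps) > 0
    cols_ok = (table.Dn + table.Pn) > 0 and (table.Ds + table.Ps) > 0
    if not (rows_ok and cols_ok):
        return NeutralityResult("MK", None, extras={"table": table})
    _, p = fisher_exact([[table.Dn, table.Ds], [table.Pn, table.Ps]], alternative="two-sided")
    ni = None
    if table.Ps > 0 and table.Ds > 0 and table.Dn > 0:
        ni = (table.Pn / table.Ps) / (table.Dn / table.Ds)
    return NeutralityResult(
        "MK", ni, p_value=float(p), p_source="fisher_exact", extras={"table": table}
    )


def mk_table_from_alignment(alignment: CodonAlignment) -> MKTable:
    """Build an MK table from an alignment with an interspecies outgroup.

    Polymorphic counts classify each segregating ingroup change as synonymous
    or not in the context of the ingroup consensus codon; fixed counts do the
    same for sites monomorphic in the ingroup but different in the outgroup.
    Sites whose codon context is incomplete are skipped.
    """
    from ._codon_tables import AA, STOPS

    if alignment.outgroup_id is None:
        raise ValueError("MK table needs an outgroup")
    out_seq = alignment.sequence(alignment.outgroup_id)
    ingroup = [s for _, s in alignment.ingroup()]
    L = alignment.length
    f = alignment.frame_offset

    def consensus(j):
        col = [s[j] for s in ingroup if s[j] not in MISSING]
        return Counter(col).most_common(1)[0][0] if col else None

    def classify(j, base_a, base_b) -> str | None:
        codon_idx, pos = divmod(j - f, 3)
        if j < f or codon_idx >= (L - f) // 3:
            return None
        cols = range(f + 3 * codon_idx, f + 3 * codon_idx + 3)
        context = [consensus(c) for c in cols]
        if any(c is None or c in MISSING for c in context):
            return None
        ca = context.copy()
        ca[pos] = base_a
        cb = context.copy()
        cb[pos] = base_b
        ca, cb = "".join(ca), "".join(cb)
        if ca in STOPS or cb in STOPS:
            return None
        return "syn" if AA[ca] == AA[cb] else "nonsyn"

    Pn = Ps = Dn = Ds = 0
    for j in range(L):
        col = [s[j] for s in ingroup]
        if any(c in MISSING for c in col) or out_seq[j] in MISSING:
            continue
        alleles = sorted(set(col))
        if len(alleles) == 2:
            cls = classify(j, alleles[0], alleles[1])
            if cls == "syn":
                Ps += 1
            elif cls == "nonsyn":
                Pn += 1
        elif len(alleles) == 1 and alleles[0] != out_seq[j]:
            cls = classify(j, alleles[0], out_seq[j])
            if cls == "syn":
                Ds += 1
            elif cls == "nonsyn":
                Dn += 1
    return MKTable(Dn=Dn, Ds=Ds, Pn=Pn, Ps=Ps)


# ---------------------------------------------------------------------------
# coalescent-simulation significance


def _stat_on_replicate(stat: str, rep: ReplicateSummary) -> float | None:
    if stat == "TajimaD":
        return tajimas_d(rep.n, rep.S, rep.k_hat).value if rep.S > 0 else None
    if stat in ("FuLiD", "FuLiF"):
        d, f = fu_li_d_f(rep.n, rep.S, rep.eta_e, rep.k_hat)
        return d.value if stat == "FuLiD" else f.value
    if stat == "FuFs":
        return fus_fs(rep.n, rep.k_hat, rep.k_haps).value
    if stat == "FayWuH":
        return fay_wu_h(rep.sfs, rep.k_hat).value
    if stat == "nH":
        return normalized_h(rep.sfs, rep.S).value
    raise ValueError(f"unknown statistic {stat!r}")


def coalescent_pvalue(
    stat: str,
    observed: float,
    n: int,
    S: int,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-tailed empirical p-value of a statistic under the neutral null.

    Simulates ``reps`` neutral constant-size coalescent samples of size ``n``
    conditioned on ``S`` segregating sites, evaluates the statistic on each,
    and returns ``2 * min(lower tail, upper tail)`` with the
    (r + 1)/(reps + 1) correction; the p-value never reaches 0 (floor
    2/(reps + 1)).
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config = ScenarioConfig(scenario="neutral", n=n, theta=None, fixed_S=S, L=max(S, 1))
    needs_haps = stat == "FuFs"
    sims = replicate_summaries(config, reps, rng, haplotypes=needs_haps)
    values = [_stat_on_replicate(stat, rep) for rep in sims]
    values = [v for v in values if v is not None and math.isfinite(v)]
    eff = len(values)
    if eff < 0.9 * reps:
        logger.warning(
            "coalescent_pvalue(%s): statistic undefined on %d of %d replicates",
            stat, reps - eff, reps,
        )
    if eff == 0:
        raise RuntimeError("statistic undefined on every replicate")
    arr = np.asarray(values)
    p_low = (int((arr <= observed).sum()) + 1) / (eff + 1)
    p_high = (int((arr >= observed).sum()) + 1) / (eff + 1)
    return min(1.0, 2.0 * min(p_low, p_high))
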