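"""Calibration experiments for the generator and the test battery.

These are the self-contained, seeded experiments used to verify that the
pipeline behaves as designed: moment checks of the neutral coalescent,
empirical type-I error of the coalescent p-value, directional shifts of the
scenario generators, and power/size of the codon Z-test on synthetic data
with known selection regimes.  Each function takes a ``numpy`` Generator (or
seed) and is deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coalsim import (
    ScenarioConfig,
    neutral_syn_fraction,
    replicate_summaries,
    simulate,
)
from .codonz import codon_z_test
from .diversity import harmonic
from .neutrality import coalescent_pvalue, fay_wu_h, fus_fs, tajimas_d


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class NeutralMoments:
    """Monte-Carlo moments of the neutral coalescent against theory."""

    reps: int
    mean_S: float
    se_S: float
    expected_S: float
    mean_k_hat: float
    se_k_hat: float
    expected_k_hat: float
    sfs_counts: tuple[int, ...]
    sfs_gof_pvalue: float


def _sfs_gof_pvalue(count_matrix: np.ndarray, theta: float) -> float:
    """Hotelling T^2 test of the per-replicate SFS means against theta / i.

    Under neutrality the expected count of mutations at derived frequency i
    is exactly theta / i for every i (Fu 1995, Theor Popul Biol 48:172).
    Pooling counts across replicates and applying a plain chi-square would
    be invalid: mutations sharing a genealogy are positively correlated, so
    the pooled counts are overdispersed relative to a multinomial and the
    chi-square rejects far too often.  Instead the replicate count vectors
    are treated as the i.i.d. unit: their mean is compared with the
    theoretical mean using the empirical covariance, giving a statistic
    that is asymptotically chi-square with n - 1 degrees of freedom.
    """
    from scipy.stats import chi2

    reps = count_matrix.shape[0]
    classes = count_matrix.shape[1]
    mu = np.array([theta / i for i in range(1, classes + 1)])
    diff = count_matrix.mean(axis=0) - mu
    cov = np.cov(count_matrix, rowvar=False)
    t2 = reps * float(diff @ np.linalg.solve(cov, diff))
    return float(chi2.sf(t2, df=classes))


def neutral_moments(n: int, theta: float, reps: int, seed) -> NeutralMoments:
    """Simulate neutral replicates and compare S, k_hat and the SFS with theory.

    Under the standard coalescent E[S] = theta * a1(n) and E[k_hat] = theta.
    """
    rng = _as_rng(seed)
    config = ScenarioConfig(scenario="neutral", n=n, theta=theta, L=633)
    sims = replicate_summaries(config, reps, rng)
    S = np.array([r.S for r in sims], dtype=float)
    k = np.array([r.k_hat for r in sims])
    counts = np.array([r.sfs_counts for r in sims], dtype=float)
    return NeutralMoments(
        reps=reps,
        mean_S=float(S.mean()),
        se_S=float(S.std(ddof=1) / math.sqrt(reps)),
        expected_S=theta * harmonic(n),
        mean_k_hat=float(k.mean()),
        se_k_hat=float(k.std(ddof=1) / math.sqrt(reps)),
        expected_k_hat=theta,
        sfs_counts=tuple(int(c) for c in counts.sum(axis=0)),
        sfs_gof_pvalue=_sfs_gof_pvalue(counts, theta),
    )


def tajima_type1_error(
    n: int,
    S: int,
    trials: int,
    seed,
    reps: int = 200,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the coalescent-p Tajima's D on neutral data.

    Each trial draws one neutral sample conditioned on ``S`` segregating
    sites, computes D, and tests it against an independent ``reps``-replicate
    neutral null; the returned fraction should be close to ``alpha``.
    """
    rng = _as_rng(seed)
    config = ScenarioConfig(scenario="neutral", n=n, theta=None, fixed_S=S, L=max(S, 1))
    rejected = 0
    for _ in range(trials):
        obs = replicate_summaries(config, 1, rng)[0]
        d = tajimas_d(obs.n, obs.S, obs.k_hat).value
        p = coalescent_pvalue("TajimaD", d, n, S, reps=reps, seed=rng)
        if p < alpha:
            rejected += 1
    return rejected / trials


def scenario_stat_values(
    scenario: str, stat: str, reps: int, seed, **config_kwargs
) -> np.ndarray:
    """Per-replicate values of one statistic under a scenario's defaults.

    ``stat`` is one of ``TajimaD``, ``FuFs``, ``FayWuH``.  Replicates on
    which the statistic is undefined are dropped.
    """
    rng = _as_rng(seed)
    config = ScenarioConfig(scenario=scenario, **config_kwargs)
    sims = replicate_summaries(config, reps, rng, haplotypes=(stat == "FuFs"))
    values = []
    for r in sims:
        if r.S == 0:
            continue
        if stat == "TajimaD":
            v = tajimas_d(r.n, r.S, r.k_hat).value
        elif stat == "FuFs":
            v = fus_fs(r.n, r.k_hat, r.k_haps).value
        elif stat == "FayWuH":
            v = fay_wu_h(r.sfs, r.k_hat).value
        else:
            raise ValueError(f"unsupported statistic {stat!r}")
        if v is not None and math.isfinite(v):
            values.append(v)
    return np.asarray(values)


def ztest_rejection_rate(
    syn_fraction: float,
    runs: int,
    seed,
    n: int = 12,
    theta: float = 15.0,
    L: int = 633,
    alternative: str = "purifying",
    alpha: float = 0.05,
    z_reps: int = 1000,
) -> float:
    """Fraction of synthetic datasets on which the codon Z-test rejects.

    Each run simulates a neutral-genealogy dataset whose mutations are split
    between the synonymous and non-synonymous classes by ``syn_fraction``
    (:func:`~domainsel.coalsim.neutral_syn_fraction` gives the no-selection
    value; larger fractions under-represent non-synonymous changes, i.e.
    purifying selection), then tests it with equal transition weighting
    (``R = 1``), matching the generator's unbiased base choice.  Undefined
    tests count as non-rejections.
    """
    rng = _as_rng(seed)
    rejected = 0
    for i in range(runs):
        config = ScenarioConfig(
            scenario="neutral", n=n, theta=theta, L=L,
            syn_fraction=syn_fraction, outgroup_divergence=0.0,
            seed=int(rng.integers(2**63)),
        )
        aln = simulate(config)
        result = codon_z_test(
            aln, alternative=alternative, R=1.0, reps=z_reps, seed=rng
        )
        if result.p_value is not None and result.p_value < alpha:
            rejected += 1
    return rejected / runs


__all__ = [
    "NeutralMoments",
    "neutral_moments",
    "neutral_syn_fraction",
    "scenario_stat_values",
    "tajima_type1_error",
    "ztest_rejection_rate",
]
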