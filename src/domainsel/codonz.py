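"""Codon-based Z-test of selection on mean pairwise dN and dS.

The mean synonymous and non-synonymous substitution rates per site are
averaged over all sequence pairs (modified Nei–Gojobori counting with
transition weight ``R``, Jukes–Cantor corrected); the standard error of
``dN - dS`` comes from bootstrap resampling of codon columns, and the test
is one-tailed against the stated alternative (purifying: dN < dS; positive:
dN > dS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .alignments import CodonAlignment, Region
from .diversity import pairwise_ng_arrays

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a proportion of differences exceeds the Jukes–Cantor domain."""


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 0.75; larger proportions are saturated and raise
    :class:`SaturationError`.
    """
    if p < 0.0:
        raise ValueError(f"negative proportion {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond Jukes–Cantor saturation")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class ZTestResult:
    """Outcome of one codon-based Z-test."""

    dN_mean: float | None
    dS_mean: float | None
    Z: float | None
    p_value: float | None
    direction: str  # purifying | positive | neutral | undefined
    alternative: str
    reps: int
    seed: int | None
    n_pairs: int = 0
    n_saturated_pairs: int = 0

    @property
    def defined(self) -> bool:
        return self.Z is not None


def _pair_distances(SDp, NDp, SSp, NSp, cols=None):
    """Per-pair JC-corrected dS and dN over the selected codon columns.

    Returns (dS, dN, saturated) arrays; saturated pairs are flagged, not
    clamped.
    """
    if cols is not None:
        SDp, NDp = SDp[:, cols], NDp[:, cols]
        SSp, NSp = SSp[:, cols], NSp[:, cols]
    sd, nd = SDp.sum(axis=1), NDp.sum(axis=1)
    ss, ns = SSp.sum(axis=1), NSp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(ss > 0, sd / np.maximum(ss, 1e-300), 0.0)
        pn = np.where(ns > 0, nd / np.maximum(ns, 1e-300), 0.0)
    saturated = (ps >= 0.75) | (pn >= 0.75)
    ps = np.minimum(ps, 0.7499)
    pn = np.minimum(pn, 0.7499)
    dS = -0.75 * np.log1p(-4.0 * ps / 3.0)
    dN = -0.75 * np.log1p(-4.0 * pn / 3.0)
    return dS, dN, saturated


def codon_z_test(
    alignment: CodonAlignment,
    region: Region | tuple[int, int] | None = None,
    alternative: str = "purifying",
    R: float = 2.0,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ZTestResult:
    """Test for purifying (dN < dS) or positive (dN > dS) selection.

    The point estimate averages JC-corrected per-pair proportions over all
    ingroup sequence pairs (saturated pairs dropped with a warning); the SE
    of the difference comes from ``reps`` bootstrap resamples of codon
    columns; the p-value is the one-tailed standard-normal tail for the
    requested alternative.
    """
    if alternative not in ("purifying", "positive"):
        raise ValueError("alternative must be 'purifying' or 'positive'")
    if isinstance(region, Region):
        alignment = alignment.slice(region.start, region.end)
    elif isinstance(region, tuple):
        alignment = alignment.slice(*region)
    n = len(alignment.ingroup())
    if n < 3:
        raise ValueError("need at least 3 ingroup sequences")

    SDp, NDp, SSp, NSp, mask = pairwise_ng_arrays(alignment, R)
    n_codons = mask.shape[1]
    if n_codons < 5:
        raise ValueError("region yields fewer than 5 codons")

    dS, dN, saturated = _pair_distances(SDp, NDp, SSp, NSp)
    keep = ~saturated
    n_sat = int(saturated.sum())
    if n_sat:
        logger.warning("codon_z_test: %d saturated pairs excluded", n_sat)
    if not keep.any():
        raise SaturationError("all pairs saturated")

    dN_mean = float(dN[keep].mean())
    dS_mean = float(dS[keep].mean())
    seed_out = seed if isinstance(seed, int) else None
    if dN_mean == 0.0 and dS_mean == 0.0:
        return ZTestResult(
            None, None, None, None, "undefined", alternative, reps, seed_out,
            n_pairs=int(keep.sum()), n_saturated_pairs=n_sat,
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = np.empty(reps)
    for b in range(reps):
        cols = rng.integers(0, n_codons, size=n_codons)
        bdS, bdN, bsat = _pair_distances(SDp, NDp, SSp, NSp, cols)
        bkeep = keep & ~bsat
        if not bkeep.any():
            diffs[b] = np.nan
            continue
        diffs[b] = bdN[bkeep].mean() - bdS[bkeep].mean()
    diffs = diffs[np.isfinite(diffs)]
    se = float(diffs.std(ddof=1))
    if se == 0.0:
        return ZTestResult(
            dN_mean, dS_mean, None, None, "undefined", alternative, reps, seed_out,
            n_pairs=int(keep.sum()), n_saturated_pairs=n_sat,
        )
    z = (dN_mean - dS_mean) / se
    if alternative == "purifying":
        p = float(norm.cdf(z))
    else:
        p = float(norm.sf(z))
    direction = "neutral"
    if p < 0.05:
        direction = "purifying" if alternative == "purifying" else "positive"
    return ZTestResult(
        dN_mean, dS_mean, float(z), p, direction, alternative, reps, seed_out,
        n_pairs=int(keep.sum()), n_saturated_pairs=n_sat,
    )
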