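"""Orchestration: per-region battery runs and sliding-window tracks.

``run_battery`` evaluates the diversity summary, the neutrality-test battery
(with coalescent-simulation p-values) and the codon Z-tests for the whole
exon ("Overall") and for each configured subregion.  ``sliding_windows``
produces per-window statistic tracks (default 100 bp window, 25 bp step) in
alignment coordinates.

Statistic sourcing within the battery: Tajima's D, Fu's Fs and the
Ewens–Watterson test use the complete-deletion ingroup summary; the
outgroup-polarized statistics (Fu & Li's D and F, Fay & Wu's H, normalized
H) are computed from the polarized site-frequency spectrum, so their
mutation counts exclude columns the outgroup cannot polarize.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._codon_tables import AA, STOPS
from .alignments import CodonAlignment, Region, RegionMap
from .codonz import ZTestResult, codon_z_test
from .diversity import DiversitySummary, haplotype_counts, sfs, summarize
from .neutrality import (
    NeutralityResult,
    coalescent_pvalue,
    ewens_watterson,
    fay_wu_h,
    fu_li_d_f,
    fus_fs,
    mk_table_from_alignment,
    mk_test,
    normalized_h,
    tajimas_d,
)

logger = logging.getLogger(__name__)

UNDEFINED_CELL = "–"  # en dash, as published selection tables render empty cells

COALESCENT_STATS = ("TajimaD", "FuFs", "FuLiD", "FuLiF", "FayWuH", "nH")


@dataclass(frozen=True)
class RunConfig:
    """Battery configuration: replicate counts, NG weighting and the seed."""

    coalescent_reps: int = 1000
    z_reps: int = 1000
    ew_reps: int = 10000
    ng_ratio: float = 2.0
    seed: int | None = None
    compute_pvalues: bool = True
    run_mk: bool = True


@dataclass
class RegionReport:
    name: str
    start: int
    end: int
    diversity: DiversitySummary | None = None
    neutrality: dict[str, NeutralityResult] = field(default_factory=dict)
    z_purifying: ZTestResult | None = None
    z_positive: ZTestResult | None = None
    error: str | None = None


@dataclass
class BatteryReport:
    gene: str
    config: RunConfig
    regions: list[RegionReport]

    def _fmt(self, value, digits=3):
        return UNDEFINED_CELL if value is None else f"{value:.{digits}f}"

    def diversity_table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            d = r.diversity
            if d is None:
                rows.append([self.gene, r.name, r.end - r.start + 1] + [UNDEFINED_CELL] * 6)
                continue
            rows.append([
                self.gene, r.name, r.end - r.start + 1, d.S,
                self._fmt(d.HHe), self._fmt(d.pi * 1e3, 2),
                self._fmt(None if d.pi_s is None else d.pi_s * 1e3, 2),
                self._fmt(None if d.pi_a is None else d.pi_a * 1e3, 2),
                self._fmt(d.pi_a_over_pi_s),
            ])
        return pd.DataFrame(
            rows,
            columns=["Gene", "Part", "Length", "Segr. sites", "HHe",
                     "pi*10^3", "pis*10^3", "pia*10^3", "pia/pis"],
        )

    def neutrality_table(self) -> pd.DataFrame:
        order = ["TajimaD", "FuFs", "FuLiD", "FuLiF", "FayWuH", "nH", "EW"]
        headers = ["Tajima's D", "Fu's Fs", "FL-D", "FL-F", "FW-H", "nH", "EW"]
        rows = []
        for r in self.regions:
            row = [self.gene, r.name]
            for stat in order:
                res = r.neutrality.get(stat)
                if res is None or res.value is None:
                    row.append(UNDEFINED_CELL)
                else:
                    row.append(f"{res.value:.3f}{res.stars}")
            rows.append(row)
        return pd.DataFrame(rows, columns=["Gene", "Part"] + headers)

    def pvalues_table(self) -> pd.DataFrame:
        """Long-format p-values with a Bonferroni-adjusted column.

        The published layout stars each cell at its raw p; the adjusted
        column multiplies by the number of defined p-values in the report.
        """
        rows = []
        for r in self.regions:
            for stat, res in r.neutrality.items():
                if res.value is None:
                    continue
                rows.append([self.gene, r.name, stat, res.value, res.p_value, res.p_source])
        df = pd.DataFrame(
            rows, columns=["Gene", "Part", "statistic", "value", "p", "p_source"]
        )
        m = df["p"].notna().sum()
        df["p_bonferroni"] = (df["p"] * m).clip(upper=1.0)
        return df

    def ztest_table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            cells = []
            for z in (r.z_purifying, r.z_positive):
                if z is None or not z.defined:
                    cells.append(UNDEFINED_CELL)
                else:
                    stars = ""
                    if z.p_value is not None:
                        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
                            if z.p_value < thr:
                                stars = s
                                break
                    annot = f" ({z.direction.capitalize()})" if z.direction in ("purifying", "positive") else ""
                    cells.append(f"{z.Z:.3f}{stars}{annot}")
            rows.append([self.gene, r.name] + cells)
        return pd.DataFrame(rows, columns=["Gene", "Part", "Z (dN<dS)", "Z (dN>dS)"])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diversity_table().to_csv(out / "diversity.tsv", sep="\t", index=False)
        self.neutrality_table().to_csv(out / "neutrality.tsv", sep="\t", index=False)
        self.pvalues_table().to_csv(out / "pvalues.tsv", sep="\t", index=False)
        self.ztest_table().to_csv(out / "ztest.tsv", sep="\t", index=False)


def _neutrality_for_region(
    region_aln: CodonAlignment,
    config: RunConfig,
    seeds: list[np.random.SeedSequence],
) -> dict[str, NeutralityResult]:
    results: dict[str, NeutralityResult] = {}
    summary = summarize(region_aln, ng_ratio=config.ng_ratio)
    n, S, k_hat = summary.n, summary.S, summary.k_hat

    results["TajimaD"] = tajimas_d(n, S, k_hat) if n >= 4 else NeutralityResult("TajimaD", None)
    results["FuFs"] = fus_fs(n, k_hat, summary.k_haps)

    spectrum = None
    if region_aln.outgroup_id is not None:
        spectrum = sfs(region_aln)
        eta = spectrum.total
        if n >= 4 and eta > 0:
            d, f = fu_li_d_f(n, eta, spectrum.singletons, spectrum.theta_pi())
        else:
            d = NeutralityResult("FuLiD", None, n=n, S_or_eta=eta)
            f = NeutralityResult("FuLiF", None, n=n, S_or_eta=eta)
        results["FuLiD"], results["FuLiF"] = d, f
        results["FayWuH"] = (
            fay_wu_h(spectrum, spectrum.theta_pi())
            if eta > 0
            else NeutralityResult("FayWuH", None, n=n, S_or_eta=0)
        )
        results["nH"] = normalized_h(spectrum, eta)

    counts = haplotype_counts(region_aln)
    if S > 0 and len(counts) > 1:
        results["EW"] = ewens_watterson(
            counts, reps=config.ew_reps, seed=np.random.default_rng(seeds[0])
        )
    else:
        results["EW"] = NeutralityResult("EW", None, n=n)

    if config.run_mk and region_aln.outgroup_id is not None:
        try:
            results["MK"] = mk_test(mk_table_from_alignment(region_aln))
        except ValueError:
            results["MK"] = NeutralityResult("MK", None)

    if config.compute_pvalues:
        for i, stat in enumerate(COALESCENT_STATS):
            res = results.get(stat)
            if res is None or res.value is None:
                continue
            S_cond = res.S_or_eta if res.S_or_eta else S
            if not S_cond:
                continue
            p = coalescent_pvalue(
                stat, res.value, n, int(S_cond),
                reps=config.coalescent_reps,
                seed=np.random.default_rng(seeds[1 + i]),
            )
            results[stat] = NeutralityResult(
                res.statistic_name, res.value, p_value=p, p_source="coalescent",
                n=res.n, S_or_eta=res.S_or_eta, extras=res.extras,
            )
    return results


def run_battery(
    alignment: CodonAlignment,
    region_map: RegionMap,
    outgroup_id: str | None = None,
    config: RunConfig | None = None,
) -> BatteryReport:
    """Run the full per-region battery (diversity, neutrality, Z-tests).

    A region whose statistics are undefined (monomorphic, too few informative
    sites) is reported with flags rather than aborting the run.  Deterministic
    given ``config.seed``.
    """
    config = config or RunConfig()
    if outgroup_id is not None and outgroup_id != alignment.outgroup_id:
        alignment = CodonAlignment(
            alignment.records, frame_offset=alignment.frame_offset, outgroup_id=outgroup_id
        )
    regions = [Region("Overall", 1, alignment.length)] + list(region_map)
    root = np.random.SeedSequence(config.seed)
    region_seeds = root.spawn(len(regions))

    reports = []
    for region, seed_seq in zip(regions, region_seeds):
        report = RegionReport(name=region.name, start=region.start, end=region.end)
        sub = alignment.slice(region.start, region.end)
        seeds = seed_seq.spawn(3 + len(COALESCENT_STATS))
        try:
            report.diversity = summarize(sub, ng_ratio=config.ng_ratio)
            report.neutrality = _neutrality_for_region(sub, config, seeds)
        except ValueError as exc:
            report.error = str(exc)
            logger.warning("region %s: %s", region.name, exc)
        for alt, attr, child in (
            ("purifying", "z_purifying", -2),
            ("positive", "z_positive", -1),
        ):
            try:
                setattr(
                    report, attr,
                    codon_z_test(
                        sub if sub.outgroup_id is None else _drop_outgroup(sub),
                        alternative=alt, R=config.ng_ratio, reps=config.z_reps,
                        seed=np.random.default_rng(seeds[child]),
                    ),
                )
            except ValueError as exc:
                logger.info("region %s: Z-test undefined (%s)", region.name, exc)
        reports.append(report)
    return BatteryReport(gene=region_map.gene, config=config, regions=reports)


def _drop_outgroup(alignment: CodonAlignment) -> CodonAlignment:
    return CodonAlignment(
        tuple(r for r in alignment.records if r[0] != alignment.outgroup_id),
        frame_offset=alignment.frame_offset,
    )


@dataclass
class WindowTrack:
    """Sliding-window statistic track in alignment coordinates.

    Windows start at 1, 1+step, ... while they fit; the midpoint convention
    is ``start + window/2 - 1``.  Monomorphic windows carry NaN values with
    ``defined = False`` rather than zeros.
    """

    window_size: int
    step: int
    points: pd.DataFrame  # columns: start, midpoint, statistic, value, defined

    def pivot(self) -> pd.DataFrame:
        return self.points.pivot(index="midpoint", columns="statistic", values="value")


def sliding_windows(
    alignment: CodonAlignment,
    statistics: tuple[str, ...] = ("pi", "TajimaD", "FayWuH", "nH"),
    window: int = 100,
    step: int = 25,
) -> WindowTrack:
    """Evaluate statistics in sliding windows along the alignment."""
    if window > alignment.length:
        raise ValueError(f"window {window} exceeds alignment length {alignment.length}")
    rows = []
    start = 1
    while start + window - 1 <= alignment.length:
        mid = start + window / 2 - 1
        sub = alignment.slice(start, start + window - 1)
        summary = spectrum = None
        try:
            summary = summarize(sub)
        except ValueError:
            pass
        for stat in statistics:
            value = None
            if summary is not None and summary.S > 0:
                if stat == "pi":
                    value = summary.pi
                elif stat == "TajimaD" and summary.n >= 4:
                    value = tajimas_d(summary.n, summary.S, summary.k_hat).value
                elif stat == "FuFs":
                    value = fus_fs(summary.n, summary.k_hat, summary.k_haps).value
                elif stat in ("FayWuH", "nH", "FuLiD", "FuLiF"):
                    if spectrum is None and sub.outgroup_id is not None:
                        spectrum = sfs(sub)
                    if spectrum is not None and spectrum.total > 0:
                        if stat == "FayWuH":
                            value = fay_wu_h(spectrum, spectrum.theta_pi()).value
                        elif stat == "nH":
                            value = normalized_h(spectrum, spectrum.total).value
                        else:
                            d, f = fu_li_d_f(
                                spectrum.n, spectrum.total, spectrum.singletons,
                                spectrum.theta_pi(),
                            )
                            value = d.value if stat == "FuLiD" else f.value
            rows.append([start, mid, stat, np.nan if value is None else value, value is not None])
        start += step
        spectrum = None
    points = pd.DataFrame(rows, columns=["start", "midpoint", "statistic", "value", "defined"])
    return WindowTrack(window_size=window, step=step, points=points)


def translate_alignment(alignment: CodonAlignment) -> list[tuple[str, str]]:
    """Translate each record codon-wise; incomplete or stop codons become X."""
    out = []
    f = alignment.frame_offset
    n_codons = (alignment.length - f) // 3
    for rid, seq in alignment.records:
        aa = []
        for j in range(n_codons):
            codon = seq[f + 3 * j : f + 3 * j + 3]
            if codon in AA:
                aa.append(AA[codon])
            elif codon in STOPS:
                aa.append("*")
            else:
                aa.append("X")
        out.append((rid, "".join(aa)))
    return out


def write_run_metadata(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    doc = {
        "package": "domainsel",
        "version": __version__,
        "config": {
            "coalescent_reps": config.coalescent_reps,
            "z_reps": config.z_reps,
            "ew_reps": config.ew_reps,
            "ng_ratio": config.ng_ratio,
            "seed": config.seed,
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
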