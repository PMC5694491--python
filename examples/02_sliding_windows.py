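"""Sliding-window statistic tracks along a simulated exon.

Windows of 100 bp advance in 25 bp steps; each window reports pi, Tajima's D
and the two polarized statistics (Fay & Wu's H, normalized H), with NaN where
a window is monomorphic or unpolarizable.
"""

from domainsel import sliding_windows
from domainsel.coalsim import ScenarioConfig, simulate

aln = simulate(ScenarioConfig(scenario="star_sweep", n=25, theta=10.0, L=633, seed=7))

track = sliding_windows(aln, window=100, step=25)
wide = track.pivot()  # midpoint x statistic table
print(wide.round(3).to_string())

# the long format keeps a `defined` flag per point:
undefined = track.points[~track.points["defined"]]
print(f"\n{len(undefined)} window/statistic points undefined")
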