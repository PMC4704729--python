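"""The full read-based pipeline on a synthetic ancient genome.

Generates a panel VCF plus a read pileup from a known demography (test
genome sampled 1000 generations ago, mean coverage 10x, 30% transition
sites, 10% low-mapping-quality reads), then runs the same code path used on
real data: VCF ingestion, transversion / mapping-quality / coverage-window
filters, random-read pseudo-haploid calling, and the projection.
"""

import tempfile
from pathlib import Path

import numpy as np

from projana import (
    FixtureConfig,
    ScenarioSpec,
    build_observations,
    build_scenario,
    compute_projection,
    generate_fixture,
    read_panel,
    read_pileup,
    summarize,
)

cfg = FixtureConfig(
    model=build_scenario(ScenarioSpec("OPM", "A", 1000)),
    num_sites=30_000,
    mean_coverage=10.0,
    mapq_low_fraction=0.1,
    transition_fraction=0.3,
    seed=5,
)
with tempfile.TemporaryDirectory() as tmp:
    paths = generate_fixture(cfg, Path(tmp) / "demo")
    panel = read_panel(paths.vcf)
    reads = read_pileup(paths.pileup)
    observations = build_observations(panel, reads, np.random.default_rng(6))
    curve = compute_projection(observations)

n_pass = sum(o.pass_filters for o in observations)
reasons = {}
for o in observations:
    for r in o.filter_reasons:
        reasons[r] = reasons.get(r, 0) + 1

print(f"panel sites            : {len(panel)}")
print(f"sites passing filters  : {n_pass}")
for r, c in sorted(reasons.items()):
    print(f"  filtered {r:22s}: {c}")
s = summarize(curve)
print(f"mean projection        : {np.nanmean(curve.w):.3f}  (expected ~exp(-0.1) = 0.905)")
print(f"MPV (mean w for x>0.5) : {s.mpv:.3f}")
print(f"LSS to the w=1 line    : {s.lss_to_one:.2f}")
print(
    "\nAbout 30% of sites fall to the transversion filter by construction and"
    "\n~2.5% to the coverage window; the surviving sites reproduce the"
    "\nsimulated truth: a flat projection near 0.905 and an LSS to the"
    "\npanel-member line well above zero."
)
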