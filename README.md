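# projana

Projection analysis of ancient genomes onto present-day reference panels.

The **projection** w(x) asks, for every derived-allele frequency x observed
in a reference panel of n chromosomes: how often does a test genome carry
the derived allele at those sites, relative to x itself?  A member of the
reference population scores w(x) = 1 everywhere.  A test genome separated
from the panel's population by t generations of drift (constant diploid
size N, no gene flow) scores a flat

    w(x) = exp(-t / 2N),

and richer histories bend the curve in characteristic ways: reference-side
expansions depress rare-allele sharing, declines inflate it, bottlenecks
produce a humped curve, and admixture from the test population lifts w at
small x.  Because an ancient genome that is *directly ancestral* to the
panel population behaves differently from one on a *diverged sister*
lineage (whose projection stops changing once sampling is more recent than
the divergence), the projection's shape can separate the two cases.

The package is aimed at population geneticists working with low-coverage
ancient genomes, where genotype calling is unreliable: the test genome
enters as raw reads and is represented pseudo-haploidly (one random read
per site).

What's inside:

* **Read pipeline** — panel VCF ingestion (genotypes + ancestral-allele
  tag), per-read pileup input, the standard aDNA filters (transversions
  only, mapping quality ≥ 30, per-sample 2.5–97.5% coverage window),
  random-read calling, and the projection with its MPV and LSS summaries.
* **Serial-sampling coalescent simulator** — a fast single-locus engine
  with ancient (non-contemporaneous) samples, piecewise-constant sizes,
  splits and pulse admixture, for predicting projections under explicit
  demographies.
* **Scenario library** — the canonical one-population / two-population
  designs (variants A–E, sampling times 0–4000 generations, both sampling
  directions).
* **Demographic fitting** — free parameters of a demography template fitted
  by Brent line searches (cyclic coordinate descent) on the LSS between
  simulated and observed curves, with common random numbers.
* **Synthetic fixtures** — panel VCF + pileup generated from a known
  demography, so the whole pipeline is testable without external data.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
from projana import (ScenarioSpec, build_scenario, simulate_projection,
                     closed_form_projection, summarize)

# an ancient genome sampled 1000 generations ago, directly ancestral to the
# panel population (N = 5000, panel of 200 chromosomes sampled today)
model = build_scenario(ScenarioSpec("OPM", "A", 1000))
curve = simulate_projection(model, num_sites=50_000, seed=1, expected=True)
s = summarize(curve)
print(f"mean w = {np.nanmean(curve.w):.3f}")
print(f"closed form exp(-t/2N) = {closed_form_projection(1000, 5000):.3f}")
print(f"MPV = {s.mpv:.3f}, LSS to w=1 line = {s.lss_to_one:.2f}")
```

prints

```
mean w = 0.901
closed form exp(-t/2N) = 0.905
MPV = 0.902, LSS to w=1 line = 2.25
```

— the simulated curve is flat at the predicted level (the ~0.005 gap is the
exact finite-panel correction: even a true panel member scores
n/(n+1) = 0.995, not 1.0), its MPV equals that level, and the LSS distance
from the panel-member line is far from zero, flagging the test genome as
non-contemporaneous.  The scripts in `examples/` walk through the other
capabilities: scenario shape signatures, sampling-time fitting, and the
full VCF + pileup pipeline on synthetic data; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the main entry points
(`projana project|simulate|fit|fixture --help`).

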