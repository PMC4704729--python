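# Methods

## The projection statistic

For a reference panel of `n` chromosomes and a single test genome, the
projection w(x) at derived-allele frequency x = i/n is

    w(i/n) = [ d_i / m_i ] / (i/n)

where `m_i` is the number of usable sites at which the panel carries the
derived allele on exactly `i` chromosomes, and `d_i` the number of those
sites at which the test genome was called derived.  Dividing by x
calibrates the statistic so that a test genome drawn from the reference
population scores 1 at every frequency: a random panel chromosome carries a
derived allele of frequency x with probability exactly x.  Monomorphic
panel categories (i = 0, n) carry no information about sharing and are
excluded; categories with `m_i = 0` are undefined and skipped, never
imputed.  The unnormalised fraction `d_i/m_i` is also exposed
(`ProjectionCurve.raw_fraction`).

Two summaries:

* **MPV** — the unweighted mean of w over defined categories with x > 0.5.
  (The acronym appears in the literature expanded both as "minimum" and as
  "mean" projection value; the computation is the same and is what we
  implement.  A site-weighted variant is available via a flag.)
* **LSS** — Σ (w_a(x) − w_b(x))² over categories defined in both curves,
  where b may be another curve or the constant line w = 1.  Curves on
  different category grids are first pooled onto a common 25-bin equal-width
  grid (`rebin_projection`; pooled w = pooled derived fraction divided by
  the site-weighted mean x of the bin, so counts are conserved).

For the simplest history — the test lineage separated from the panel's
population by t generations, constant diploid size N, no gene flow — the
projection is flat at exp(−t/2N).  This is a diffusion / large-panel
limit.  The exact finite-panel value is slightly lower; in the cleanest
case (t = 0, neutral spectrum) it is exactly n/(n+1), which the simulator
reproduces to four decimals and which we use as a correctness anchor.

## Read-based calling and site filters

Ancient genomes are represented pseudo-haploidly: at each site one read is
drawn uniformly at random and its allele taken at face value.  Before the
draw, reads with mapping quality below 30 (strict: MQ = 30 survives) and
reads carrying neither panel allele are discarded; a per-site mean-MQ
alternative is exposed (`mapq_mode="site_mean"`) because the aggregation
level of the published MQ filter is ambiguous.  Base quality is not
filtered.  Site-level filters: biallelic SNPs only; transversions only
(post-mortem deamination creates C→T/G→A artifacts); per-site coverage must
lie inside the central 2.5–97.5% interval of the sample's own coverage
histogram (computed over all sites with ≥ 1 read, before other filters).
The cutoffs are rounded inward: min_cov is the largest value with ≤ 2.5% of
mass strictly below it, max_cov the smallest with ≤ 2.5% strictly above, so
the inclusive window always retains ≥ 95% of sites.  With discrete
coverage distributions the excluded mass is typically below 5% (≈ 2.5% for
Poisson(10)); tests compare against the rule's own expectation, not a
nominal 5%.  Ancestral alleles come from an INFO tag (default `AA`, first
`|`-separated token); lowercase (low-confidence) annotations are rejected
unless explicitly allowed.  Positions are 1-based; inputs are assumed
reference-strand oriented and are never complemented.

## The serial-sampling coalescent simulator

A bespoke single-locus engine (compiled with numba):

* lineages enter the genealogy at their sampling times — an ancient sample
  is simply a lineage that activates t generations back;
* within a deme of current diploid size N holding k active lineages,
  coalescence waits an exponential time with rate k(k−1)/(4N); sizes are
  piecewise constant, and waits are redrawn at every size/event/sampling
  breakpoint (valid by memorylessness);
* a population split moves all lineages of the derived deme into the
  ancestral deme; a pulse moves each lineage of the recipient to the source
  independently with probability f.  At equal times, sample entries are
  processed first, then pulses, then splits, ties by declaration order.

The continuous-time approximation is standard and accurate for the sizes
used here (N ≥ 500).

**Mutations** follow the infinite-sites model.  Each site carries one
mutation on a branch chosen proportionally to branch length, and — the part
that is easy to get wrong — a genealogy contributes sites in proportion to
its *total* branch length.  Placing exactly one mutation per simulated tree
("fixed-S") weights short trees too heavily and inflates singletons (the
1/i spectrum oracle catches this at 10⁵ sites), and it biased the flat OPM
projection by ≈ −0.015 at t = 1000.  The sampled path therefore draws a
Poisson(L/L̄) number of sites per tree, with L̄ calibrated by a 500-tree
pilot; the expectation path accumulates raw branch lengths into a
(panel count, test flag) table, integrating mutation placement out
analytically ("expected mode", the low-noise option used for scenario
curves and fitting objectives).  The absolute mutation rate never enters:
the projection conditions on the panel count, so only relative branch
lengths matter.

The engine only ever tracks, per branch, the number of panel leaves below
it and whether the test leaf is below it — no explicit tree is built in the
bulk path.  A readable pure-Python implementation of the same process
(`simulate_genealogy`) returns explicit trees and serves as an internal
cross-check; msprime is used in the test suite as an external oracle (mean
pairwise TMRCA, serial-sample joint spectra) and matches the engine to
Monte Carlo precision.

Randomness: each simulation call consumes one sequential stream seeded from
the caller's seed (pilot and main phases use SeedSequence-derived children).
Identical seeds replay identical site lists; scenario grids and fits derive
independent child seeds per task.

## Canonical scenarios

Study conditions baked into the scenario library: panel of 200 chromosomes
(100 diploids), diploid N = 5000, divergence 2000 generations ago (ga),
pulse fraction 0.05 at 750 ga, bottleneck size 500 between 500 and 1000 ga,
expansion/decline between 500 and 5000 at 750 ga, sampling times
{0, 500, 1000, 2000, 3000, 4000} ga, 25 years per generation for
year-valued inputs.  In the one-population family (OPM) the ancient sample
is directly ancestral to the present-day population; in the two-population
family (TPM) it sits on a sister branch.  A diverging population takes the
size its ancestor has at the divergence time (so 500 in variant C, 5000
otherwise).  In variant B of the OPM the pulse donor is an unsampled sister
population with the same divergence time.  A TPM sample older than the
divergence lives in the continuing ancestral deme.  The `ancient_panel`
direction swaps the panel and test sampling times.

The published eight-population human demography is supported only as a
user-supplied template; the four fitted parameters reported for it
(`T_8` = 38,950 yr, `T_15` = 610,175 yr, `f_NEA-ANC1` = 0.018,
`f_FRE-YOR` = 0.02) ship as `HUMAN_MODEL_PARAMETERS`, because the remaining
parameter values are not part of this package's sources.

## Demographic fitting

Free parameters (named slots in a demography template, with box bounds and
an optional log transform) are fitted by cyclic coordinate descent: one
bounded Brent line search per parameter per cycle, minimising the summed
LSS between simulated and observed curves; cycles stop when a full pass
improves the objective by less than `tol` (default 10⁻³) or after
`max_cycles` (default 10).  Every objective evaluation reuses one fixed
seed (common random numbers), making the objective a deterministic — if
jagged — function of the parameters, and by default runs the simulator in
expected mode.  Because Brent never lands exactly on a bound, both bounds
are evaluated explicitly after each line search, so a true value at a bound
is returned as the bound.  Candidate values are accepted only when they
improve the incumbent objective, so the returned score never exceeds the
starting score and always equals a fresh evaluation at the returned values.

Identifiability caveat, measured not assumed: from a 2×10⁵-site observed
curve of the two-population pulse model, profile fits against near-noiseless
simulated grids spread with sd ≈ 100 generations for the divergence time
but sd ≈ 0.011 for the pulse fraction — the curve simply carries little
information about a 5% pulse.  Sampling-time and divergence-time recovery
are demonstrated in the tests and the acceptance script; pulse-fraction
recovery to ±0.01 is not attainable at that observation size, and the
corresponding stress test documents the measured hit rate rather than
papering over it.

## Synthetic fixtures

`generate_fixture` dresses simulated sites up as the files the real-data
path consumes: a diploid VCF (derived alleles scattered over a uniformly
random subset of lineages — exact by exchangeability — lineages paired into
individuals by index; REF = ancestral allele, AA INFO tag), a per-read
pileup with Poisson coverage, a configurable fraction of sub-30 mapping
qualities and a configurable transition fraction (ancestral base uniform;
derived base the transition partner, or a uniform transversion partner),
and a truth table of the simulated counts.  Defaults: coverage 10×, 10%
low-MQ reads, 30% transitions, no base error.  Deliberately absent:
sequencing error (optional uniform `base_error` exists for robustness
tests), post-mortem damage profiles, fragment-length structure and
reference bias — so a passing round trip certifies the pipeline's
bookkeeping and filters, not robustness to real aDNA damage.

## Problem sizes and numerical choices

Scenario curves in tests and the acceptance script use 2×10⁵ sites
(expectation mode where only the curve is needed), 10⁵ sites for spectrum
oracles, 2×10⁴ replicates for TMRCA checks, and 1.2–3×10⁴ genealogies per
fitting objective evaluation; statistical assertions use envelopes
calibrated from replicate simulations at equal size rather than fixed
magic numbers.  Degenerate inputs (no reads, unknown ancestral allele,
third alleles, all-filtered sites) yield flagged observations or clean
errors, never silent exceptions; mixed panel sizes and empty inputs raise.
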