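# Methods

`ptbquant` quantifies how a multi-domain RNA-binding protein (PTB, four RRM
domains) engages a pre-mRNA substrate, from four kinds of bench data:
single-molecule photobleaching movies, tethered hydroxyl-radical probing
gels, in vitro splicing gels and filter-binding titrations. This note
records the models, their assumptions, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Photobleaching stoichiometry

### Model

Surface-tethered RNA is imaged by TIRF until every bound GFP-tagged protein
has bleached; the acquisition is 500 bins of 200 ms, with the first 30 bins
recording the RNA dye before the GFP channel is switched on. A complex with
`i` bound proteins shows `i` downward bleaching steps. Because complexes
with zero bound proteins carry no GFP and are never selected, `i` follows a
binomial distribution over the `n` binding sites at occupancy `θ`,
truncated at `i ≥ 1`:

```
P(i | n, θ) = C(n,i) θ^i (1−θ)^(n−i) / (1 − (1−θ)^n),   i = 1..n
```

Three estimators of `n` are implemented; on real data they are reported
side by side (columns A/B/C of the per-RNA report) because each has
different failure modes.

**A. Pearson χ² fit** (`TruncatedBinomialModel`). For each candidate
`n = 2..8` the χ² between observed step counts and `N·P(i|n,θ)` is
minimised over `θ ∈ [10⁻³, 1−10⁻³]` (coarse 199-point grid, then bounded
scalar refinement, xatol 10⁻¹⁰). The contiguous sparse tail — largest-`i`
cells with expected count below 1 — is pooled into the preceding cell to
avoid division blow-ups. Pooling deliberately applies to the tail only and
never reduces the table below two cells: pooling a *head* cell whose
expectation is small but whose observed count is large would let an extreme
`θ` hide gross disagreement inside the pooled cell (the optimiser finds and
exploits such degeneracies), and a fully pooled table has zero degrees of
freedom, making every parameter value look perfect. Ties across `n`
within 10⁻⁹ resolve to the smallest `n` (parsimony). The χ² profile over
`n` is retained in the results object.

**B. Linearization** (`LinearizationModel`). For binomial counts the ratio
statistic is exactly linear in `i`:

```
y(i) = i·P_i / P_(i−1) = (n+1)·θ/(1−θ) − i·θ/(1−θ)
```

Points use `i ≥ 2` (the zero-step occurrence is unobservable) with both
occurrences positive; the line is fitted by unweighted ordinary least
squares, giving `θ̂ = −s/(1−s)` and `n̂ = round(−b/s − 1)`. A non-negative
slope is rejected as non-binomial. This estimator is cheap and
assumption-light but high-variance: the tail point rests on few counts, and
a by-chance near-flat line sends `−b/s − 1` far above the truth. At
`n = 4, θ = 0.4, N = 300` complexes its probability of landing within ±1
of the true `n` is about 93% (measured over 2000 simulated histograms);
inverse-variance and GLS weighting raise this only to ~94–95%. Users should
treat column B as a range check on column A, not as an independent
high-precision estimate.

**C. Emission mixture** (`EmissionMixtureModel`). The total emission of a
single fluorophore — constant brightness until an exponential bleach time —
is exponential with mean `μ`; a complex with `i` fluorophores emits an
Erlang(`i`) total with mean `i·μ`. `μ` is first estimated from one-step
complexes by least-squares fit of the empirical CDF to `1 − exp(−x/μ)`
(Hazen plotting positions; degenerate inputs are flagged when the mean
squared CDF residual exceeds 0.01). The full emission set is then fitted by
the truncated-binomial-weighted Erlang mixture CDF, with `θ` taken from the
step analysis and `μ` refined within a factor of 3 of the single-step
estimate; `n` minimises the summed squared CDF deviation. Least squares on
the cumulative distribution (rather than maximum likelihood) matches how
these distributions are conventionally fitted in subunit-counting work.

### Step detection

No standard exists for counting bleaching steps, so the detector is an
explicit design choice: penalised least-squares binary segmentation of the
GFP segment into constant levels (penalty `3·σ²·log T` per changepoint,
`σ` a robust noise estimate from the MAD of first differences), then
counting downward level changes exceeding `3σ`. The unit step height is
estimated as the median of the smallest cluster of significant drops
(within 1.5× of the minimum) and each drop contributes `round(drop/unit)`
steps, so simultaneous bleaches in one bin are resolved by height. At a
per-bin noise of 0.15 step heights the detector reproduces the hidden
fluorophore count on ≥ 95% of simulated traces. Pre-counted step histograms
are accepted everywhere as an alternative entry point, so the estimators do
not depend on the detector.

### Colocalization

The fraction of RNA-channel spots with a GFP partner within a radius is
computed by greedy nearest-first matching with each GFP spot used at most
once. The matching radius is experiment-specific and has no default
justification beyond typical point-spread sizes; it is a required argument.

## Footprint quantification

Band intensities from tethered hydroxyl-radical probing gels arrive as
tables (gel densitometry itself is out of scope). Each probe lane is
normalised by the mean lane/control ratio over user-designated background
bands (invariant bands; which bands are invariant is an experimental
judgement, so the set is an input, not inferred). Normalisation is
idempotent and removes any global lane scale. Per-band cleavage ratios
(normalised probe / normalised control) are classified with closed lower
bounds: ratio ≥ 2 strong, 1.2 ≤ ratio < 2 weak, below 1.2 none. Bands with
zero control intensity are reported as unquantifiable (NaN), not errors.

Construct coordinates are mapped to full-length reference numbering across
the 1060-nt intron deletion: positions ≤ 327 are unchanged, later positions
shift by +1060 (construct 328 → reference 1388). The map is strictly
increasing and injective. Contact maps collect classified calls from all
probes, sorted by position, with per-window summaries over the annotated
U-rich elements (URE6, nt 239–254; URI6, nt 284–300; 1-based inclusive).

A single-replicate weak call is intrinsically fragile: at 10% multiplicative
band noise the probe/control ratio carries ≈ 11–12% noise, so a true fold
of 1.5 lands outside the [1.2, 2) window in roughly 5–10% of realisations.
The module reports per-experiment calls; replicate aggregation is left to
the user (no aggregation rule is defensible from a single gel).

## Splicing quantification

Percent exon skipping from the three product intensities weights the two
inclusion junctions by one half (each included transcript contributes both
junction products):

```
% skipping = 100 · s57 / (s57 + 0.5·(s56 + s67))
```

The statistic is scale-invariant and monotone in its arguments; no
molar/primer-efficiency correction is applied. Percent activity of a mutant
is baseline-subtracted and normalised to wild type,
`100·(skip_mut − skip_none)/(skip_wt − skip_none)`; values are stored at
full precision and rounded to integers only at report level. Replicates are
summarised per lane first (mean, sample SD with n−1), then combined.

## Binding

With RNA at 2–4 nM and protein titrated far above it, the single-site law
gives `bound/free = [P]/Kd`. `KdModel` fits an ordinary least-squares line
of bound/free against `[P]` with a free intercept (absorbing background
retention on the filters) and reports `Kd = 1/slope` with its propagated
fit standard error (`se_Kd = se_slope/slope²`), labelled as a fit error
rather than a replicate SD. No ligand-depletion (quadratic) or cooperative
model is offered; the linear method is the analysis being reproduced.
Two warnings guard its assumptions: protein not in ≥ 10× excess of RNA, and
near-saturated points (fraction bound > 0.98), whose bound/free values have
essentially unbounded noise sensitivity and leverage on the slope. For the
same reason the simulated recovery studies use a sub-saturating titration
(1–300 nM for Kd ≈ 20 nM), inside the full experimental range.

## Synthetic data

The generators sample exactly the models above: truncated-binomial bound
counts by rejection sampling; per-fluorophore geometric bleach times (per-bin
probability 0.02, i.e. mean 50 bins) with constant per-bin brightness
`μ·0.02`, making total emissions discrete-exponential with mean `μ = 100`
(negligibly censored by the 470-bin GFP segment); additive Gaussian bin
noise; a dye-window marker level above any GFP level so noiseless traces
are monotone; mean-one lognormal band noise on probe lanes with a drawn
global loading factor, against a noiseless control lane; splicing triples
that invert the skipping formula exactly at zero noise; and isotherms with
additive noise on the bound fraction clipped to [0, 1). Default study
conditions: `n = 4` sites, `θ = 0.5`, 500 complexes, 500 × 200 ms bins with
a 30-bin dye window. Every generator takes an explicit seed and is
bit-reproducible.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: fluorophore blinking and incomplete GFP
maturation (both bias step counts low), brightness heterogeneity between
fluorophores, drift and focus loss, non-specific surface adsorption,
band-shape overlap and lane smearing on gels, primer-extension efficiency
differences between products, and RNA depletion at low protein
concentrations in titrations.

## Problem sizes in the test suite

The shipped tests use the study-scale conditions: 10⁶ draws for pmf
convergence (3σ bands), 500 traces for detector validation, 100 replicate
histograms of 300 complexes for stochastic site-number recovery, 2000
emissions for mixture recovery, and 100 noisy titrations for Kd recovery.
These sizes make every stochastic check deterministic under the fixed
canonical seed while completing in well under a minute each.
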