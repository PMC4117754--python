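# ptbquant

Quantitative analysis of how a multi-domain RNA-binding protein engages a
pre-mRNA target, built for the data a bench characterisation of the
splicing repressor PTB (polypyrimidine tract binding protein, four RRM
domains) produces:

* **single-molecule photobleaching** (`ptbquant.smtirf`) — infer the number
  of protein binding sites *n* on an RNA and their fractional occupancy *θ*
  from TIRF intensity traces of surface-tethered complexes;
* **tethered hydroxyl-radical footprinting** (`ptbquant.footprint`) —
  normalise probing-gel band tables, compute probe/control cleavage ratios,
  call strong/weak contacts and assemble per-domain contact maps;
* **in vitro splicing** (`ptbquant.splicing`) — percent exon skipping from
  the three splicing-product band intensities, and mutant repressor
  activity relative to wild type;
* **filter binding** (`ptbquant.binding`) — apparent dissociation constants
  from the slope of bound/free RNA versus protein concentration;
* **synthetic data** (`ptbquant.simulate`) — seeded generators for every
  input above, with the exact statistical structure the analyses assume, so
  the whole pipeline is testable without gels or movies.

## The core model

Complexes with zero bound GFP-tagged proteins are invisible on the slide,
so the number of photobleaching steps *i* per complex follows a binomial
law truncated at *i* ≥ 1:

    P(i | n, θ) = C(n,i) θ^i (1−θ)^(n−i) / (1 − (1−θ)^n),  i = 1..n

Three estimators of *n* are provided, reported side by side as columns
A/B/C of the per-RNA report:

* **A** — Pearson χ² fit of the step-count histogram over candidate
  *n* = 2..8, minimised over θ (`TruncatedBinomialModel`);
* **B** — the linearization *i·P_i/P_(i−1)* versus *i*, a straight line
  with slope −θ/(1−θ) and intercept (n+1)·θ/(1−θ) for binomial counts
  (`LinearizationModel`);
* **C** — least-squares fit of the total-emission cumulative distribution
  by a truncated-binomial-weighted Erlang mixture, after estimating the
  single-fluorophore mean emission from one-step complexes
  (`EmissionMixtureModel`).

Each model object is constructed from data and `fit()` returns a results
object with the estimates, profiles and a `summary()` table. See
`docs/methods.md` for assumptions, numerical choices and known limitations.

## Worked example

Simulate a study-scale experiment (500 complexes on an RNA with four sites
at 50% occupancy, a 15 nM binder) and run the full analysis:

```
$ ptbquant simulate --seed 0 --out demo
$ ptbquant bleach-fit --traces demo/traces.csv --out demo/bleach.json
n_hat (chi2) = 4, theta_hat = 0.516
$ ptbquant emission-fit --traces demo/traces.csv --out demo/emission.json
n_hat (emission) = 5, mu_hat = 104.6
$ ptbquant report --bleach demo/bleach.json --emission demo/emission.json \
      --label wt --out demo/report.tsv
rna     n_chisq  theta_chisq  n_linearization  n_emission
wt      4        0.516        4                5
$ ptbquant binding-fit --table demo/isotherm.csv --out demo/kd.json
Kd = 12.7 +/- 0.5 nM
```

The report row is the A/B/C site-count table for this RNA: the χ² fit and
the linearization both recover the true four sites, the emission mixture
lands one high (its stated uncertainty is about one site), and the fitted
occupancy 0.516 sits next to the true 0.5. The Kd estimate 12.7 nM
recovers the simulated 15 nM within the noise of a single titration.

In the library the same numbers come from the model objects directly:

```python
>>> from ptbquant import StepCountHistogram, fit_truncated_binomial
>>> hist = StepCountHistogram({1: 141, 2: 158, 3: 86, 4: 15})
>>> print(fit_truncated_binomial(hist).summary())
Truncated-binomial chi-square fit
  complexes analysed : 400
  sites n̂           : 4
  occupancy θ̂       : 0.435
  min chi-square     : 0.259
  ...
```

And the splicing-side arithmetic:

```python
>>> from ptbquant import percent_activity
>>> print(percent_activity(59, 91, 22).summary())
% activity = 100*(59 - 22)/(91 - 22) = 54% (unrounded 53.62)
```

## Command-line pipeline

`ptbquant` exposes `simulate`, `bleach-fit`, `emission-fit`, `probe-quant`,
`splice-quant`, `binding-fit` and `report`. All inputs and outputs are
plain CSV/TSV/JSON; every run writes a structured log (tool version,
parameters, seed, input SHA-256) beside its outputs. Exit codes: 0 success,
2 usage error, 3 input schema mismatch, 4 analysis error, 5 unreadable
input.

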