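# Methods

## Classification model

A sputum examination is called **eosinophilic at a threshold**
`(c, G)` — cutoff `c` on the intact eosinophil differential %, qualifying
set `G` of free-eosinophil-granule (FEG) grades — when

```
(intact differential available AND eos% ≥ c)  OR  (FEG grade ∈ G)
```

The two standard thresholds are `c = 1.2` with `G = {few, moderate,
many}` (upper limit of normal; any granule evidence counts) and `c = 2.3`
with `G = {moderate, many}` (clinically relevant endotype; few granules
are not regarded as clinically relevant). The comparison is `≥` by
default and configurable to `>` for sensitivity checks. Under this rule
the 2.3% calls are a strict subset of the 1.2% calls (nesting), which the
suite verifies as an invariant.

FEG grades derive from clump counts per 400× field as none = 0,
few = 1–2, moderate = 3, many ≥ 4. The conventional wording of the scale
overlaps at 2 clumps ("1–2 few, 2–3 moderate"); we resolve the boundary
count 2 to the milder grade and keep "> 3 many" literal. The mapping is a
single configurable table.

A sample with neither an intact differential nor any FEG enumeration is
*indeterminate*: called negative with an audit flag, and by default
excluded from longitudinal pair scanning entirely (configurable to count
an indeterminate initial as negative; an indeterminate sample never
counts as the eosinophilic side).

## Staged prevalence and tally conventions

Tiers: intact-only `a/n`; FEG-augmented `p = (a+b+c)/n` where `b` adds
below-cutoff samples with qualifying FEG and `c` adds
no-intact-differential samples with qualifying FEG; total
`p + (1−p)·q` where `q` is the fraction of multi-sample patients with at
least one re-emergence event. Extrapolating `q`, estimated only in the
repeatedly-sampled subset, to the entire cohort (including single-sample
patients) is an assumption; the Markov model is the independent check.

Two conventions for `c` are implemented:

* **nested** (library default): every non-viable sample whose grade is in
  the threshold's own qualifying set. Logically consistent; preserves
  nesting.
* **paper_tally**: non-viable *few* samples count only at the 1.2% tier
  and *moderate/many* only at the 2.3% tier. This reproduces the
  published composition arithmetic (7850 = 6289+384+1177;
  5435 = 4647+66+722) but is not a coherent per-sample rule — as a
  classification it would violate nesting. We therefore keep the
  classifier nested and reproduce the published numbers at the tally
  level only.

Percentages are reported to one decimal. Two published figures differ
from their recomputation in the last digit (35.6% vs recomputed 35.5%,
and the 2.3%-threshold extrapolation 17.8%/48.5% vs recomputed
17.7%/48.4%); comparisons against those figures use an absolute band of
0.15 percentage points rather than silently "correcting" either side.

## Emergence detection and etiology

Events are scanned over consecutive examination pairs `(i, i+1)` within a
patient: negative call at `i`, positive call at `i+1`, FEG-augmented
rule. A patient can contribute several events. Etiology is attributed
mutually exclusively from two booleans: *neutrophilia at initial*
(initial neutrophil % strictly above the cutoff; default 64.4%, a
conventional upper limit of normal for the sputum neutrophil
differential, always recorded in summaries) and *steroid decrease*
(oral **or** inhaled fluticasone-equivalent daily dose strictly lower at
the subsequent sample). Unknown doses or a missing initial differential
make the corresponding condition indeterminate-false rather than
guessed. Neither — a flare of eosinophilic inflammation. Event-level
etiology fractions are mutually exclusive and sum to 1.

## Markov sensitivity model

Per-sample calls (indeterminates excluded) form per-patient sequences;
consecutive-pair transition counts are pooled across patients into one
2×2 table (one chain for the cohort) and row-normalized — the MLE.
Unequal calendar gaps between examinations are ignored: time is the
examination index, matching the discrete-time formulation. The
stationary eosinophilic occupancy is `π_E = p_NE/(p_NE + p_EN)`; a
next-step composite `prev + (1−prev)·p_NE` is also provided. Rows with
no outgoing pairs leave the chain partially undefined and projections
refuse to run; optional Laplace (+1) smoothing is available for sparse
synthetic runs and is off by default.

## Synthetic cohort generator

Each patient holds a latent eosinophilic state evolving as a two-state
chain `(p_NE, p_EN)` initialized at its stationary distribution; series
lengths are 1 (single-sample patients) or `1 + ZTGeom(p)` (multi-sample;
mean `1 + 1/p`). Observations given the latent state are conditionally
independent across visits:

* **eos %**: log-normal per effective state (capped at 97%, stored to
  2 decimals). A latent-eosinophilic visit is *masked* with probability
  `masking_prob`, in which case the observed eos % is drawn from the
  negative-state distribution. The masking draw comes first and its
  realized cause is then reflected in the covariates (a masked visit
  shows elevated neutrophils with probability
  `mask_neutrophil_coupling`; dose trajectories step down over visits,
  supplying dose-decrease etiologies). Conditioning in this direction —
  rather than deriving the mask from the covariates — keeps every
  closed-form expectation exact while producing the same observable
  pattern: latent eosinophilia hidden behind neutrophilia or steroids.
* **FEG clumps**: Poisson with a rate per (latent state, differential
  viability). Rates depend on viability because degenerated, non-viable
  cytospins carry granules far more often than viable below-cutoff
  samples — cytolysis and degeneration covary — and no single per-state
  rate can produce both observed frequencies.
* **viability**: Bernoulli, state-independent; optionally the FEG
  enumeration itself can be missing (`feg_missing_prob`, default 0),
  which is the only source of indeterminate samples.
* **supporting fields** (total cell count, viability %, squamous %,
  non-eosinophil differential lines, clinical state, doses) are drawn
  from plausible clinic-like distributions, the differential balanced to
  sum to exactly 100 after rounding. They are carried for realism and
  etiology attribution, not analysed further.

A single `numpy.random.Generator` seed determines the cohort byte for
byte. The ground-truth ledger records latent states, mask indicators and
the true chain parameters per patient.

`closed_form_expectations` computes, exactly under these assumptions:
sample-category fractions, call prevalence, the stationary
consecutive-pair emergence probability, and the patient-level
probability of ≥ 1 event via a forward recursion over (latent state,
observed call) that forbids the event pair and skips indeterminate
pairs, averaged over the series-length distribution. These serve as test
oracles (simulation vs formula) and as the calibration objective.

### Calibrated defaults

`paper_cohort_config()` freezes a least-squares calibration of the
emission and chain parameters to the published cohort's eight category
statistics (intact-positive fractions at both thresholds, FEG-positive
with/without differential, few vs moderate/many non-viable grades, and
both patient-level emergence fractions), with cohort dimensions matching
the source database (9570 patients, 31% multi-sample, mean 3.7
examinations per multi-sample patient, ≈ 17,700 samples). The fitted
values — latent `p_NE = 0.0509`, `p_EN = 0.0737` (sticky chain,
stationary latent occupancy ≈ 0.41), masking probability 0.065,
negative/positive eos % log-normals with medians 0.36/3.9 and log-sigmas
0.90/0.68, non-viable fraction 0.158, FEG rates 0.009/0.75 (viable
N/E) and 0.67/3.05 (non-viable N/E) — reproduce all eight statistics to
well under 0.1 percentage points analytically, and a full-scale
simulated cohort run through the pipeline in `paper_tally` mode lands
within 2 percentage points of every published staged tier.

### What the generator does not emulate

Per-patient heterogeneity in chain parameters, calendar-time effects
(the real data span 16 years of practice change), disease-diagnosis
strata, dose-dependent masking strength, serial correlation in
viability, and the published *events per patient* rate (0.385/0.365),
which was not a calibration target — the synthetic rate is ≈ 0.3 because
masking is drawn independently per visit. Passing tests on synthetic
cohorts therefore demonstrate correctness of the pipeline's estimators
under the stated generative assumptions, not the clinical
representativeness of any particular dataset.

## Numerical and interface choices

* Differential percentages must sum to 100 ± 0.5 (rounding tolerance,
  configurable); dose fields may be unknown (`None`), which is never
  treated as zero.
* Same-day examinations keep input order and emit a warning; rows
  violating invariants go to a rejects report with reasons, never
  silently dropped.
* Cohort ingestion accepts a clump count, a pre-assigned grade, or both;
  inconsistent pairs are rejected (auditability over repair).
* Degenerate inputs: empty multi-sample part → emergence and Markov
  stages are marked not estimable rather than erroring the whole fit;
  `p_NE = p_EN = 0` leaves the stationary distribution undefined.
* Problem sizes in the test suite: full-scale cohorts (9570 patients)
  for the staged-tier and nesting checks, 5000 patients for parameter
  recovery, 1000 series for the scanner/oracle comparison, smaller
  seeded cohorts elsewhere; the whole suite runs in well under a minute.

## Known limitations

* The extrapolation inherits the published design's assumption that the
  multi-sample subset's re-emergence propensity transfers to
  single-sample patients.
* What horizon the published Markov figures quantify is not stated;
  both the stationary and the next-step composite are reported and no
  attempt is made to match those two numbers.
* Etiology percentages cannot be compared against the published
  breakdown, whose columns sum to more than 100% with undefined
  denominators; this package reports mutually exclusive event-level
  fractions instead.
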