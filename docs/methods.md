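# Methods

## The assay and its two readouts

LuTHy-style screens test binary protein-protein interactions twice in one
workflow.  Proteins X and Y are expressed in mammalian cells as a NanoLuc
luciferase (NL) donor fusion and a ProteinA-mCitrine (PA-mCit) acceptor
fusion.  In intact cells, complex formation brings donor and acceptor within
resonance distance and shifts luminescence emission toward the acceptor's
band; after lysis, the ProteinA tag captures the bait on IgG surfaces and
any co-precipitated NL-tagged prey is read out by luminescence.

**BRET.**  With SWL and LWL the luminescence measured in the short
(370–480 nm) and long (520–570 nm) bands,

    BRET = LWL / SWL − Cf,          Cf = LWL(PA-NL) / SWL(PA-NL)

where Cf is the donor bleed-through: the long/short ratio of cells
expressing the donor-only PA-NL reference.  A PA-NL well scored with the Cf
derived from itself gives exactly 0 — a self-correction identity the test
suite enforces to machine precision.

**LuC.**  With NL_IN the input luminescence of the lysate and NL_OUT the
luminescence recovered after co-precipitation,

    PIR(PA-NL) = NL_OUT(PA-NL) / (v × NL_IN(PA-NL))
    LuC        = (NL_OUT / (v × NL_IN)) / PIR(PA-NL)

The volume factor v (default 3) reflects the liquid handling: three times
more lysate volume is precipitated than is read as input.  It is a named
configuration constant, overridable for other pipetting schemes.  The PA-NL
reference normalized against its own PIR gives exactly 1.

**Corrected ratios.**  Every pair is accompanied by two single-tag
controls: control 1 (free NL donor with the pair's acceptor) and control 2
(the pair's donor with free PA-mCit acceptor).  The corrected scores
subtract the *larger* of the two control ratios:

    cBRET = BRET − max(BRET_c1, BRET_c2)
    cLuC  = LuC  − max(LuC_c1,  LuC_c2)

Corrected values may be negative and are never clipped; the calling layer
handles signs.  Subtraction makes the correction translation-equivariant,
and all ratios are invariant under common channel rescaling (gain changes)
— both properties are enforced by tests.

Correction-factor scope: Cf and PIR are computed per plate when that plate
carries PA-NL wells, otherwise from the experiment's pooled PA-NL wells.
Pooling behaviour is configurable because reference placement varies
between laboratories; the scope actually used is recorded in the result.
Both factors use the mean of per-well ratios, not the ratio of summed
channels, so well-to-well expression differences cancel.

Replicate aggregation corrects within each replicate experiment first and
then averages the corrected values; raw channels are never averaged across
experiments.

## Calling and calibration

Calls are fixed-threshold, not p-value based.  Defaults: cBRET ≥ 0.01 and
cLuC ≥ 0.03 (inclusive).  Pairs in which *both* proteins are membrane
proteins use the more stringent 0.03 / 0.05 because membrane crowding
concentrates donor and acceptor in a two-dimensional compartment and
inflates proximity signals without a genuine complex.  Localization is a
two-level annotation (membrane / non-membrane) with non-membrane as the
default for unannotated proteins.  Pairs scored without both controls are
flagged `uncorrected` and refused by the caller.

`roc_analysis` supports recalibration on labeled reference panels: the
empirical ROC over the distinct score values (predictions use the same
inclusive ≥ convention as calling), trapezoidal AUC, the Hanley–McNeil
analytic standard error, and the Youden-optimal threshold *as a
suggestion*.  The published cutoffs are treated as configuration defaults
rather than recomputed, because reproducibility of calls takes precedence
over reverse-engineering the original optimality criterion, which is not
derivable from the ratios alone.  Tests verify the AUC against brute-force
concordant-pair counting on random instances, including heavy ties.

Fisher's exact test (used for sub-group recovery comparisons) delegates to
`scipy.stats.fisher_exact` with the conventional minimum-likelihood
two-sided definition; a test checks it against full hypergeometric
enumeration for small margins.  Replicate correlations (Pearson/Spearman)
use the usual t-approximation for two-tailed p-values and reject constant
input, where the coefficient is undefined.

## Titration fits

**Donor saturation.**  The response model is the one-site rectangular
hyperbola `BRET(r) = BRETmax · r / (BRET50 + r)` in the acceptor:donor
ratio r.  The underlying equilibrium occupancy is not exactly hyperbolic in
r when donor expression approaches KD, but the hyperbola is the standard
donor-saturation model and matches the "ratio at half-maximal BRET"
semantics of BRET50; at donor ≪ KD the two coincide.  The acceptor:donor
ratio itself is estimated as `(fluorescence/luminescence) /
tandem_reference_ratio`, using the PA-mCit-NL tandem fusion whose 1:1
stoichiometry calibrates the instrument's fluorescence-per-luminescence
scale.  Fitting: bounded least squares, initialization at
(max response, ratio nearest half-max), relative tolerance 1e-8.  Series
with fewer than 4 distinct ratios, spanning under a 4-fold range, or flat
responses are reported `converged=False` with a message — never a silent
number.  BRET50 is a *relative* affinity readout: it rank-correlates with
KD but is not an absolute KD estimate.

**Dose response.**  Four-parameter logistic on log10(dose):
`y = bottom + (top − bottom) / (1 + 10^(hill·(log10 EC50 − x)))` with
hill > 0 and `top` the high-dose asymptote.  Zero/vehicle doses are mapped
to a floor two decades below the lowest nonzero dose (configurable) — a
fitting convention, not a physical claim.  Direction (stimulation vs
inhibition, hence EC50 vs IC50) is the sign of top − bottom.  Up to three
seeded restarts with jittered initial values are attempted on solver
failure.

**Normalizations.**  Perturbation time courses are divided pointwise by
their untreated (or unheated) control series; time labels must match
exactly, with no interpolation, because the design normalizes like wells to
like wells.  Eight-orientation tagging matrices are divided by their
maximum entry, so the best tag placement reads 1.0 and negative entries
keep sign.

## Variant profiling

Partners measured against wild-type and variant baits are classified per
readout: **lost/gained** when the positive call flips between profiles;
**decreased/increased** when the call is retained positive in both, the
max-T adjusted resampling p is below α = 0.05, and |Δ| clears an effect
floor (defaults 0.01 cBRET / 0.03 cLuC, mirroring the calling cutoffs);
**unchanged** otherwise.  Both-negative partners are always unchanged —
movement below the detection threshold is not interpreted.  Partners
present in only one profile are reported `incomparable`, never dropped.
The classification is antisymmetric under swapping the profiles
(lost↔gained, decreased↔increased), which the tests check.

Two resampling routes:

* `resampling_many_to_one` is a seeded max-T permutation analog of a
  parametric many-to-one (Dunnett-style) post hoc comparison: pooled
  observations are permuted, the per-permutation maximum of the group-vs-
  control mean differences forms the reference distribution, and each
  group's adjusted p is the exceedance fraction.  Exact many-to-one
  quantiles are heavy machinery for 2-replicate plate designs; the
  permutation analog is assumption-light, controls the family-wise error
  (verified by simulation: ≤ 0.07 at nominal 0.05), and reduces to the
  two-sample permutation test for a single group (verified against full
  enumeration).
* Per-partner p-values inside `compare_variant_profiles` use a
  pooled-residual resampling null: replicate residuals are pooled across
  all partners of both profiles, null deltas are formed by resampling
  them, and the max over partners per resample provides family-wise
  adjustment.  With 2 replicates per partner, a within-partner permutation
  has only 6 arrangements and a minimum attainable p of 1/3; borrowing the
  replicate noise across the panel — defensible because all wells share
  the same instrument and workflow — is what makes per-partner inference
  possible at this design size.

## The simulator

The generator emulates the study conditions the pipeline is meant for, with
ground truth for every stage.  Defaults (chosen once; all invented values
are flagged here):

| parameter | default | rationale |
|---|---|---|
| pairs / replicates | 160 / 2 | two independent experiments, reference-set scale |
| fraction positive | 0.5 | balanced truth for ROC-style evaluation |
| log10 KD | uniform −9…−5 | low- to high-affinity span of published panels |
| donor / acceptor expression | lognormal, median 1e-7 / 2e-7 M, 50% CV | overexpression-level transfection with realistic well-to-well spread (invented) |
| Cf (bleed-through) | 0.2 | typical donor-only long/short ratio |
| PIR | 0.2 | plausible capture fraction of the reference (invented) |
| BRETmax | uniform 0.1–0.6 | orientation/geometry-dependent ceiling per pair |
| capture efficiency | 0.6 | fraction of captured bait retaining prey (invented) |
| LuC background | 0.01 | nonspecific precipitation floor (invented) |
| channel noise | 5% CV, multiplicative lognormal | luminescence noise scales with signal |
| volume factor | 3 | 15 µl precipitated vs 5 µl input |

Generative model per well: SWL ∝ donor expression; LWL = SWL × (Cf +
BRETmax × occupancy); cell fluorescence ∝ acceptor expression; NL_IN ∝
donor expression; NL_OUT = v × NL_IN × PIR × (background + capture ×
occupancy); each channel gets independent multiplicative noise.  Occupancy
is the exact two-species equilibrium solution (the smaller root of
`c² − c(D+A+KD) + DA = 0`, evaluated in the numerically stable form
`2A / (S + √(S²−4DA))`), zero for non-interacting pairs.  The algebra makes
the pipeline identities exact at zero noise: scored cBRET = BRETmax ×
occupancy and cLuC = capture × occupancy, which the regression tests check
to 1e-9.  LuC couples capture to occupancy linearly — the simplest model
consistent with co-precipitation efficacy depending on expression and
capture; capture saturation is deliberately omitted.  An optional additive
occupancy term for co-membrane pairs (off by default) reproduces the
membrane-crowding false-positive mechanism in the BRET channel only, since
crowding creates proximity without a precipitable complex.

Saturation titrations report the closed-form truth `r_half = 0.5 + KD/D`
(set occupancy = 1/2 in the quadratic); image pairs place a known ratio
field under an integer-pixel channel shift (wrap-around) with additive
Gaussian noise.

What the simulator does *not* emulate: cell-biological artifacts
(aggregation, mislocalization, trafficking), optical crosstalk beyond the
single Cf scalar, plate-position effects, or saturation of the capture
surface.  Passing the simulation benchmarks therefore demonstrates the
*computational* correctness of scoring, calling and fitting under the
stated noise model — not the biological error rates of a real screen.

## Imaging

Dual-view image pairs are registered by exhaustive integer-shift search
maximizing normalized cross-correlation on the overlap, ties broken toward
the smaller shift and then row-major; the rigid dual-view geometry makes
sub-pixel registration unnecessary, and a shift landing on the search-window
edge is flagged low-confidence rather than trusted.  The ratio map pipeline
is median filter (k×k, edge-replicated) → per-channel percentile background
subtraction (default 5th percentile; 0 disables subtraction) → threshold on
the short (donor) channel → per-pixel long/short division on the surviving
mask.  A positive threshold makes division by zero impossible by
construction; the threshold itself is data-dependent and must be chosen by
the user (a value just above the background tail of the short channel is a
reasonable starting point).  An empty mask is a valid result.

## Problem sizes and determinism

The test suite and the acceptance script run the benchmark screen (160
pairs × 2 replicates), 200 noisy titrations, a 20-pair affinity panel and a
20-partner variant panel; these sizes give stable statistics while keeping
a full run in seconds.  All stochastic components take explicit seeds;
identical parameters and seed reproduce datasets byte-identically.

## Known limitations

* The per-partner variant test borrows noise across partners; if replicate
  noise is strongly partner-dependent, its p-values are approximate.
* BRET50 estimates assume the titration reaches near-saturation; truncated
  grids are flagged but not extrapolated.
* The ROC standard error is analytic (Hanley–McNeil); bootstrap intervals
  are not provided.
* mCit_OUT is carried as a QC column only; no printed statistic uses it.
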