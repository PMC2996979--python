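# Methods

## The statistic: CpG observed/expected ratio

Animal DNA methylation occurs almost exclusively at CpG dinucleotides,
and 5-methylcytosine deaminates to thymine at a much higher rate than
unmethylated cytosine. Over evolutionary time, persistently methylated
sequence is therefore depleted of CpG: the observed/expected ratio

    CpGo/e = n_CpG / (n_C · n_G) · l² / (l − 1)

(with *l* the number of unambiguous nucleotides in the sequence) is
depressed where methylation has been chronic and sits near 1 where it
has been absent. Two controls accompany it, computed by the same
formula: GpCo/e, which has no depletion mechanism and should sit near 1
whatever the base composition, and TpGo/e, which absorbs the decay
product and should anticorrelate with CpGo/e.

Counting conventions: ambiguous bases (N and other IUPAC codes) are
excluded from *l* and from the base counts, and any dinucleotide window
containing one contributes to no count — any other convention would let
ambiguity codes contaminate the counts nondeterministically. A ratio
whose denominator vanishes (or with *l* < 2) is undefined and is
propagated as missing, never as zero: zero would masquerade as extreme
methylation. Undefined ratios are excluded from every downstream fit
and the exclusion count is logged.

The TpG check uses the Pearson product-moment correlation with the
standard t-based two-sided p-value. A rank correlation would serve as
well; the plain correlation is the conventional default and the choice
is isolated in one function.

## The mixture model

Transcriptome-wide, CpGo/e values C_i are modelled as a two-component
univariate normal mixture

    C_i ~ p₁·N(μ₁, σ₁²) + p₂·N(μ₂, σ₂²),  p₁ + p₂ = 1,

fit by EM (`NormalMixture.fit`). The lower-mean component collects
predicted hyper-methylated genes, the upper one predicted
hypo-methylated genes; a sequence is labelled by whichever component
claims posterior responsibility > 0.5 (ties to hyper-methylated).

Numerical choices:

- **Initialisation and restarts.** EM runs from the best of 20 seeded
  restarts. The first uses component means at the 25th/75th data
  quantiles; later restarts jitter the quantile pair uniformly.
  Initial sds are the pooled sd, initial weights uniform.
- **Convergence.** Relative log-likelihood change below 1e-8 or 1,000
  iterations. The log-likelihood path is retained and checked for
  monotonicity on every fit.
- **Variance floor.** Component sds are floored at 1e-6 × the data
  range, excluding degenerate spike components.
- **Canonical order.** Components are always reported in increasing-mean
  order, so label switching cannot leak into results.
- **k = 1** has the closed-form normal MLE and bypasses EM.
- The inner EM loop is compiled with numba; the parametric bootstrap
  refits the model hundreds of times and an interpreted loop would
  dominate the runtime of everything else combined.

**Model comparison.** The two-component fit is compared against the
single-normal null by the likelihood-ratio statistic
2·(logL₂ − logL₁). The usual χ² reference distribution is invalid for
mixture-order testing (the null sits on the boundary of the parameter
space and the extra component's weight is unidentified under it), so
`compare_models` reports the raw statistic, AIC/BIC for both models,
and a parametric-bootstrap p-value: datasets of the same size are
simulated from the fitted null, both models are refit to each, and the
p-value is the plus-one-corrected exceedance fraction
(b + 1)/(n_boot + 1). Default 99 replicates (the plus-one correction
is exact at round numbers minus one); bootstrap refits use 5 restarts —
single-normal data has no separated optima to miss.

The mixing weights are estimated freely. The classification accuracy
attainable at the fitted transcriptome geometry
(0.45·N(0.40, 0.12²) + 0.55·N(0.70, 0.21²)) is bounded by the Bayes
classifier under the generating densities, which achieves 0.823 — the
two components genuinely overlap, and tests benchmark EM-based
assignment against that optimum rather than against a round number.

## GO Slim functional comparison

Sequences are binned by the GO-Slim terms their GO annotations map to.
A sequence joins every bin any of its terms maps to, but at most once
per bin, so no gene is double-weighted within a category. Bins are
summarised as mean CpGo/e ± standard error (sample sd/√n; undefined for
singleton bins) and compared by one-way fixed-effects ANOVA followed by
Tukey's HSD. The Tukey–Kramer form
q = |μ̄_i − μ̄_j| / √(MSW/2 · (1/n_i + 1/n_j)) with the studentized-range
distribution handles the widely varying bin sizes; with exactly two
groups it reduces to the pooled two-sample comparison. Because a
sequence in several bins contributes one observation per bin,
observations are not strictly independent across bins; this mirrors
the binning rule and is recorded in the result's metadata rather than
corrected for. The GO→slim map is always an input file — slim sets are
versioned resources and none is bundled as ground truth.

## Assay simulators

**Methylation-sensitive PCR.** HpaII and MspI both recognise CCGG;
MspI cuts regardless of internal-CpG methylation, HpaII is blocked by
it. Digestion is simulated over an explicit per-cytosine methylation
state map: a site cuts under MspI always and under HpaII only when its
internal CpG (the second C) is unmethylated; amplification is predicted
iff no site inside the amplicon is cut, matching the all-or-nothing
presence/absence scoring of the assay. MspI sensitivity to outer-C
methylation is deliberately ignored — the assay's inference uses only
the internal-CpG distinction. Coordinates are 0-based half-open, and
sites are searched on the given strand only (CCGG is its own reverse
complement, so nothing is lost).

**Bisulfite sequencing.** Conversion is simulated per cytosine:
methylated Cs survive, unmethylated Cs convert to T independently with
probability 1 − failure_rate. Calling aligns each clone globally to the
untreated reference (match +1, mismatch −1, gap −2; clones below 60%
identity are rejected as off-locus) and reads each reference C:
CpG-context C→methylated / T→unmethylated; non-CpG-context T→converted
/ C→conversion failure; gaps and other bases are ambiguous. Ambiguous
calls are excluded from per-site fraction denominators (conservative —
the assay reports binary states). The pooled non-CpG conversion rate is
the completeness QC, expected at 100% for a successful treatment. Only
the converted sense strand is modelled, as clones of one strand's PCR
product are what gets sequenced.

## The synthetic-data generator

The generator realises the mechanism the statistic rests on: sequences
are built as iid bases at a configured GC content, then every CpG is
replaced by TpG independently with a per-sequence decay probability *d*
drawn from its class's normal (clamped to [0, 0.98]). Because each
conversion also removes one C from the o/e denominator, the expected
ratio is

    E[CpGo/e] ≈ (1 − d) · l / (l − (l − 1)·p_G·d),  p_G = gc/2,

not 1 − d (at d = 0.5, gc = 0.5 this is ≈ 0.571). `expected_cpg_oe` is
the analytic oracle and `decay_for_target_mean` inverts it; the same
bookkeeping shows GpCo/e is exactly compensated (GpC occurrences
destroyed by conversion balance the lost Cs), which is why the control
stays at 1 at every decay level. Decay acts on the represented strand
only — all statistics here are computed single-strandedly on transcript
sequences.

Defaults emulate the study population: 12,210 sequences of 300–900 bp
at GC 0.5, two classes with weights 0.45/0.55 and decay means solving
the expectation above for CpGo/e targets 0.40 and 0.70 (d ≈ 0.667 and
0.364), decay sds 0.10/0.18. Realised class sds exceed the decay-induced
spread because finite-length sequences add counting noise (≈0.10–0.14
in CpGo/e units at these lengths), so sequence populations are noisier
than the value-level mixture geometry; calibration checks that target
the exact component sds therefore sample the normal mixture directly
(`sample_mixture_values`). What the generator does not emulate: codon
or ORF structure, transition/transversion bias beyond CpG decay,
assembly artefacts, or annotation error — passing tests show the
statistics behave correctly under the stated mechanism, not that real
EST collections are this clean.

Bisulfite clone sets are generated from a reference amplicon (default
180 bp, a typical bisulfite-PCR product size) carrying an exact,
evenly spaced number of CpG sites; each clone draws an independent
methylation state per site from its configured probability and is then
converted in silico.

## Problem sizes and runtime

Default test and reproduction sizes are chosen so the statistical
check is decisive at the smallest adequate scale: the mixture
recovery/bootstrap runs at the full n = 12,000 with 99 replicates; the
law-of-large-numbers check uses 4,000 iid sequences (SE of the mean
≈ 0.002 against a ±0.02 band); control populations use 700–2,000
sequences; the Tukey type-I calibration uses 100 seeded replicates of
two n = 50 groups.

## Package shape

The inferential core follows the statsmodels convention — a
`NormalMixture` model object whose `fit()` returns a
`NormalMixtureResults` with estimates, likelihood, information
criteria and `summary()` — because that is the one place where a
fitted statistical model is the product. The surrounding stages
(I/O, dinucleotide metrics, category tests, assay simulators,
generator) are plain functions over small dataclasses, orchestrated by
the `cpgmeth` CLI; forcing them into a single Model/Results pair would
obscure rather than organise them.

## Known limitations

- The per-gene prediction is a population-genetic signal (historical
  methylation), not a direct measurement; genes with recent methylation
  changes are misclassified by construction.
- Mixing weights, not just means/sds, are estimated; with heavy
  component overlap the weight split is the least stable parameter.
- Tukey p-values treat multi-bin sequences as independent observations
  (see above).
- The bisulfite caller handles point differences and small indels via
  global alignment but is not designed for chimeric or truncated
  clones; those fail the identity floor and are dropped.
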