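# Methods

This note records the models the package implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate about real data.

## Isotopologue correction

A fragment's observed mass spectrum under a stable-isotope tracer is modeled
as a linear mixture: `s = M x`, with `x` the true label distribution over
m+0..m+n and `M` the correction matrix.  Column `j` (exactly `j` labeled
positions) is the convolution of

1. the natural-abundance mass-shift distribution of **all atoms except the
   `j` labeled positions** — computed element-by-element as the n-fold
   convolution of each element's single-atom isotope distribution — and
2. a `Binomial(j, p)` distribution for label retention at tracer purity `p`.

Unlabeled positions of the tracer element therefore carry natural abundance,
the standard convention for this correction; the fully unlabeled column of a
two-carbon fragment is `[(1−a)², 2a(1−a), a²]` with `a` the ¹³C abundance.

*Natural abundances* live in a versioned table (`isoflux.isotopes`,
version 2026.1): ¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038,
¹⁸O 0.00205, ²⁹Si 0.046832, ³⁰Si 0.030872, ³³S 0.0075 / ³⁴S 0.0425 /
³⁶S 0.0001, ³¹P only.  These are the standard terrestrial representative
values; instruments or labs that calibrate differently can pass their own
table.

*Tracer purity* defaults to 0.99, typical of commercial [U-¹³C] substrates,
and is always overridable.

*Observed range* `K` defaults to `n_tracer + 3` so that the ²⁹/³⁰Si and
³⁴S envelopes of TBDMS-derivatized GC/MS fragments are captured; columns are
truncated to rows 0..K and therefore sum to ≤ 1 (exactly 1 when K covers the
full support).

*Deconvolution* is non-negative least squares (scipy's `nnls`), renormalized
to the simplex, rather than a matrix inverse: with noise, unconstrained
inverses produce negative fractions.  The price is a small upward bias at
isotopologues whose true fraction is zero (the estimate sits on the
constraint boundary), of order the per-channel noise; averaging replicate
*spectra* before deconvolving shrinks this with 1/√n, whereas averaging
per-replicate solutions does not.  Measurements whose total intensity is
zero are rejected as empty rather than silently zero-filled.

*Kinetics* are summarized by the mono-exponential `x(t) = x_ss (1 − e^{−kt})`
fit with bounded least squares (`x_ss ∈ [0,1]`, `k ≥ 0`).  This is a summary
model, not a mechanistic one: real enrichment curves of downstream
metabolites are multi-exponential, and `k` should be read as an effective
turnover rate.

## First-turn label-propagation model

The simulator encodes the first turn of label flow only:

* **Glucose tracer.**  `g` of pyruvate is m+3; PDH makes acetyl-CoA m+2 with
  probability `f_pdh` (`a₂ = g·f_pdh`), carboxylation routes make
  oxaloacetate m+3 with probability `f_pc` (`o₃ = g·f_pc`).  Citrate
  condenses the two pools independently: m+2 `a₂(1−o₃)`, m+3 `o₃(1−a₂)`,
  m+5 `a₂o₃`.  Four-carbon intermediates carry m+3 = `o₃` directly and
  inherit m+2 = `a₂(1−o₃)` after one oxidative turn.
* **Glutamine tracer.**  Glutamate and 2-ketoglutarate are m+5 with
  probability `f_glnox`; oxidative decarboxylation yields citrate m+4
  (`(1−f_red)·f_glnox`), reductive carboxylation citrate m+5
  (`f_red·f_glnox`), and malate m+3 follows the oxidative route.  GSH
  inherits the glutamate label scaled by the newly-synthesized fraction
  `f_gsh`; GSSG is the random pairing of two GSH units
  (m+10 `p₅²`, m+5 `2p₅(1−p₅)`), which makes the simulated GSSG MID exactly
  the self-convolution of the GSH MID at every timepoint.

Each metabolite approaches steady state as `1 − e^{−k_met t}` with a shared
rate (default 0.1/min, putting the panel near plateau by the 4-hour
glutathione timepoint); the remainder stays at m+0 and fractions sum to 1
exactly.  **Not modeled:** multi-turn cycle scrambling, so species such as
GSH m+3 or GSSG m+6/m+8 (which require a second oxidative turn feeding
glutamate) are never generated; the model is a generator for testing
single-isotopologue readouts, not a flux-fitting model.

Flux-ratio indices are computed from replicate means at the latest sampled
timepoint and clamped to [0,1]; a vanishing denominator flags the index as
missing instead of raising, since a zero-labeled pool is a legitimate
biological outcome.

Default panel fragments are representative TBDMS-derivatized compositions
(e.g. citrate `C20H39O7Si3@6`, with `@n` the backbone carbons) and
underivatized species for the LC/MS glutathione branch; they stand in for
instrument-specific fragment lists, which users should supply for real data.

## Extracellular-flux bioenergetics

Plates carry per-well OCR/ECAR time series through the canonical injection
order basal → oligomycin → FCCP → rotenone+myxothiazol → monensin (monensin
optional; its absence disables the maximal-glycolysis state).  Phase
summaries average the last `cycles_per_phase` cycles (default 3, i.e. all of
a standard three-measurement phase) per well, normalize by well protein, and
aggregate as group mean ± SEM.  Derived components:

```
OCR_mito = basal − rotmyx     OCR_coupled = basal − oligomycin
OCR_leak = oligomycin − rotmyx   OCR_mito_max = FCCP − rotmyx
```

Noise can make these negative; they are floored at zero with a logged
warning rather than propagated.

ATP rates follow the published extracellular-flux bookkeeping.  The
`AssayConstants` defaults — P/O 2.486 for coupled respiration, 1 ATP per
lactate, 0.167 ATP per O atom credited to glycolysis-coupled oxidation,
1 H⁺ per O₂ from CO₂ hydration, bicarbonate pK 6.093, buffering power
0.1 mpH/pmol H⁺ — are configuration, not ground truth: buffering power in
particular must be calibrated per medium and instrument, and every unit test
uses explicit simple constants so that no external coefficient is ever load-
bearing in a correctness check.

The maximal state is defined as the corner point (J_ATPglyc under
rotenone/myxothiazol + monensin with the respiratory acidification term at
zero, J_ATPox from `OCR_mito_max − OCR_leak` under FCCP).  Two quantities the
figure-level vocabulary leaves open are fixed here as package definitions:
`%OXPHOS_max` is evaluated at that corner, and *fraction of capacity used*
is the basal total ATP rate over the sum of the two maxima (a length ratio,
not an area ratio).  Flexibility is the Euclidean length of
`{(x,y): x+y = J_ATP_basal, 0 ≤ x ≤ glyc_max, 0 ≤ y ≤ ox_max}`, computed in
closed form (√2 times the clipped x-extent) and verified against a
discretized oracle; capacity is `glyc_max · ox_max`.  Flexibility scales
linearly and capacity quadratically under a uniform rescaling of all rates,
and percentage shares are scale-free.

## Ranked lists and overlap testing

The ranking score is `sign(FC) · (−log₁₀ p)`.  A literal signed `log p`
would rank the most significant genes *last*; the −log₁₀ form puts
significant up-regulation at the top, which is what downstream preranked
analyses expect.  Screen hits ranked "most depleted to most enriched" use
the same score with depleted entries negative, emitted ascending; ties in p
break lexicographically by id.

The overlap test intersects the two id universes (warning on loss), counts
`|top-n(A) ∩ top-n(B)|` (optionally plus bottom ends), and builds the null
by shuffling list B's order; `p = (1 + #{null ≥ obs})/(1 + n_perm)` is
one-sided for enrichment.  Because the statistic is integer-valued, the test
is conservative where the null distribution is coarse: at N=1,000 and depth
50 the most extreme achievable size below 0.05 is ≈0.034, approaching the
nominal level only at depths where the hypergeometric null is fine-grained
(≈0.044 at depth 150).  Calibration checks therefore use such a depth; users
comparing very short lists should expect conservative p-values.

## Synthetic data

Generators are pure functions of a `ScenarioSpec`; each data kind draws from
its own stream split from the master seed, so adding a generator never
changes existing outputs.  Default sizes mirror the conditions the package
is meant for: 4 tracer replicates at σ = 0.01 on normalized intensities,
plates with 9 wells per group × 5 phases × 3 cycles at 5% relative noise
with ~20 µg protein per well (CV 10%), and ranked pairs over 1,000 genes
(a 19,038-gene microarray universe scaled down for speed; the overlap
statistics scale with n²/N, so nothing qualitative depends on N).

MID noise is i.i.d. Gaussian on the normalized spectrum, clipped at zero,
then scaled by a lognormal per-sample intensity.  The clip models an
instrument's non-negative baseline and leaves ~σ/√(2π) of spurious mass on
empty channels — a real effect of thresholded spectra that the recovery
tests deliberately retain.  What the generators do **not** emulate: peak
overlap and deconvolution artifacts, retention-time drift, heteroscedastic
shot noise, plate edge effects, or injection-transient cycles; passing
recovery tests therefore validates the arithmetic and its noise robustness,
not instrument-specific preprocessing.

## Pipeline and formats

Tables are plain CSV with `# key=value` header comments carrying the package
version, run seed, constants hash, and isotope-table version; floats are
written with `repr` and read back with round-trip parsing, so valid tables
round-trip losslessly and identical configurations produce byte-identical
bundles.  Configuration is a single YAML document; the library API is the
primary interface and the pipeline is a thin orchestration layer over it.
Units are fixed package-wide: time in minutes, OCR in pmol O₂/min, ECAR in
mpH/min, protein in µg, ATP rates in pmol ATP/min/µg protein, media fluxes
in mol/cell/h.

## Known limitations

* First-turn tracing only; no isotopomer (positional) resolution and no
  multi-turn scrambling species.
* The exponential kinetic fit is a summary, and `fit_labeling_kinetics`
  happily fits grossly non-monotone data (by design — flagging is left to
  the caller).
* ΔΔCt assumes amplification efficiency 2 exactly.
* ChIP enrichment implements one reading (ratio of ratios over the mean of
  negative regions) of an under-specified normalization convention.
* The permutation overlap test is conservative at coarse depths (see above).
* Bioenergetic coefficients are literature-style defaults, not calibrations;
  absolute J_ATP values are only as good as the buffering power and P/O
  supplied.
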