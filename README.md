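# isoflux

Quantitative machinery for comparing the metabolism of drug-resistant cancer
cell lines: correction and interpretation of ¹³C stable-isotope tracer data,
extracellular-flux bioenergetics (ATP production rates, capacity,
flexibility), permutation tests for ordered gene-list overlap, and the small
closed-form assay normalizations (ΔΔCt, tumor volume, media fluxes, fold
changes, ChIP enrichment) that surround them.

The package is aimed at cell-metabolism labs that run GC/MS–LC/MS tracer
experiments and Seahorse-style flux assays and want the downstream arithmetic
to be reusable, seeded, and tested — rather than living in per-project
spreadsheets.  Everything is exercisable on synthetic data with known ground
truth; no instrument exports are required to validate an analysis.

## What it computes

**Isotopologue correction** (`isoflux.isocorrect`).  A measured mass
isotopologue distribution (MID) mixes biological labeling with natural
isotope abundance and tracer impurity.  For a fragment with `n` labelable
positions the observed spectrum is `M x`, where column `j` of the correction
matrix `M` is

```
M[:, j] = natural(formula minus j labeled atoms) ⊛ Binomial(j, p)
```

(`p` = tracer isotopic purity, `⊛` = convolution).  The true fractional
enrichment `x` is recovered by non-negative least squares,
`argmin_{x≥0} ‖Mx − s‖₂`, renormalized to sum to 1.  Labeling kinetics are
summarized by `x(t) = x_ss (1 − e^{−kt})`.

**Tracer simulation and flux ratios** (`isoflux.tracesim`).  A first-turn
label-propagation model of glycolysis, the citric acid cycle, and glutathione
synthesis generates ground-truth MIDs under [U-¹³C]-glucose or
[U-¹³C]-glutamine, and flux-ratio indices read pathway activity from
corrected data: anaplerosis `cit m+3/(m+2 + m+3)`, reductive carboxylation
`cit m+5/(m+4 + m+5)`, de novo glutathione synthesis `GSH m+5 / glutamate m+5`.

**Bioenergetics** (`isoflux.bioenergetics`).  Phase-wise OCR/ECAR summaries
(basal, oligomycin, FCCP, rotenone+myxothiazol, monensin) yield respiration
components and ATP production rates,

```
J_ATPox   = OCR_coupled · 2 · P/O
J_ATPglyc = PPR_glyc · ATP/lactate + OCR_mito · 2 · (P/O)_glyc
PPR_glyc  = ECAR/BP − OCR_mito · (H⁺/O₂)_CO₂
```

and the bioenergetic space: plotting (J_ATPglyc, J_ATPox) inside the
rectangle spanned by the two maxima, **capacity** is the rectangle's area and
**flexibility** is the length of the constant-total-ATP segment through the
basal point clipped to the rectangle.

**Ranked-list overlap** (`isoflux.ranklist`).  Gene lists ranked by
`sign(FC) · (−log₁₀ p)` are compared by the size of their top-`n`
intersection against a null built by shuffling one list's order
(`p = (1 + #{null ≥ obs})/(1 + n_perm)`); under independence the expected
overlap at depth `n` out of `N` genes is `n²/N`.

## Worked example

```bash
python examples/tracer_fluxes.py
```

simulates six replicates of a [U-¹³C]-glutamine experiment for a cell line
with 25% reductive carboxylation and 50% de novo GSH synthesis, adds 1%
instrument noise, corrects the spectra, and prints

```
reductive_index      = 0.250   (generative truth 0.25)
gsh_synthesis_index  = 0.498   (generative truth 0.50)
```

— the pipeline recovers the planted pathway fractions from noisy raw
spectra.  `examples/bioenergetic_space.py` does the same for a two-group
plate assay:

```
control    J_ATPox=   14.9  J_ATPglyc=    7.0 %OXPHOS= 68.1  capacity=      698 flexibility=   28.5
resistant  J_ATPox=   23.5  J_ATPglyc=    4.4 %OXPHOS= 84.3  capacity=     1095 flexibility=   25.3
```

(rates in pmol ATP/min/µg protein): the "resistant" group's raised
respiration shows up as a higher oxidative share and a ~1.6× larger capacity.
The other scripts in `examples/` cover isotopologue correction, ranked-list
overlap, the closed-form assay metrics, and a full pipeline run.

## Layout

```
src/isoflux/
  isocorrect.py     correction matrices, NNLS deconvolution, kinetics
  tracesim.py       first-turn label-propagation model, flux-ratio indices
  bioenergetics.py  phase summaries, J_ATP, capacity/flexibility geometry
  ranklist.py       signed-significance ranking, permutation overlap test
  assay_metrics.py  ddCt, tumor volume, media flux, folds, ChIP enrichment
  synthdata.py      seeded generators with ground-truth sidecars
  io.py             CSV schemas (MID tables, plate tables)
  pipeline.py       declarative end-to-end runs with manifests
docs/methods.md     model assumptions, defaults, numerical choices, limits
examples/           one narrative script per capability
```
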