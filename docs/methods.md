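# Methods

This note documents the models implemented in `screenerr`, their
assumptions, the parameters that matter, and what the synthetic data do and
do not capture.

## Virion packaging and template-switching recombination

A virion packages two RNA genomes drawn independently from the plasmid
pool's abundance vector *p*. Free mixing is assumed — pooled transfection
delivers many plasmids per producer cell, so co-transfection structure is
ignored. The homozygous-virion fraction is then *h* = Σᵢ pᵢ² (1/11 ≈ 9.09%
for the equimolar 11-clone assay sublibrary).

Reverse transcription is modeled as at most **one effective template
switch** in the interval between the ORF and its barcode, a Bernoulli event
with per-virion probability *p*<sub>switch</sub>. The available data
constrain only the aggregate pair-uncoupling probability, not a per-base
crossover path, so a full crossover walk would add parameters without
evidence. A switch in a heterozygous virion yields the ORF of one genome
with the barcode of the other; the provirus is flagged chimeric exactly
when the resulting (ORF, BC) pair is not a library pairing. Homozygous
virions can never produce detectable chimeras, giving the detectable
fraction *f* = *p*<sub>switch</sub> · (1 − *h*).

**Calibration.** The default `fixed_per_design` switch rates invert that
relation at the measured assay frequencies: 0.2615/(10/11) = 0.2877 for the
720 bp layout and 0.0545/(10/11) = 0.0600 for the 96 bp layout. Per-base
linear and exponential modes are provided for extrapolation to other
homology lengths, least-squares fitted to the two calibration points; with
only two points no functional form is asserted as correct.

**The correction formula.** The analysis module implements the
conventional corrected estimate *f*<sub>true</sub> = *f*<sub>measured</sub>
· (1 + *h*) (26.15% → 28.53%). Note this is not the exact inverse of the
generative relation: inverting *f* = *p*(1 − *h*) gives *p* = 28.77% for
the long-homology case, ≈ 0.24 percentage points above the corrected
estimate. Both conventions are kept deliberately — the estimator is the
one conventionally reported, the generative inverse is available as
`calibrate_switch_rate` — and the discrepancy is documented here rather
than reconciled.

**Transduction.** Integrations per plated cell are Poisson(MOI); cells
with zero integrations are dropped, emulating puromycin selection
(zero-class removal only — selection kinetics are not modeled).
Multi-integrant cells contribute each provirus independently. In
`individual_then_pooled` mode each cell line receives virus packaged from a
single clone, so every virion is homozygous by construction and the
simulated PCR-control arm measures exactly 0% at any switch probability.

## Plasmid carryover

Copies per cell: c(t) = c₀ · input_fraction · 10^(−benzonase_logs) ·
2^(−PD) · e^(−δ·PD).

| parameter | default | units | rationale |
|---|---|---|---|
| `c0_std` | 70 | copies/cell | the only quantitative anchor: ~70-fold plasmid:provirus copy excess at ~1 provirus/cell in early reference samples |
| `dna_input_fraction` | 1.0 | — | protocol variants use 0.2 / 0.1 |
| `benzonase_log_reduction` | 3 at ≥ 50 U/ml, linear below | log₁₀ | doses of 50–1000 U/ml were equally effective; assays report detection limits, not a rate, so this is a working model |
| `decay_per_pd` (δ) | 0.5 | per PD | loss is faster than pure halving over the first ~2 PDs; a phenomenological stand-in — whether early loss is degradation or uneven uptake is unresolved |

With the defaults, the residual falls below 1% of c₀ by 6 doublings,
matching the observed complete dilution. Mass-to-copies arithmetic uses
650 Da per base pair and 6.6 pg per diploid genome (both exposed); the
10 kb vector length in the worked copy-ratio example is a stated working
assumption, not a measured value. qPCR relative quantitation is modeled as
simple additivity of proviral and plasmid copies per genome, normalized so
one provirus per genome reads 1.0 (the genomic control cancels).

## PCR with GC-dependent efficiency and saturation

Per-cycle efficiency: e(gc) = clip(e_max − slope·(gc − gc_ref), floor,
e_max), defaults e_max = 0.95, slope = 0.5, gc_ref = 0.40, floor = 0.5
(0.85 at 60% GC). Only the *direction* of the GC effect is empirically
constrained; slope and floor are free parameters with these documented
defaults, and GC-bias claims are therefore directional/property-based, not
numeric.

Each cycle's increment is damped by a shared factor s = max(0, 1 −
total/capacity) — a smooth logistic-style slowdown standing in for primer
and nucleotide depletion (an abrupt-stop variant is available behind a
flag for sensitivity analysis). The effective cycle count of a run is Σ s
over cycles; a sample with N-fold more input saturates log(N)/log(1+e)
cycles earlier (≈ 6.4 cycles for N = 70 at e = 0.95). Because every
effective cycle multiplies species *i* by (1 + eᵢ·s), two samples with
equal template totals experience identical saturation trajectories and the
GC bias cancels exactly in their ratio; the carryover-driven bias emerges
only from unequal totals. With the default efficiency parameters the
70-fold excess produces a ~0.5 log₂ spread across the 40→60% GC ladder —
a clear, strongly significant signature at mock-screen scale, on the
conservative side of the severalfold depletion real screens can show
(whose per-cycle GC penalties are not measurable from the available data).

Amplification runs to a fixed nominal cycle count (default 30) at fixed
capacity (default 10¹² molecules), so template-abundance differences
surface as effective-cycle differences. The real protocol's three nested
PCR rounds are collapsed into this single amplification: rounds 2–3
re-amplify an already saturated pool and the mechanism of interest lives in
round 1. Expectation mode iterates the deterministic recurrence;
stochastic mode draws binomial per-molecule duplications. Sequencing is a
multinomial draw over realized copies.

## Scenario generator

Defaults mirror the standard screen protocol: MOI 0.5, representation
1000 cells/element (200 for the mock hairpin screen, its documented
coverage), 10 population doublings, 30 bp barcodes, 500 reads/element.
Plated cells are representation·n/(1 − e^(−MOI)) so that the *surviving*
population carries the stated coverage.

Growth applies per-ORF selection coefficients *s* (relative growth
2^(1+s) per bulk doubling) with multinomial resampling of
representation·n cells at each whole doubling, so drift variance scales as
1/representation. Growth is tracked on the sparse joint (barcode element ×
actual ORF) table: a chimeric provirus grows with the fitness of the ORF
it is physically linked to while its reads report its barcode's element —
this is precisely the mechanism that degrades barcode concordance at high
recombination rates. Ground-truth log₂FC is defined on expected abundances
in the infinite-population limit (pds·sᵢ minus the renormalization
constant), so stochastic runs can be scored against it.

Reference modes: `early_cells` (carryover present at `reference_pd`,
default PD0 — the real protocol samples ~2 d post-transduction, whose PD
equivalent is unstated, so PD0 with the full initial load is the
conservative default), `equilibrated_cells` (the uninduced arm passaged
`pds` doublings; fitness off, drift on), `plasmid_mass_matched` (naked
plasmid at 200-fold template excess, the observed order of excess when
plasmid mass is matched to gDNA mass), and `linearized_plasmid_in_gdna`
(plasmid copies matched to the transduced sample's template copies, the
copy-matched reference that shows no bias). Carryover plasmid is
apportioned across subpools inversely to titer — equal cell representation
requires more supernatant volume from low-titer pools — reproducing the
inverse titer–abundance distortion (a 4-fold titer range with the default
load gives a ~2–10× subpool read spread).

## Numerical and design choices

- Normalization is counts-per-fixed-total (10⁶ by default); the simplest
  scheme consistent with distribution-level comparisons, configurable.
- log₂FC uses pseudocount 1 on normalized counts to guard zeros without
  compressing the mock screen's dynamic range.
- GC bins: exact strata when GC takes ≤ 10 distinct values (the mock
  ladder), otherwise equal-width 2.5-point bins over the observed range.
- The rate comparison defaults to an exact binomial test of the second
  sample's counts at the first sample's rate (construction chosen for the
  small-count assay comparison; Fisher's exact test is exposed as an
  alternative). No multiple-testing correction is applied anywhere.
- One global seed is expanded into per-stage substreams by hashing fixed
  stage labels, so a stage rerun in isolation reproduces its stream.
- Sign agreement treats log₂FC = 0 as nonnegative; single-barcode ORFs
  report NaN concordance.
- Recovery of ground truth is evaluated under a *graded* fitness ladder
  (continuous s across elements). Under a nearly-all-neutral fitness
  spec, rank correlation against truth is uninformative — hundreds of
  tied-at-zero truth values bound Spearman's ρ near 0.2 regardless of
  estimator quality — so the neutral-plus-enrichers case is instead
  checked by requiring configured enrichers to occupy the top ranks.

## Problem sizes

Simulation-backed tests use the mock library at representation 200
(~0.5 M plated cells per run) and 50-seed scenario grids; the
recombination-assay consistency checks use 20 seeds × 10⁵ proviruses.
These sizes put Monte-Carlo error well below the tested effect sizes while
keeping the full suite fast.

## What the synthetic data do not capture

Sequence-level reverse transcription (only aggregate pair uncoupling),
deletion-type intramolecular recombination between repeated promoters,
episomal replication or integration of carryover plasmid, polymerase
chemistry and PCR-generated chimeric amplicons (the assay's PCR control
showed none), primer thermodynamics, index hopping, sequencing error, and
cell-cycle or spatial growth structure. Passing tests therefore
demonstrate the *mechanisms* — undetectable homozygous recombination,
dilution kinetics, effective-cycle imbalance — under idealized sampling
noise, not the full noise floor of real screens.
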