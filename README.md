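# screenerr

Error models and diagnostics for pooled barcoded genetic screens in
mammalian cells.

Pooled retro/lentiviral screens read out the abundance of short DNA
barcodes (BCs) as proxies for the library elements (ORFs, shRNAs, gRNAs)
they are paired with. `screenerr` simulates and quantifies three systematic
error sources that corrupt that readout, and implements the statistical
procedures used to detect and correct them:

1. **Barcode–ORF recombination.** Retroviral particles package two RNA
   genomes; during reverse transcription the RT enzyme can switch templates
   within the homologous interval separating an ORF from its barcode. In a
   heterozygous virion (genomes from different clones) a switch produces a
   chimeric provirus whose barcode reports the wrong ORF. Because switches
   inside homozygous virions are invisible, the measured chimera frequency
   *f* understates the per-virion switch probability *p*:

       f_detectable = p · (1 − h),    h = Σᵢ pᵢ²  (homozygous-virion fraction)

   and the conventional corrected estimate of the true frequency is
   *f*<sub>true</sub> = *f*<sub>measured</sub> · (1 + *h*). For an equimolar
   11-clone pool, *h* = 1/11 ≈ 9.09%. The risk scales with the homology
   length between ORF and barcode (720 bp vs 96 bp in the two stock vector
   layouts, calibrated to measured frequencies of 26.15% and 5.45%).

2. **Packaging-plasmid carryover.** Residual transfection plasmid in viral
   supernatant is carried into the transduced culture and co-purifies with
   genomic DNA, so an early reference sample can contain ~70× more PCR
   template copies than its integrated proviruses. The excess halves every
   population doubling (plus a faster early decay) and is gone by ~6 PDs.
   Copy arithmetic: 5.8 pg of a 10 kb vector per 50 ng of gDNA ≈ 71 plasmid
   copies per proviral copy.

3. **GC bias from unequal effective PCR cycles.** Per-cycle amplification
   efficiency declines with template GC. That bias cancels between two
   samples amplified for the same number of *effective* cycles, but a
   template-rich (contaminated) reference saturates log(N)/log(1+e) cycles
   earlier than a clean endpoint sample, leaving a spurious negative
   correlation between GC content and log₂ fold change — GC-rich elements
   appear to deplete. Eliminating the template excess (Benzonase treatment,
   reduced transfection input, equilibrated or copy-matched references)
   abolishes the correlation.

The package provides a simulator for each stage (virion packaging and
template switching; carryover load and dilution; saturating GC-biased PCR
and multinomial sequencing), scenario generators that chain them into
complete synthetic screens (including a 1000-hairpin mock library in five
exact GC strata, 200 each at 40/45/50/55/60% GC), and analysis routines:
count normalization, log₂FC, per-ORF barcode concordance, recombination
frequency estimation with the homozygosity correction, an exact binomial
rate comparison, and GC-bias / subpool-distortion diagnostics.

## Worked example

```python
import numpy as np
import screenerr as se

# Recombination assay: 11 equimolar clones, long-homology (720 bp) layout,
# pooled packaging, 100k proviruses sequenced.
_, est = se.run_recomb_assay_scenario(11, "5BC", mode="pooled",
                                      n_sequenced=100_000, seed=1)
print(f"measured chimera frequency : {100*est.f_measured:.2f}%")
print(f"homozygous-virion fraction : {100*est.h:.2f}%")
print(f"corrected true frequency   : {100*est.f_true_est:.2f}%")

# Mock GC-ladder screen, contaminated vs clean reference.
lib = se.make_mock_shrna_library(np.random.default_rng(0))
for name, cfg in [
    ("contaminated reference ", se.ScenarioConfig(representation=200, seed=1)),
    ("Benzonase-clean        ", se.ScenarioConfig(representation=200, seed=1,
                                                  benzonase_units=500,
                                                  dna_input_fraction=0.1)),
]:
    ds = se.run_screen_scenario(cfg, lib)
    rep = ds.gc_bias()
    print(f"{name}: r = {rep.pearson_r:+.3f}, p = {rep.p_value:.2e}, "
          f"effective-cycle gap = {ds.n_eff_end - ds.n_eff_ref:.2f}")
```

Output:

```
measured chimera frequency : 25.84%
homozygous-virion fraction : 9.09%
corrected true frequency   : 28.18%
contaminated reference : r = -0.390, p = 1.26e-37, effective-cycle gap = 6.21
Benzonase-clean        : r = +0.020, p = 5.28e-01, effective-cycle gap = 0.01
```

The measured 25.84% is one Monte-Carlo draw around the calibrated
detectable fraction 0.2877 × (10/11) ≈ 26.15%; the correction inflates it
by the 9.09% of virions whose recombination is undetectable. In the mock
screen, the ~70-copies-per-cell carryover costs the reference sample ~6
effective PCR cycles, inducing a strongly significant negative GC trend
that disappears when the plasmid is eliminated.

A command-line interface mirrors the library (`screenerr make-library`,
`recomb-assay`, `simulate-screen`, `gc-bias`, `contamination`); all outputs
are TSV with a provenance header and are byte-identical under a fixed
`--seed`.

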