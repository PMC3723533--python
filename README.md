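# palinconv

Phylogeny-based analysis of gene-conversion dynamics in Y-chromosomal
palindromes, for molecular-evolution researchers working with paralogous
sequence variants (PSVs) in segmental duplications.

The male-specific region of the human Y chromosome carries large inverted
repeats ("palindromes") whose arms stay >99.9% identical through arm-to-arm
gene conversion. In a haploid chromosome a PSV behaves like a pseudo-diploid
genotype: pseudoheterozygous (0/1) when the arms differ, pseudohomozygous
(0/0 or 1/1) when conversion has homogenised them. Genotyping PSVs across
many chromosomes whose relationships in the SNP-defined Y phylogeny are
known turns these states into a record of historical conversion events.

`palinconv` implements that analysis end to end:

* **Minimum-event calling** — each PSV is a single-origin character; its
  0/0 → 0/1 mutation is placed at the MRCA of derived-allele carriers and
  the minimum number of conversion events is found by Sankoff-style dynamic
  programming under a directed transition system (0/1 → 0/0 and 0/1 → 1/1
  cost 1; pseudohomozygous states are absorbing; no recurrent mutation).
* **Bias statistics** — 1-df goodness-of-fit χ² against a 1:1 split for
  direction (to-ancestral vs to-derived) and GC class (fixes S = {G,C} vs
  fixes W = {A,T}); 2×2 χ² with Yates correction for arm-vs-spacer
  contrasts.
* **Rates** — events divided by a generation budget calibrated from backbone
  resequencing (95 substitutions ≙ 52,000 generations over 47 chromosomes),
  with lower/upper bounds for multiply-sampled haplogroups.
* **Phase analysis** — arm orientation vs a reference phase (SAME /
  INVERTED / UNINFORMATIVE / MOSAIC), minimum-flip inversion parsimony on
  the tree, and minimum co-conversion tracts: maximal runs of adjacent
  converted PSVs whose fixed alleles match a single arm-specific reference
  haplotype, with bp spans as minimum tract lengths.
* **Interspecific comparisons** — arm/spacer divergence from triad
  (human/chimp/gorilla) alignments, outgroup-polarised W↔S replacement
  tables with CpG/TpG/CpA masking, GC-content contrasts, and ≥5-read /
  Q≥20 consensus calling from pileup evidence.
* **Forward simulator** — generates every input (tree, genotypes, phases,
  triad alignment) with a complete ground-truth log, so each stage is
  testable without external data.

## Worked example

```python
from palinconv import datasets, gof_chisq, rate_range

c = datasets.CONVERSION_COUNTS                    # bundled survey tallies
direction = gof_chisq(c["to_ancestral"], c["to_derived"])
gc = gof_chisq(c["fixes_S"], c["fixes_W"])
rates = rate_range(c["total"], datasets.GENERATION_BUDGET)
print(f"{direction.chi2:.2f} {direction.p:.4f}")
print(f"{gc.chi2:.2f} {gc.p:.2e}")
print(f"{rates.rate_lower:.2g} {rates.rate_upper:.2g}")
```

prints

```
4.63 0.0314
19.25 1.14e-05
0.00029 0.00083
```

— the 86:60 split towards ancestral states is significant at p ≈ 0.031, the
59:20 split towards strong bases at p ≈ 1.1×10⁻⁵, and the 146 events over
the 175,000–505,500-generation budget give a conversion rate of roughly
2.9–8.3×10⁻⁴ events per generation. The scripts in `examples/` walk through
each capability the same way: event calling on a toy tree, bias and rate
statistics, tract and inversion inference, interspecific tables, and a
simulated end-to-end pipeline run.

A thin CLI mirrors the stages (`palinconv simulate | call-conversions |
test-bias | estimate-rate | phase | interspecific | run-all`).

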