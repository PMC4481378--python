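# ricechip

Design-side tooling for **genic, single-copy-gene SNP genotyping arrays in
rice**, plus the two analyses such arrays are mostly used for in breeding
programmes: background-recovery estimation in marker-assisted backcross
lines, and window-haplotype phylogenetics of germplasm panels.

High-density SNP chips built from random genome-wide variants suffer from
cross-hybridisation when a probe's flanking sequence occurs in more than
one place. Restricting the design to single-copy (SC) genes — genes with
no paralog above a similarity threshold anywhere in the genome — removes
that redundancy. The package implements the whole desk pipeline:

- **copy-number mining** (`ricechip.copynumber`): all-vs-all local
  alignment (Smith–Waterman, affine gaps, +2/−3, gap 5/2) with
  Karlin–Altschul bit scores, `bits = (λ·S − ln K)/ln 2`; genes linked by
  any inter-gene hit ≥ 200 bits form multi-copy (MC) paralog families
  (connected components), the rest are SC. SC genes partition into
  conserved wheat–rice orthologs (CSCWR) vs rice-unique (SCR), with
  agronomic cloned genes (AGCR) and MC controls (MCR) as separate lists.
- **SNP selection** (`ricechip.snpselect`): bi-allelic SNPs from
  alignments or VCF, kept only when the ±35 bp window is fully inside the
  gene and free of any other variant; codon-level
  synonymous/non-synonymous annotation from GFF3 gene models; manifest
  summary statistics (per-category SNPs/gene, per-chromosome totals,
  region shares, adjacent-SNP spacing).
- **probe design** (`ricechip.probes`): 71-mer forward/reverse probes
  with the SNP at position 36, scored for convertibility by a documented
  deterministic surrogate (GC composition, homopolymer runs, 35-mer flank
  uniqueness); inclusion iff best score > 0.30, "recommended" at ≥ 0.6.
- **genotype QC** (`ricechip.qc`): call rates, strict DQC > 0.85 and
  marker call-rate > 0.95 filtering, replicate concordance.
- **backcross analysis** (`ricechip.backcross`): marker origins (R/D/H/M)
  against the two parents, recovery % = 100·(R + 0.5·H)/(R + H + D)
  genome-wide and per chromosome, donor-segment BED painting, per-gene
  haplotype recovery over an agronomic gene list.
- **phylogenetics** (`ricechip.phylo`): 5-marker window haplotypes,
  pairwise mismatch distances with pairwise deletion, canonical
  Saitou–Nei neighbour joining, deterministic Newick output.
- **simulation** (`ricechip.simulate`): seeded generators for gene
  families, SNP layouts with known survivor truth, Haldane-model
  backcross populations with known donor fractions, and genotype
  matrices with controlled missingness.

## Worked example

```python
import numpy as np
from ricechip import backcross as bc, simulate as sim

# 30 BC2 lines on a rice-like genome (12 chromosomes, 100 markers each)
matrix, truth = sim.simulate_backcross(
    n_generations=2, n_lines=30, markers_per_chrom=100, seed=97)

report = bc.analyze_line(matrix, "line_001", "recipient", "donor")
print(f"overall recovery {report.overall_pct:.1f}% "
      f"(true {100 * (1 - truth.donor_fraction[0]):.1f}%)")
print("chr9 recovery", round(report.per_chrom_pct["chr9"], 1))
print("donor segments", report.donor_segments[:2])
```

prints

```
overall recovery 82.4% (true 82.3%)
chr9 recovery 87.5
donor segments [('chr1', 5400000, 18300000, 'het'), ('chr1', 23700000, 25500000, 'het')]
```

i.e. the marker-based estimate for this BC2 line (82.4 %) matches its
realised recipient fraction (82.3 %; the population expectation for BC2
is 87.5 %), and the residual donor chromatin — still heterozygous in a
backcross line — is painted as 0-based half-open intervals whose
boundaries sit midway between the bounding discordant markers.

The same toolkit is exposed as a CLI
(`ricechip copynum|snpselect|probes|qc|background|phylo|simulate ...`).

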