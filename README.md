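# allelequant

Measuring how strongly *individual* HLA class I alleles are expressed is
harder than measuring HLA-A/B/C in bulk: the loci are paralogous and the
alleles within a locus differ by a handful of nucleotides, so ordinary
primers and pan-class-I antibodies cannot tell them apart. `allelequant`
implements the complete computational chain for allele-specific
expression measurement:

- **`allele_db`** — an IMGT/HLA-style cDNA database with ATG-anchored
  coordinates (+1 = A of the start codon, no zero) and exon models, plus
  a scan for *discriminating positions*: columns where a target allele
  differs from every other allele in the family.
- **`primer_design`** — ARMS (amplification-refractory) assay design: a
  primer's 3′-terminal base is placed on a discriminating position so
  extension fails on non-target alleles. Candidates are screened for
  length, nearest-neighbor melting temperature, amplicon size and — by
  in-silico PCR against the whole database — cross-reactivity. A
  long-range mode designs locus-specific pairs anchored in within-locus
  conserved regions whose amplicon spans every exon–exon junction, so
  splice variants would appear as shorter products. An independent
  validator (`validate_pair`) re-checks every constraint with separate
  code.
- **`qpcr_quant`** — absolute quantification: plasmid dilution series →
  standard curve CT = b + m·log10(copies) → Pfaffl efficiency
  E = 10^(−1/m) with QC (floor 1.92, warning band below 1.96) → copy
  numbers → target/reference ratios → geometric means across
  experiments → fold-induction kinetics.
- **`flow_quant`** — quantitative flow cytometry: a log–log bead
  calibration maps MFI to antibody-binding capacity (ABC, antibodies per
  cell); a semi-quantitative scale grades specific/isotype MFI ratios
  into −, +/−, 1+, 2+, 3+, 4+ at thresholds 3, 10, 30, 50, 100.
- **`cdc_scoring`** — complement-dependent microcytotoxicity: percent
  dead = 100·red/(red+green), unweighted well averaging, positive call
  strictly above 50 % killing, low-count flags below 200 cells/well.
- **`synthetic_data`** — generators for every input with recorded ground
  truth (engineered discriminating SNPs, known curve parameters and copy
  numbers, known ABC values, binomial kill fractions), used by the test
  suite for end-to-end recovery checks.
- **`pipeline` / `allelequant` CLI** — orchestration, YAML run configs,
  and the shipped panel of validated HLA class I assays.

## Worked example

```bash
allelequant simulate --seed 1 --outdir fixtures/
allelequant qpcr --wells fixtures/wells.tsv --plasmid-bp 4031 --out qpcr.json
```

The simulated scenario carries six typed alleles plus the `FBXL12`
reference gene over a 0/24/48/72 h stimulation course in three
experiments. The recovered 72 h fold-inductions (from `qpcr.json`,
truth in parentheses):

```
A*01:01  8.87 (8.9)   A*02:01 10.48 (10.7)
B*01:01 29.63 (30.1)  B*02:01 40.05 (41.8)
C*01:01 18.27 (18.6)  C*02:01  5.47 (5.4)
```

i.e. with CT noise σ = 0.1 the full chain — curve fit, efficiency QC,
copy estimation, reference normalization, geometric-mean combining —
recovers the programmed inductions within a few percent. Designing an
allele-specific assay against the simulated family:

```bash
allelequant design --db fixtures/alleles.fasta --target "A*01:01" --config design.yaml
```

returns ranked primer pairs whose 3′ ends sit on the allele's engineered
discriminating SNP, each re-validated to have no predicted product on
any of the other eleven alleles.

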