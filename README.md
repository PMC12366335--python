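# metatraits

Community-level statistics for shotgun soil metagenomes, built for studies
that contrast microbial communities across land uses (e.g. urban greenspace
vs natural arid soils). The package turns the tabular outputs of a standard
metagenomics toolchain — single-copy-gene coverages, gene catalogs with
read counts, ribosomal-protein coding sequences, vOTU abundance tables with
lifestyle labels and host links — into:

* **genomic life-history traits** per sample: average genome size (AGS),
  average 16S rRNA copy number (ACN), GC content mean and variance, codon
  usage bias (CUB), proportion of unannotated genes, and sugar-acid
  preference (SAP);
* **normalized and aggregated functional abundances**: RPKM and
  reads-per-base-per-million, category rollups (CAZy substrates, N-cycle
  processes, heavy metals, drug classes), prevalence/abundance filtering,
  rarefaction and richness;
* **virus–host dynamics**: per-sample virus–host ratios (VHR), Pearson
  coupling between each virus and its predicted host, VHR-vs-host
  correlations, virulent/temperate abundance ratios, and host-abundance vs
  viral-link profiles;
* **permutation-based community comparisons**: Bray–Curtis dissimilarity
  and a PERMANOVA whose null exchanges whole sites between groups, plus a
  site-level permutation test for scalar traits.

A synthetic-community generator with known ground truth
(`metatraits.synthetic`) stands in for real sequencing data, so every
estimator can be validated by parameter recovery.

## The estimators

With per-sample coverages `c_1..c_35` of 35 universal single-copy gene
families, total sequenced bases `B` and 16S coverage `c_16S`:

    genome equivalents  G = mean(c_1..c_35)
    AGS = B / G                   ACN = c_16S / G

Codon usage bias uses the effective number of codons over the 59
synonymous codons (18 amino-acid families, degeneracies 2/3/4/6). With
Wright's per-family homozygosity `F̂ = (n·Σp_i² − 1)/(n − 1)`,

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆        (capped to [20, 61])

ENC′ replaces `F̂` by the chi-square deviation of observed codon usage from
the usage expected under a background nucleotide composition,
`F′ = (χ² + n − m)/(m(n − 1))`, and reduces exactly to ENC when the
background is uniform. CUB = 1 / mean(ENC′ over ribosomal protein genes).

Normalization follows `RPKM = C / ((L/1000)·(N/10⁶))` and
reads-per-base-per-million = RPKM/1000. PERMANOVA partitions squared
Bray–Curtis distances (`R² = SS_between/SS_total`,
`F = (SS_between/(a−1))/(SS_within/(n−a))`) with significance from
permutations that move whole sites between groups, the exchangeable unit
in a nested urban/natural design.

## Worked example

```
$ metatraits all --seed 1 --outdir runs/demo
$ cat runs/demo/report.txt
metatraits run summary
======================
trait means [natural]: acn=4.001, ags_bp=4.049e+06, cub=0.01751, gc_mean=0.6188, gc_var=0.00637, p_unannotated=0.5376, sap_unweighted=1.264, sap_weighted=1.264
trait means [urban]: acn=3.945, ags_bp=3.928e+06, cub=0.0176, gc_mean=0.623, gc_var=0.006785, p_unannotated=0.5375, sap_unweighted=1.264, sap_weighted=1.264
virulent/temperate ratio [natural]: 1.056
virulent/temperate ratio [urban]: 0.775
PERMANOVA (site_exchange): R2=0.558 F=20.184 p=0.1
```

This simulates the default community (50 genomes, 18 samples over 6 sites,
200 vOTUs), then estimates traits from the simulated sequencing summaries:
mean AGS ≈ 4.0 Mb and ACN ≈ 4.0 recover the generator's abundance-weighted
truth (the run's maximum AGS recovery error is 0.6%); CUB ≈ 0.0176 sits
between the uniform-usage floor (1/61 ≈ 0.0164) and the full-bias ceiling
(1/20 = 0.05), matching the moderate synonymous bias the generator plants.
The PERMANOVA detects the planted urbanization effect (R² = 0.56) at the
smallest p its 20 exhaustive site exchanges allow (2/20 = 0.1).

Library use is just as direct:

```python
>>> from metatraits import enc, enc_prime, simulate_codon_counts
>>> gene = simulate_codon_counts(bias=0.5, n_genes=1, codons_per_gene=300, seed=4)[0]
>>> round(enc(gene), 3)
35.609
>>> round(enc_prime(gene, [0.25, 0.25, 0.25, 0.25]), 3)   # uniform background
35.609
```

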