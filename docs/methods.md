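# Methods

## Scope and data model

`metatraits` computes community-level statistics that, in a real study,
would sit downstream of read QC, assembly, gene calling, mapping and
database annotation. None of those upstream tools are wrapped: the package
consumes their *tabular* products — coverage tables, count matrices,
coding sequences, vOTU tables with lifestyle and host annotations, and a
sample design (sample → site → urban/natural group). A synthetic-community
generator produces all of these with known ground truth, which is what the
test suite exercises.

## Synthetic community generator

The generator emulates an arid-soil metagenome study at toy scale.

* **Genome panel** — `n` genomes with lognormal lengths
  (default `mu = ln(4·10⁶)`, `sigma = 0.35`; median 4 Mb, the range typical
  of soil bacteria), Beta(30, 20) GC fractions (centred near 0.60), and
  uniform-integer rRNA operon counts in 1..7 (oligotroph to copiotroph).
  Every genome carries exactly one copy of each of 35 abstract universal
  single-copy families — the defining property of the genome-equivalents
  estimator; family identity is irrelevant to it and kept abstract.
* **Abundances** — log-normal: a genome baseline (sd 1.0), a site random
  effect (sd 0.3), a per-sample residual (sd 0.2), and an urban-vs-natural
  shift of ±`group_effect`/2 (default 0.8) applied to a random half of the
  genomes with random sign. The generator for this matrix exists because
  every downstream stage consumes genome-copy abundances; its site/group
  structure is what the comparison stage is meant to detect.
* **Sequencing digest** — the noiseless contract is exact: every
  single-copy coverage equals `κ·Σ a_g`, 16S coverage `κ·Σ a_g·rrn_g`,
  total bases `κ·Σ a_g·L_g` (default `κ = 20`, putting single-copy
  coverage in the hundreds-to-thousands range of real shotgun depth).
  Poisson noise, when enabled, replaces coverages by Poisson draws around
  those means. Per-read GC is the source genome's GC plus Gaussian jitter
  (sd 0.05) truncated to (0, 1), with genomes drawn ∝ `a_g·L_g`
  (2000 reads per sample by default).
* **Gene catalog** — lognormal in-frame gene lengths (median 900 bp);
  one category label per gene drawn from a scheme whose unassigned
  remainder is the unannotated fraction (default 54%, typical of soil
  catalogs); counts are multinomial draws of 200 000 reads per sample from
  gene relative abundances shared across samples.
* **Ribosomal codon tables** — amino acids uniform over the 18 synonymous
  families; within a family the codon distribution interpolates between
  uniform (bias 0) and a point mass on the lexicographically first codon
  (bias 1): `p = (1−b)/m + b·1[preferred]`. Default bias 0.3, 20 genes of
  200 codons per sample. Serialized as shuffled concatenations of codons,
  so FASTA round trips reproduce the tables exactly.
* **Virus–host matrix** — each vOTU picks a uniform host genome; temperate
  vOTUs (default 65%, matching the temperate-dominated character of soil
  viromes) follow `v = α·h` (lysogenic co-replication, r = +1 noiselessly);
  virulent vOTUs are either linearly anti-coupled
  `v = c − β·h` with `c = β·(max h + mean h)` so `v > 0` and r = −1
  noiselessly, or (with probability 0.3) independent lognormal series
  (r ≈ 0). The mixture produces both the strongly-negative and the
  near-zero modes seen in natural-soil correlation distributions.
  Multiplicative Gaussian noise (default sd 0.2) perturbs all entries.

Randomness: one root seed; each generator derives a named substream
(CRC32-keyed `SeedSequence`), so adding a stage never shifts another
stage's stream and fixtures are byte-identical across runs.

What the generator does **not** emulate: read-level errors, assembly and
binning artifacts, compositional coupling between taxa induced by
sequencing depth, annotation false positives, or hosts shared by
cross-reacting virus clusters. Passing recovery tests therefore
demonstrates estimator correctness on clean inputs, not robustness to
those real-data pathologies.

## Trait estimators

* **Genome equivalents** = arithmetic mean of the 35 single-copy family
  coverages; AGS = total bases / genome equivalents; ACN = 16S coverage /
  genome equivalents. On noiseless input these equal the
  abundance-weighted community means exactly; with Poisson noise at
  single-copy coverage ≥ 10 they recover the truth within a few percent.
* **GC statistics** — mean and *population* (divide-by-N) variance of the
  per-read GC pool; the variance describes the read pool itself, not an
  inferential estimate, and reads are equally weighted (fixture reads are
  near-constant length).
* **ENC** — Wright's estimator on 59 synonymous codons. Conventions the
  literature leaves open, all recorded in the run metadata: Ile is the
  single 3-fold family; Leu/Ser/Arg are kept as 6-fold families; families
  with fewer than 2 observations are excluded from their class mean; a
  completely unobserved 3-fold class is imputed as the mean of the 2-fold
  and 4-fold class means; the result is capped to [20, 61].
* **ENC′** — `F′ = (χ² + n − m)/(m(n−1))` with expected within-family
  codon frequencies built from a background (A, C, G, T) composition as
  position-wise products. This reduces *algebraically* to Wright's `F̂`
  under a uniform background — the tested contract — rather than claiming
  numeric identity with any particular published implementation. `F′` is
  floored at 0 (it can go slightly negative when `n < m` under a skewed
  background); the floor cannot trigger under a uniform background.
  When no background is supplied, CUB uses the pooled composition of the
  genes themselves — the composition the correction is meant to remove.
* **CUB** = 1 / mean(ENC′ over ribosomal protein genes) ∈ [1/61, 1/20].
* **SAP** — weighted and unweighted sugar/amino-acid decomposition
  abundance ratios. The weighting scheme is pluggable (a `weight` column
  in the pathway map); the default, `w_g = 1/(number of pathways
  containing g)`, avoids double-counting shared genes. This default is a
  package choice, not an assertion about any published scheme.
* Missing inputs yield NaN trait entries — flagged missing, never silently
  zero.

## Abundance tables

RPKM = `C/((L/1000)(N/10⁶))`; reads-per-base-per-million = RPKM/1000.
Totals `N` are total mapped reads per sample and must be supplied
explicitly; falling back to column sums is logged loudly. Aggregation
duplicates a multi-label feature's value into each of its categories
(the usual CAZy-substrate rollup); an even-split policy is selectable.
The prevalence/abundance filter removes features below 10% prevalence
**and** below 10⁻⁵ mean relative abundance — the conjunctive reading of
the usual filter phrasing; an OR rule is available by flag, and the mean
is taken across all samples (another documented choice). Rarefaction is a
single multivariate-hypergeometric draw per call (averaging is the
caller's loop, keeping seeds explicit); `expected_richness` is its
analytic twin, `E[S] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d))`.

## Virus–host statistics

VHR = virus/host relative abundance per sample, missing where the host is
absent (the presence gate; the threshold defaults to > 0 and is
configurable because pseudo-counted workflows rarely produce exact
zeros). All correlations are Pearson, require ≥ 5 joint observations
(configurable), and are reported *missing* — never 0 — when a series is
constant; exact proportional coupling makes VHR constant, so its
host-correlation is missing by construction, and excluded-pair counts are
always reported. The host-link profile classifies (host, sample) points
by median splits of both axes; medians are a neutral stand-in for the
visual cluster boundaries such plots are usually read with.

## Community comparison

Anderson's formulation: squared distances enter the sums of squares;
`SS_total = Σ_{i<j} d²ᵢⱼ/n`, `SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g`,
`R² = SS_between/SS_total`, pseudo-F with (a−1, n−a) degrees of freedom.
Because sites are nested within urbanization, free permutation of samples
would test the wrong null; the default `site_exchange` scheme reassigns
group labels to whole sites (samples move with their site), enumerating
all `C(n_sites, n_urban_sites)` distinct assignments exhaustively when
that number does not exceed the requested permutation count, and sampling
with the "+1" convention otherwise. The observed assignment is always part
of the null, so p > 0. With the default 6-site design there are 20
assignments and the attainable p floor is 2/20 = 0.1 — a property of small
nested designs, not of the implementation. The scalar-trait test uses the
same machinery on site means (difference of group means of site means,
two-sided), standing in for a mixed model with site as a random effect;
likelihood-based mixed models are deliberately out of scope.

Permutation streams are keyed to lexicographically sorted sample ids, so
results are invariant to input ordering under a fixed seed.

## Numerical and design notes

* TSV floats are written with `%.17g`, so fixtures round-trip IEEE doubles
  exactly and equal-seed runs are byte-identical (verified by SHA-256
  manifests).
* The run report omits the output path from its config echo so equal-seed
  runs in different directories produce identical manifests.
* Pipeline stages communicate only through files; piecewise and monolithic
  runs yield identical artifacts.
* Default problem sizes (50 genomes, 18 samples, 6 sites, 2000 genes,
  200 vOTUs) keep a full run under a minute on one core while leaving all
  estimators in their operating regimes (single-copy coverage ≫ 10,
  ≥ 5 samples per correlation, ≥ 2 sites per group).

## Known limitations

* Two-group designs only for the site-exchange permutation schemes.
* The 35 single-copy families are abstract indices; no marker-gene
  detection is performed.
* ENC′ background correction assumes position-independent base
  composition within codons.
* Lifestyle labels, host links and category label maps are taken as given;
  their upstream error rates (lifestyle predictable for a minority of real
  viral contigs, hosts for fewer) are outside the model, so real-data
  correlation distributions will be noisier and sparser than synthetic
  ones.
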