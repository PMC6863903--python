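# Methods

This note documents the models implemented in `strainpop`, the assumptions
they make, the defaults and why, and what the synthetic-data tests do and do
not demonstrate about real data.

## Pooled-read diversity estimators

`popgen.pi_intra` evaluates per-site heterozygosity from raw allele counts:
two reads drawn *without replacement* at a site (the C_i−1 denominator makes
the single-site estimator unbiased for 2f(1−f) under binomial read
sampling at true allele frequency f; the test suite verifies this to 3
standard errors at 10× and 100× coverage). `popgen.pi_inter` draws one read
from each sample independently. Both sums run over the whole genome, so the
normalizing constant |G| is the full core-genome length *including
monomorphic sites*, not the SNV count — this is what places per-site π in
the 10⁻⁶–10⁻³ range for realistic communities. Sites with coverage below 2
(intra) or 1 (inter) cannot contribute and are excluded; `n_sites_used`
reports how many sites actually entered the sum, rather than silently
renormalizing.

F_ST = 1 − π_within/π_between is undefined when π_between = 0 (two
monomorphic, identical samples); it is reported as missing with a warning
rather than clamped. Negative values are legitimate estimator noise when
two samples are effectively one population and are passed through.

## pN/pS and the Neutrality Index

Expected nonsynonymous/synonymous opportunity is computed by enumerating the
nine single-base mutants of every codon with equal weight — no
transition/transversion bias, matching a plain enumeration model. Changes to
or from stop codons are counted nonsynonymous (they are certainly not
silent); internal stop codons in an input frame raise a warning but do not
abort, since fragmentary core-gene models are common in metagenome catalogs.
The genetic code defaults to the bacterial table (whose synonymous/
nonsynonymous classes coincide with the standard code).

Observed counts use biallelic SNVs only; multi-state SNVs (two alternative
alleles, ~0.1–0.3% of sites in practice) are retained for π and F_ST —
whose sums run over all base pairs — but excluded from pN/pS, spectra and
divergence classification. Per-gene pN/pS adds 1 to observed synonymous
counts so that genes without synonymous SNVs stay defined; the genome-wide
ratio pools counts across genes and applies no pseudocount, since pooled
counts are large. Both modes are exposed.

The Neutrality Index classifies SNVs at two resolutions. Strain level: a
SNV is divergent if it varies among reconstructed strain haplotypes and
polymorphic if no strain carries it (the strain alignment is invariant
there). Clade level: divergent additionally requires uniformity within
every clade, moving putative recent within-clade variants into the
polymorphic class. NI is reported with its two component ratios; any zero
denominator (pS, dS, dN) yields an explicit "undefined" error naming the
component rather than an infinity.

## SNV handling

Coverage normalization emulates read downsampling at the count level: every
sample is thinned allele-wise by independent Binomial(count, T/M) draws to
the smallest per-sample median coverage T. Thinning keeps counts integral
and is frequency-unbiased, unlike deterministic scaling. Hard filtering
applies GATK-convention keep directions (QD ≥ 2, FS ≤ 60, MQ ≥ 40, base
quality RMS ≥ 30, MQRankSum ≥ −12.5, ReadPosRankSum ≥ −8), each threshold
and direction configurable; a missing annotation passes with a log entry,
so records from callers that omit a statistic are not silently dropped.
Polymorphic classification uses inclusive bounds 0.05 ≤ f ≤ 0.95; above is
fixed, below is absent; zero-coverage sites are excluded with a warning.

## Strain haplotype analyses

Distances between strains are Hamming counts over the biallelic SNV sites;
percent identity converts a SNV count and an alignment length, reported at
two decimals. Clade assignment is single linkage at a distance threshold,
defaulting to the midpoint of the largest gap in the sorted pairwise
distance distribution — a reproducible stand-in for reading clades off a
splits network by eye. Presence (frequency ≥ 5%) and dominance (≥ 90%,
inclusive) calls, dominant haplotypes (per-site major allele ≥ 90%), and
differential-SNV counts between dominant haplotypes follow directly;
differential counts exclude sites undefined in either haplotype and report
how many were excluded.

Unfolded allele-frequency spectra require an ancestral state per site; with
no outgroup available the ancestral allele is the one carried by the
majority of strains, ties resolved by designating one tree tip as ancestral.
Derived frequency is 1 minus the ancestral-allele frequency in the sample,
histogrammed in 20 equal right-closed bins by default (a presentation
choice). Multi-state sites are excluded.

## Co-abundance binning

The canopy procedure follows the published algorithm order: membership at
Pearson > 0.9 to the canopy profile (per-sample median of members, iterated
to a fixed point, cap 100 passes), merge at median-profile Pearson > 0.97,
removal of bins whose profile is nonzero in fewer than 3 samples, member
pruning at Spearman < 0.7, overlap resolution keeping each gene in its
largest bin (ties by bin id). Canopy seeding order is not specified by the
cited algorithm beyond randomness; seeds are visited in a seeded random
permutation and genes already absorbed by a canopy do not seed new ones,
which keeps runs deterministic. Merging uses pre-pruning median profiles,
matching the order in which the steps are described. Genes with zero
coverage variance have undefined correlations and are excluded with a
warning. Bins classify as MGS at ≥ 700 genes and CAG at 3–699.

The MAD core filter removes a gene when its coverage deviates from the
per-sample member median by at least 24 times the unscaled MAD in any
sample (no 1.4826 normal-consistency factor — the rule is stated on the raw
MAD). When MAD = 0 in a sample, only exact-median genes pass that sample's
criterion, with a warning.

## Gene catalog construction

Similarity hits (BLAST outfmt-6-like) are filtered — identity ≥ 95%,
alignment ≥ 90% of the shorter gene, e-value ≤ 10⁻⁶, length ratio ≤ 4, no
partial/complete links, no self-hits — and clustered by single linkage;
identity and coverage are applied on nucleotide coordinates since the
package clusters nucleotide genes. Cluster representatives take the
position-wise majority base with seeded random tie-breaks. Members whose
length differs from the cluster's modal length are excluded from the vote
(the smallest modal length wins ties), which avoids embedding a multiple
aligner in a bookkeeping step; the number of excluded members is
recoverable from the membership table. A two-stage variant (intra-sample
catalogs, then cross-sample linking) is provided and coincides with
one-stage clustering away from borderline hits.

## Diversity measures

Phylogenetic species evenness uses the phylogenetic correlation matrix C
(shared root-to-tip branch length between two tips, standardized to a unit
diagonal — valid for non-ultrametric strain trees) and, over the strains
present in a sample,

    PSE = (N · Σ_i c_ii m_i − mᵀCm) / (N² − N·m̄),

the abundance-weighted form whose denominator uses N·m̄ (mean abundance of
present strains). This is the form implemented by the standard R
implementation and is the one under which a star phylogeny with equal
abundances gives exactly 1 and uneven abundances strictly less; the variant
sometimes written with denominator N² − Σm_i² is constant at 1 on star
trees regardless of evenness and is not used. With fewer than two strains
present PSE is undefined and reported as missing. β-diversity is normalized
weighted UniFrac, delegated to scikit-bio behind this module's interface
(frequencies are scaled to integer counts of total 10⁹, exact to ~10⁻⁹,
because the array-based implementation consumes integers); an independent
per-branch traversal implementation lives in the test suite as the oracle.
Multifurcating roots are bifurcated with a zero-length internal node, which
leaves both UniFrac sums unchanged.

Associations: Spearman rank correlation (ρ, ρ², p) for paired vectors such
as π vs α-diversity, and a seeded Mantel-style permutation test (Spearman
statistic on off-diagonal entries, p = (1+#{perm ≥ obs})/(1+n_perm),
default 9,999 permutations) for paired distance matrices such as host vs
symbiont F_ST. The Mantel permutation loop is implemented here rather than
delegated so that an explicit generator seeds it.

## The synthetic community generator

`simdata` generates what the analysis assumes: a clade-structured set of
strain core genomes (Poisson(d_between/2) substitutions on each clade stem,
Poisson(d_within/2) on each terminal branch, all substitutions at distinct
sites so Hamming distances are exactly tree-additive — a no-back-mutation
regime enforced by rejecting configurations whose expected substitutions
exceed 10% of the genome), Dirichlet per-sample strain mixtures, per-site
Poisson coverage with multinomial read sampling and a uniform base-flip
error, invariant SNVs whose alternative allele rides at one global
frequency shared across samples (emulating population-wide unassigned
variants), and gene-abundance matrices with planted co-abundant groups and
24×MAD coverage outliers.

Defaults mirror the sulfur-oxidizer study regime scaled to desk size: 11
strains in clades of 4/3/3/1; d_between = 150 and d_within = 16 on a 30 kb
genome (proportional to the observed ~6.4k between-clade and ~0.7k
within-clade SNV separations over a 1.27 Mb core); 19 samples;
Dirichlet α = 0.3, which yields dominant-strain samples at realistic rates;
coverage 100× (between the two symbionts' 482× and 36× regimes); sequencing
error 10⁻³; invariant-SNV rate 5×10⁻⁴ of sites, putting invariant SNVs at a
few percent of all SNVs. The 30 kb genome and the test-suite problem sizes
(10⁴ calibration replicates, 750-gene binning fixtures, 6–8 sample
pipelines) were chosen as the smallest scales at which the statistical
assertions have comfortable power.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: read-level artifacts (mapping bias, indels,
chimeric assembly), recombination, linkage decay within strains, coverage
autocorrelation along the genome, strain-frequency covariation structure
beyond i.i.d. Dirichlet, and any selective structure (substitutions are
placed uniformly, so pN/pS ≈ 1 and NI ≈ 1 by construction — which is
precisely what makes it a calibration null). An optional founder-effect
mixture scenario (serial bottleneck resampling over host age) was
considered and left out of the defaults; the study's environmental-pool
composition is unknown, so any such scenario would be qualitative only.

## Numerical and design notes

- All randomness flows from explicit `numpy.random.Generator` objects
  seeded from user-supplied integers; no global RNG state. Identical seeds
  give byte-identical pipeline outputs.
- The π estimators are evaluated in closed form per site
  ((C² − ΣX²)/(C(C−1)) and 1 − Σf₁f₂) and verified against exhaustive
  read-pair enumeration to 10⁻¹⁰.
- Published Neutrality Index component ratios are reproduced exactly at two
  decimals from the published count tables; the NI values themselves are
  checked within one unit in the last printed digit because the published
  roundings are internally inconsistent with any single rounding rule.
- Degenerate inputs have defined behaviour throughout: empty count
  matrices, zero-coverage sites, constant vectors, single-strain samples,
  single-sample runs (empty F_ST matrix with a warning), zero-variance
  genes, MAD = 0, empty clusters — each documented at the raising site.

## Known limitations

- `classify_divergence` trusts the haplotype matrix: sites absent from it
  are invariant by definition, so errors in upstream deconvolution
  propagate into the NI classes.
- The clade-assignment default threshold (largest distance gap) assumes the
  between/within separation is the dominant gap; for flat distance
  distributions supply an explicit threshold.
- Canopy clustering is O(seeds × genes) per iteration with dense Pearson
  computations; matrices beyond ~10⁵ genes will want chunking.
- VCF export writes per-sample alternative-allele frequencies (AF), not the
  full AD counts, which is lossy for multi-allelic depth breakdowns; the
  counts TSV is the lossless canonical format.
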