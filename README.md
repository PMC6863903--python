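# strainpop

Strain-resolved population genetics for metagenomes of host-associated
bacterial symbionts. The package implements the downstream analysis stack
used to study chemosynthetic endosymbionts (sulfur- and methane-oxidizing
gammaproteobacteria) of deep-sea *Bathymodiolus* mussels: from per-sample
nucleotide count tables over a core-genome gene set, and from strain
haplotypes produced by deconvolution tools, to nucleotide diversity,
fixation index, pN/pS, the Neutrality Index, allele-frequency spectra,
strain diversity measures, and the co-abundance binning that defines the
symbiont core genomes. A synthetic community simulator with known ground
truth makes every stage testable without sequencing data.

## Who this is for

Researchers with (a) pooled-read pileups over a bacterial core genome across
many host individuals (counts TSV or VCF with allele depths), (b) optionally
strain haplotypes, a strain tree and per-sample strain frequencies from a
deconvolution tool such as DESMAN, (c) gene × sample mean-coverage matrices,
and (d) in-frame gene sequences — who want population-genetic inference at
the level of within-sample and between-sample variation.

## The statistics at the core

Intra-sample nucleotide diversity is the probability that two reads drawn
without replacement at a site carry different bases, averaged over the
genome of length |G|:

    π(S,G) = (1/|G|) Σ_i Σ_{B1} Σ_{B2≠B1} (X_{i,B1}/C_i) · (X_{i,B2}/(C_i−1))

where X_{i,B} is the count of base B at site i and C_i the coverage.
Inter-sample π draws one read from each sample, and the fixation index is

    F_ST(S1,S2) = 1 − (π(S1)+π(S2)) / (2·π(S1,S2)).

pN/pS normalizes the observed nonsynonymous/synonymous ratio of biallelic
SNVs by the mutational opportunity obtained by enumerating all nine
single-base changes of every codon. The Neutrality Index

    NI = (pN/pS) / (dN/dS)

contrasts polymorphic SNVs (those no reconstructed strain carries, i.e.
invariant in the strain alignment) against divergent SNVs (those that
differ between strains, optionally restricted to between-clade differences);
NI > 1 indicates purifying selection on divergence. Strain-level α-diversity
is phylogenetic species evenness (PSE), β-diversity is normalized weighted
UniFrac, and co-abundance binning is canopy clustering of gene coverage
profiles into MGSs (≥ 700 genes) and CAGs (3–699 genes) with a 24×MAD
coverage-outlier filter defining each core genome.

## Worked example

Simulate a default community (11 strains in four clades over a 30 kb core
genome, 19 samples, 100× coverage) and run every analysis:

```bash
strainpop run --outdir demo --seed 7
```

which writes `pi_intra.tsv`, `fst_matrix.tsv`, `pnps_per_gene.tsv`,
`neutrality_index.tsv`, `afs.tsv`, `strain_presence.tsv`,
`alpha_diversity.tsv`, `beta_diversity.tsv`, `associations.tsv`,
`snv_classes.tsv` and `manifest.json`. With seed 7 the first lines of
`pi_intra.tsv` read

```
# statistic=pi_intra genome_length=30000 seed=7
sample  pi                      n_sites_used
S01     0.0025772332757018515   352
S02     0.003176909920329566    352
```

i.e. per-site diversity of ~2.6×10⁻³ in sample S01 computed over 352
variable sites — the same order of magnitude observed for diverse
sulfur-oxidizer populations in real hosts. `associations.tsv` shows the
diagnostic coupling between the SNV-based and strain-based views of the
same mixtures (Spearman π vs PSE, Mantel F_ST vs weighted UniFrac):

```
test                  statistic           rho2               p
pi_vs_alpha_spearman  0.9649122807017543  0.931055709449061  2.6387737136486e-11
fst_vs_beta_mantel    0.9580363357093145  0.9178336205393303 0.001
```

Because the simulator places substitutions uniformly with no regard to codon
position, the genome-wide pN/pS of a run is near 1 (0.87 for this seed) —
the neutral expectation, and a calibration check of the estimator. Rerunning
with the same seed reproduces every output byte for byte.

The same analyses are available as library functions
(`strainpop.popgen.pi_intra`, `fst`, `pnps_gene`, `neutrality_index`,
`strainpop.strains.pairwise_snv_distance`, `derived_afs`,
`strainpop.diversity.pse`, `weighted_unifrac`,
`strainpop.binning.canopy_cluster`, `mad_core_filter`, ...) and as focused
subcommands (`strainpop simulate|catalog|bin|snv|popgen|strains|diversity`).

## Layout

- `src/strainpop/simdata.py` — synthetic communities with ground truth
- `src/strainpop/catalog.py` — nonredundant gene catalog clustering
- `src/strainpop/binning.py` — canopy co-abundance binning, MAD filter
- `src/strainpop/snv.py` — count matrices, normalization, hard filters
- `src/strainpop/popgen.py` — π, F_ST, pN/pS, Neutrality Index
- `src/strainpop/strains.py` — haplotype distances, clades, dominance, AFS
- `src/strainpop/diversity.py` — PSE, weighted UniFrac, association tests
- `src/strainpop/pipeline.py`, `cli.py`, `io.py` — driver, CLI, formats
- `docs/methods.md` — models, assumptions, parameter choices, limitations
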