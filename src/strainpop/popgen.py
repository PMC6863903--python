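"""Pooled-read population-genetic estimators: π, F_ST, pN/pS and the NI.

Intra-sample nucleotide diversity over a genome G of length |G| is

    π(S, G) = (1/|G|) Σ_i Σ_{B1} Σ_{B2 ≠ B1} (X_{i,B1}/C_i) (X_{i,B2}/(C_i − 1))

i.e. the probability that two reads drawn without replacement at a site carry
different bases, averaged over the genome.  Inter-sample π draws one read
from each sample (with replacement within each sample):

    π(S1, S2, G) = (1/|G|) Σ_i Σ_{B1 ≠ B2} (X_{i,B1,S1}/C_{i,S1}) (X_{i,B2,S2}/C_{i,S2})

and the fixation index between two samples is

    F_ST = 1 − π_within/π_between = 1 − (π(S1) + π(S2)) / (2 π(S1, S2)).

|G| is the full core-genome length including monomorphic sites; sites absent
from the count matrix contribute zero, so only variable sites need storing.

pN/pS normalizes the observed nonsynonymous/synonymous SNV ratio by the
mutational opportunity obtained by enumerating all nine single-nucleotide
changes of every codon.  The Neutrality Index NI = (pN/pS)/(dN/dS) contrasts
polymorphic against divergent SNV classes, where divergence is defined from
reconstructed strain haplotypes at either strain or clade resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .snv import BASES, AlleleCountMatrix, SNVRecord
from .strains import StrainHaplotypeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nucleotide diversity and F_ST
# ---------------------------------------------------------------------------

@dataclass
class PiResult:
    """Per-site nucleotide diversity with bookkeeping."""

    value: float
    genome_length: int
    n_sites_used: int


@dataclass
class FstResult:
    value: float  # NaN when pi_between == 0
    pi_within: float
    pi_between: float
    pi_1: PiResult
    pi_2: PiResult
    pi_12: PiResult


def pi_intra(m: AlleleCountMatrix, sample: str, genome_length: int | None = None) -> PiResult:
    """Intra-sample nucleotide diversity π(S, G).

    Sites with coverage < 2 cannot yield a read pair and contribute zero;
    they are excluded from ``n_sites_used``.
    """
    G = m.genome_length if genome_length is None else int(genome_length)
    if G <= 0:
        raise ValueError("genome_length must be positive")
    x = m.sample_counts(sample).astype(float)
    cov = x.sum(axis=1)
    usable = cov >= 2
    x = x[usable]
    cov = cov[usable]
    # sum over ordered base pairs B1 != B2 of (x1/C)(x2/(C-1)) = (C^2 - sum x^2)/(C(C-1))
    per_site = (cov**2 - (x**2).sum(axis=1)) / (cov * (cov - 1.0))
    return PiResult(float(per_site.sum() / G), G, int(usable.sum()))


def pi_inter(m: AlleleCountMatrix, sample1: str, sample2: str, genome_length: int | None = None) -> PiResult:
    """Inter-sample nucleotide diversity π(S1, S2, G); symmetric in samples."""
    G = m.genome_length if genome_length is None else int(genome_length)
    if G <= 0:
        raise ValueError("genome_length must be positive")
    x1 = m.sample_counts(sample1).astype(float)
    x2 = m.sample_counts(sample2).astype(float)
    c1 = x1.sum(axis=1)
    c2 = x2.sum(axis=1)
    usable = (c1 >= 1) & (c2 >= 1)
    f1 = x1[usable] / c1[usable, None]
    f2 = x2[usable] / c2[usable, None]
    per_site = 1.0 - (f1 * f2).sum(axis=1)
    return PiResult(float(per_site.sum() / G), G, int(usable.sum()))


def fst(m: AlleleCountMatrix, sample1: str, sample2: str, genome_length: int | None = None) -> FstResult:
    """Fixation index between two samples; NaN (with warning) when π_between = 0.

    Negative values are possible and reflect estimator noise when the two
    samples are effectively one population.
    """
    p1 = pi_intra(m, sample1, genome_length)
    p2 = pi_intra(m, sample2, genome_length)
    p12 = pi_inter(m, sample1, sample2, genome_length)
    pi_within = p1.value + p2.value
    pi_between = 2.0 * p12.value
    if pi_between == 0.0:
        warnings.warn(
            f"pi_between = 0 for samples {sample1}, {sample2}; F_ST undefined",
            stacklevel=2,
        )
        value = float("nan")
    else:
        value = 1.0 - pi_within / pi_between
    return FstResult(value, pi_within, pi_between, p1, p2, p12)


def fst_matrix(m: AlleleCountMatrix, genome_length: int | None = None) -> "pd.DataFrame":
    """Pairwise F_ST over all sample pairs (symmetric, zero diagonal)."""
    import pandas as pd

    n = len(m.samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fst(m, m.samples[i], m.samples[j], genome_length).value
    return pd.DataFrame(out, index=m.samples, columns=m.samples)


# ---------------------------------------------------------------------------
# Expected and observed synonymous/nonsynonymous counts
# ---------------------------------------------------------------------------

@dataclass
class CodingGeneSet:
    """In-frame nucleotide sequences per core gene plus the code table id."""

    genes: dict
    table_id: int = 11  # bacterial code; syn/nonsyn classes match the standard code

    def __post_init__(self):
        for gid, seq in self.genes.items():
            if len(seq) % 3 != 0:
                raise ValueError(f"gene {gid} length {len(seq)} not divisible by 3")


def _codon_translator(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]

    def translate(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    return translate


def codon_ns(codon: str, table_id: int = 11) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) counts among the 9 single-base mutants.

    All changes weighted equally; changes to or from a stop codon count as
    nonsynonymous.  Codons containing non-ACGT bases are skipped by callers.
    """
    tr = _codon_translator(table_id)
    aa = tr(codon)
    n = s = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            aa2 = tr(mut)
            if aa2 == aa and aa != "*" and aa2 != "*":
                s += 1
            else:
                n += 1
    return float(n), float(s)


def expected_ns_ratio(sequence: str, table_id: int = 11) -> tuple[float, float]:
    """Expected N and S mutation counts for an in-frame gene.

    Enumerates the nine single-nucleotide changes of each codon with equal
    weight.  An internal stop codon triggers a warning but is still counted
    (its mutants classified under the to/from-stop rule); codons with
    ambiguous bases are skipped with a warning.
    """
    if len(sequence) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    sequence = sequence.upper()
    tr = _codon_translator(table_id)
    n_tot = s_tot = 0.0
    for k in range(0, len(sequence), 3):
        codon = sequence[k : k + 3]
        if any(b not in BASES for b in codon):
            warnings.warn(f"codon {codon} at {k} contains non-ACGT base; skipped", stacklevel=2)
            continue
        if tr(codon) == "*" and k < len(sequence) - 3:
            warnings.warn(f"internal stop codon {codon} at position {k}", stacklevel=2)
        n, s = codon_ns(codon, table_id)
        n_tot += n
        s_tot += s
    return n_tot, s_tot


def snv_effect(gene_seq: str, pos: int, ref: str, alt: str, table_id: int = 11) -> str:
    """Classify a biallelic SNV on an in-frame gene as 'N' or 'S'.

    ``pos`` is 1-based within the gene.  The codon context is taken from the
    gene sequence; the reference base need not match the sequence (the strain
    consensus may differ), in which case the stated ref is substituted in.
    """
    gene_seq = gene_seq.upper()
    idx = pos - 1
    ci = idx // 3
    off = idx % 3
    codon = gene_seq[3 * ci : 3 * ci + 3]
    if len(codon) < 3 or any(b not in BASES for b in codon):
        raise ValueError(f"position {pos} has no complete ACGT codon context")
    codon = codon[:off] + ref + codon[off + 1 :]
    mut = codon[:off] + alt + codon[off + 1 :]
    tr = _codon_translator(table_id)
    aa, aa2 = tr(codon), tr(mut)
    return "S" if (aa2 == aa and aa != "*") else "N"


def observed_ns(
    snvs: Iterable[SNVRecord], gene_seq: str, table_id: int = 11
) -> tuple[int, int]:
    """Observed (N, S) counts of biallelic SNVs on one gene."""
    n = s = 0
    for rec in snvs:
        if not rec.biallelic:
            continue
        eff = snv_effect(gene_seq, rec.pos, rec.ref, rec.alts[0], table_id)
        if eff == "N":
            n += 1
        else:
            s += 1
    return n, s


def pnps_gene(
    snvs: Iterable[SNVRecord], gene_seq: str, pseudocount_s: float = 1.0, table_id: int = 11
) -> float:
    """Per-gene pN/pS = (obsN / (obsS + pseudocount)) / (expN / expS).

    The +1 synonymous pseudocount keeps genes without observed synonymous
    SNVs defined.  Undefined (NaN, with warning) when the gene offers no
    synonymous mutational opportunity (expS = 0).
    """
    obs_n, obs_s = observed_ns(snvs, gene_seq, table_id)
    exp_n, exp_s = expected_ns_ratio(gene_seq, table_id)
    if exp_s == 0:
        warnings.warn("expected synonymous count 0; per-gene pN/pS undefined", stacklevel=2)
        return float("nan")
    return (obs_n / (obs_s + pseudocount_s)) / (exp_n / exp_s)


def pnps_genome(
    snvs_by_gene: Mapping[str, Sequence[SNVRecord]],
    genes: CodingGeneSet,
    pseudocount_s: float = 0.0,
) -> float:
    """Genome-wide pN/pS from pooled observed and expected counts.

    Counts are pooled across genes before taking ratios; the default applies
    no pseudocount since pooled counts are large.
    """
    obs_n = obs_s = 0
    exp_n = exp_s = 0.0
    for gid, seq in genes.genes.items():
        n, s = observed_ns(snvs_by_gene.get(gid, ()), seq, genes.table_id)
        obs_n += n
        obs_s += s
        en, es = expected_ns_ratio(seq, genes.table_id)
        exp_n += en
        exp_s += es
    if exp_s == 0 or obs_s + pseudocount_s == 0:
        warnings.warn("genome-wide pN/pS undefined (zero synonymous denominator)", stacklevel=2)
        return float("nan")
    return (obs_n / (obs_s + pseudocount_s)) / (exp_n / exp_s)


# ---------------------------------------------------------------------------
# Divergent/polymorphic classification and the Neutrality Index
# ---------------------------------------------------------------------------

def classify_divergence(
    snvs: Iterable[SNVRecord],
    haplotypes: StrainHaplotypeSet,
    level: str = "strain",
) -> dict:
    """Label each SNV 'divergent' or 'polymorphic' at strain or clade level.

    At ``level='strain'`` a SNV is divergent iff it varies among the
    reconstructed strain haplotypes; SNVs absent from the haplotype matrix
    (invariant SNVs) are polymorphic.  At ``level='clade'`` a SNV is
    divergent iff it varies among strains *and* is uniform within every
    clade; within-clade variable and invariant SNVs are polymorphic.
    """
    if level not in ("strain", "clade"):
        raise ValueError(f"unknown level {level!r}")
    if level == "clade":
        if haplotypes.clade_map is None or any(
            s not in haplotypes.clade_map for s in haplotypes.strains
        ):
            raise ValueError("clade-level classification requires a total strain→clade map")
    labels = {}
    for rec in snvs:
        site = rec.site
        if not haplotypes.has_site(site):
            labels[site] = "polymorphic"  # invariant SNV: strain alignment constant
            continue
        states = haplotypes.site_states(site)
        varies = len(set(states)) > 1
        if level == "strain":
            labels[site] = "divergent" if varies else "polymorphic"
        else:
            if not varies:
                labels[site] = "polymorphic"
                continue
            uniform_within = True
            by_clade: dict = {}
            for strain, st in zip(haplotypes.strains, states):
                cl = haplotypes.clade_map[strain]
                by_clade.setdefault(cl, set()).add(st)
            uniform_within = all(len(v) == 1 for v in by_clade.values())
            labels[site] = "divergent" if uniform_within else "polymorphic"
    return labels


@dataclass
class SnvClassCounts:
    """Divergent/polymorphic × nonsynonymous/synonymous SNV counts."""

    dN: int
    dS: int
    pN: int
    pS: int

    def __post_init__(self):
        if min(self.dN, self.dS, self.pN, self.pS) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class NiResult:
    value: float
    pnps: float  # polymorphic N/S ratio
    dnds: float  # divergent N/S ratio
    counts: SnvClassCounts


def neutrality_index(counts: SnvClassCounts) -> NiResult:
    """NI = (pN/pS) / (dN/dS); > 1 indicates purifying selection on divergence.

    Raises ValueError naming the offending zero denominator component.
    """
    for name in ("pS", "dS", "dN"):
        if getattr(counts, name) == 0:
            raise ValueError(f"NI undefined: {name} = 0")
    pnps = counts.pN / counts.pS
    dnds = counts.dN / counts.dS
    return NiResult(pnps / dnds, pnps, dnds, counts)


def ni_from_snvs(
    snvs: Sequence[SNVRecord],
    haplotypes: StrainHaplotypeSet,
    genes: CodingGeneSet,
    level: str = "strain",
) -> NiResult:
    """Classify biallelic SNVs by divergence level and effect, then compute NI."""
    labels = classify_divergence(snvs, haplotypes, level)
    tallies = {"dN": 0, "dS": 0, "pN": 0, "pS": 0}
    for rec in snvs:
        if not rec.biallelic or rec.gene_id not in genes.genes:
            continue
        eff = snv_effect(genes.genes[rec.gene_id], rec.pos, rec.ref, rec.alts[0], genes.table_id)
        key = ("d" if labels[rec.site] == "divergent" else "p") + eff
        tallies[key] += 1
    return neutrality_index(SnvClassCounts(**tallies))
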