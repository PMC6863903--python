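"""Synthetic strain communities with the statistical structure the analysis assumes.

The generator emulates the data regime of a strain-resolved symbiont
metagenome study: a handful of closely related strain core genomes organised
into clades, per-sample strain mixtures, pooled-read pileups at configurable
coverage with sequencing error, population-wide "invariant" SNVs that no
strain carries, and gene-abundance matrices with planted co-abundant groups
and coverage outliers.

Strain genomes are produced by placing Poisson-distributed substitutions on
the branches of a clade-structured tree without back-mutation (every
substitution hits a distinct site), so the Hamming distance between two
strains equals the number of substitutions on the path separating them and
the tree and sequences are mutually consistent.  The low-divergence regime
this assumes (< 1% of positions) is guarded by a validation error.

Defaults mirror the sulfur-oxidiser study conditions scaled to desk size:
11 strains in four clades of 4/3/3/1, between- and within-clade SNV
separations proportional to the observed ~6.4k/0.7k over 1.27 Mbp scaled to
a 30 kb genome, 19 samples, Dirichlet(0.3) mixtures that produce
dominant-strain samples, and per-site Poisson coverage of 100×.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import GeneAbundanceMatrix
from .snv import BASES, AlleleCountMatrix
from .strains import StrainHaplotypeSet

_BASE_ARR = np.array(list(BASES))


@dataclass
class SimulationConfig:
    n_strains: int = 11
    clade_sizes: tuple | None = None  # defaults to (4,3,3,1) for 11 strains, else singletons
    d_between: float = 150.0  # expected SNVs separating strains of different clades
    d_within: float = 16.0  # expected SNVs separating strains of the same clade
    genome_length: int = 30000  # bp, multiple of 3
    n_genes: int = 50
    n_samples: int = 19
    coverage: float = 100.0  # mean reads per site
    seq_error: float = 0.001  # per-base error probability
    dirichlet_alpha: float = 0.3  # concentration of per-sample strain mixtures
    invariant_snv_rate: float = 5e-4  # fraction of sites carrying unassigned polymorphism
    seed: int = 0

    def __post_init__(self):
        if self.clade_sizes is None:
            self.clade_sizes = (4, 3, 3, 1) if self.n_strains == 11 else (1,) * self.n_strains
        self.clade_sizes = tuple(int(c) for c in self.clade_sizes)
        if sum(self.clade_sizes) != self.n_strains:
            raise ValueError("clade_sizes must sum to n_strains")
        if any(c < 1 for c in self.clade_sizes):
            raise ValueError("clade sizes must be positive")
        if not (0 <= self.seq_error < 0.25):
            raise ValueError("seq_error must be in [0, 0.25)")
        if self.coverage < 2:
            raise ValueError("coverage must be at least 2")
        if self.genome_length % 3 != 0:
            raise ValueError("genome_length must be a multiple of 3")
        if self.n_genes < 1 or self.genome_length // self.n_genes < 3:
            raise ValueError("n_genes incompatible with genome_length")
        expected_subs = (
            len(self.clade_sizes) * self.d_between / 2.0
            + self.n_strains * self.d_within / 2.0
            + self.invariant_snv_rate * self.genome_length
        )
        if expected_subs > 0.1 * self.genome_length:
            raise ValueError(
                f"expected ~{expected_subs:.0f} substitutions exceed 10% of the genome; "
                "back-mutation would no longer be negligible"
            )


def _gene_bounds(genome_length: int, n_genes: int) -> list:
    """Partition the genome into contiguous in-frame genes (lengths % 3 == 0)."""
    base = (genome_length // n_genes) // 3 * 3
    bounds = []
    start = 0
    for k in range(n_genes):
        length = genome_length - start if k == n_genes - 1 else base
        bounds.append((f"gene_{k + 1:04d}", start, length))
        start += length
    return bounds


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated community.

    ``assigned_pos``/``assigned_alt``/``assigned_states`` describe the SNV
    sites that vary among strain genomes (one substitution each, biallelic);
    ``invariant_*`` describe unassigned population-wide variants whose
    alternative allele occurs at one global frequency shared across samples.
    """

    config: SimulationConfig
    root_seq: str
    strain_seqs: dict
    tree_newick: str
    clade_map: dict
    frequencies: pd.DataFrame  # samples x strains, rows sum to 1
    assigned_pos: np.ndarray  # 0-based genome coordinates, sorted
    assigned_alt: np.ndarray  # alt base per assigned site
    assigned_states: np.ndarray  # (n_assigned, n_strains) of 0/1
    invariant_pos: np.ndarray
    invariant_alt: np.ndarray
    invariant_freq: np.ndarray  # global alt frequency per invariant site
    gene_bounds: list = field(default_factory=list)

    @property
    def strains(self) -> list:
        return list(self.frequencies.columns)

    @property
    def samples(self) -> list:
        return list(self.frequencies.index)

    def pos_to_site(self, pos: int) -> tuple[str, int]:
        """Map a 0-based genome coordinate to (gene_id, 1-based position)."""
        for gid, start, length in self.gene_bounds:
            if start <= pos < start + length:
                return (gid, pos - start + 1)
        raise ValueError(f"position {pos} outside the genome")

    def all_variant_positions(self) -> np.ndarray:
        return np.sort(np.concatenate([self.assigned_pos, self.invariant_pos])).astype(int)

    def true_site_freqs(self, sample: str, positions: np.ndarray) -> np.ndarray:
        """True per-site allele frequencies (n_positions, 4) for one sample.

        At assigned sites the frequency is the strain-frequency-weighted
        allele mix; at invariant sites the alternative allele appears at its
        global frequency; elsewhere the reference base is fixed.
        """
        w = self.frequencies.loc[sample].to_numpy()
        freqs = np.zeros((len(positions), 4))
        assigned_ix = {p: i for i, p in enumerate(self.assigned_pos)}
        invariant_ix = {p: i for i, p in enumerate(self.invariant_pos)}
        for k, pos in enumerate(positions):
            ref = self.root_seq[pos]
            if pos in assigned_ix:
                i = assigned_ix[pos]
                alt = self.assigned_alt[i]
                f_alt = float(w @ self.assigned_states[i])
                freqs[k, BASES.index(ref)] = 1.0 - f_alt
                freqs[k, BASES.index(alt)] += f_alt
            elif pos in invariant_ix:
                i = invariant_ix[pos]
                g = float(self.invariant_freq[i])
                freqs[k, BASES.index(ref)] = 1.0 - g
                freqs[k, BASES.index(self.invariant_alt[i])] += g
            else:
                freqs[k, BASES.index(ref)] = 1.0
        return freqs

    def to_haplotype_set(self) -> StrainHaplotypeSet:
        sites = pd.DataFrame(
            [
                (*self.pos_to_site(p), self.root_seq[p], a)
                for p, a in zip(self.assigned_pos, self.assigned_alt)
            ],
            columns=["gene_id", "pos", "ref", "alt"],
        )
        return StrainHaplotypeSet(
            sites,
            self.strains,
            self.assigned_states,
            alignment_length=self.config.genome_length,
            tree_newick=self.tree_newick,
            clade_map=dict(self.clade_map),
        )

    def coding_genes(self) -> dict:
        """Reference (root) gene sequences, in frame, keyed by gene id."""
        return {gid: self.root_seq[s : s + L] for gid, s, L in self.gene_bounds}

    # -- serialization -----------------------------------------------------
    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "strains.fasta", "w") as fh:
            for name, seq in self.strain_seqs.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k : k + 80] + "\n")
        (outdir / "strain_tree.nwk").write_text(self.tree_newick + "\n")
        with open(outdir / "strain_frequencies.tsv", "w") as fh:
            fh.write(f"# per-sample strain relative abundances, seed={self.config.seed}\n")
            self.frequencies.to_csv(fh, sep="\t", index_label="sample")
        truth = {
            "clade_map": self.clade_map,
            "assigned_sites": [
                {"pos": int(p), "site": self.pos_to_site(int(p)), "ref": self.root_seq[int(p)], "alt": str(a)}
                for p, a in zip(self.assigned_pos, self.assigned_alt)
            ],
            "invariant_sites": [
                {"pos": int(p), "site": self.pos_to_site(int(p)), "ref": self.root_seq[int(p)],
                 "alt": str(a), "freq": float(f)}
                for p, a, f in zip(self.invariant_pos, self.invariant_alt, self.invariant_freq)
            ],
            "genome_length": self.config.genome_length,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_strains(config: SimulationConfig) -> SyntheticTruth:
    """Generate clade-structured strain genomes, tree, and sample mixtures.

    Substitution counts are Poisson(d_between/2) on each clade stem branch
    and Poisson(d_within/2) on each strain terminal branch, so two strains
    of different clades differ by ~d_between (+ d_within) sites and two
    strains of the same clade by ~d_within.  All substitutions hit distinct
    sites (no back-mutation).
    """
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    root = _BASE_ARR[rng.integers(0, 4, size=G)]

    strains = []
    clade_map = {}
    stem_of = []  # clade index per strain
    for c, size in enumerate(config.clade_sizes, start=1):
        for k in range(1, size + 1):
            name = f"s{c}.{k}"
            strains.append(name)
            clade_map[name] = f"clade_{c}"
            stem_of.append(c - 1)
    n_clades = len(config.clade_sizes)

    if n_clades == 1:
        # a single clade's stem is shared by every strain and produces no SNVs
        stem_subs = np.zeros(1, dtype=int)
    else:
        stem_subs = rng.poisson(config.d_between / 2.0, size=n_clades)
    tip_subs = rng.poisson(config.d_within / 2.0, size=config.n_strains)
    total = int(stem_subs.sum() + tip_subs.sum())
    positions = rng.choice(G, size=total, replace=False) if total else np.array([], dtype=int)
    alt_bases = np.empty(total, dtype=object)
    for i, p in enumerate(positions):
        choices = [b for b in BASES if b != root[p]]
        alt_bases[i] = choices[rng.integers(0, 3)]

    # assign mutation slices to branches
    states = np.zeros((total, config.n_strains), dtype=np.int8)
    cursor = 0
    branch_lengths_stem = []
    for c in range(n_clades):
        sl = slice(cursor, cursor + stem_subs[c])
        members = [j for j in range(config.n_strains) if stem_of[j] == c]
        states[sl, members] = 1
        cursor += stem_subs[c]
        branch_lengths_stem.append(stem_subs[c] / G)
    branch_lengths_tip = []
    for j in range(config.n_strains):
        sl = slice(cursor, cursor + tip_subs[j])
        states[sl, j] = 1
        cursor += tip_subs[j]
        branch_lengths_tip.append(tip_subs[j] / G)

    # sequences
    strain_seqs = {}
    for j, name in enumerate(strains):
        seq = root.copy()
        mut = states[:, j] == 1
        seq[positions[mut]] = alt_bases[mut]
        strain_seqs[name] = "".join(seq)

    # drop sites where no strain differs from root (possible only if a clade
    # contains every strain — then stem mutations are shared by all)
    informative = (states.sum(axis=1) > 0) & (states.sum(axis=1) < config.n_strains)
    positions_i = positions[informative]
    alt_i = alt_bases[informative]
    states_i = states[informative]
    order = np.argsort(positions_i)
    positions_i, alt_i, states_i = positions_i[order], alt_i[order], states_i[order]

    # invariant (unassigned) SNVs on so-far untouched sites
    n_inv = int(round(config.invariant_snv_rate * G))
    free = np.setdiff1d(np.arange(G), positions, assume_unique=False)
    inv_pos = np.sort(rng.choice(free, size=n_inv, replace=False)) if n_inv else np.array([], dtype=int)
    inv_alt = np.empty(n_inv, dtype=object)
    for i, p in enumerate(inv_pos):
        choices = [b for b in BASES if b != root[p]]
        inv_alt[i] = choices[rng.integers(0, 3)]
    inv_freq = rng.uniform(0.05, 0.95, size=n_inv)

    # per-sample strain mixtures
    freqs = rng.dirichlet([config.dirichlet_alpha] * config.n_strains, size=config.n_samples)
    frequencies = pd.DataFrame(
        freqs,
        index=[f"S{k + 1:02d}" for k in range(config.n_samples)],
        columns=strains,
    )

    tree = _newick(config, strains, stem_of, branch_lengths_stem, branch_lengths_tip)
    return SyntheticTruth(
        config=config,
        root_seq="".join(root),
        strain_seqs=strain_seqs,
        tree_newick=tree,
        clade_map=clade_map,
        frequencies=frequencies,
        assigned_pos=positions_i.astype(int),
        assigned_alt=alt_i,
        assigned_states=states_i,
        invariant_pos=inv_pos.astype(int),
        invariant_alt=inv_alt,
        invariant_freq=inv_freq,
        gene_bounds=_gene_bounds(G, config.n_genes),
    )


def _newick(config, strains, stem_of, stem_len, tip_len) -> str:
    if config.n_strains == 1:
        return f"({strains[0]}:{tip_len[0]:.8f});"
    parts = []
    j = 0
    for c, size in enumerate(config.clade_sizes):
        members = []
        for _ in range(size):
            members.append(f"{strains[j]}:{tip_len[j]:.8f}")
            j += 1
        if size == 1:
            # singleton clade: fold the stem into the terminal branch
            name, bl = members[0].split(":")
            parts.append(f"{name}:{float(bl) + stem_len[c]:.8f}")
        else:
            parts.append(f"({','.join(members)})clade_{c + 1}:{stem_len[c]:.8f}")
    return f"({','.join(parts)});"


def simulate_counts(
    truth: SyntheticTruth,
    config: SimulationConfig | None = None,
    sites: str = "variant",
    seed_offset: int = 1,
) -> AlleleCountMatrix:
    """Simulate pooled-read pileup counts from the true allele frequencies.

    Per site and sample, coverage is Poisson(config.coverage) and read bases
    are multinomial draws from the true allele frequencies after applying a
    uniform base-flip error of probability ``seq_error``.  ``sites`` selects
    either all genome positions ("all") or only the variant positions
    ("variant", default), the latter being sufficient for the diversity
    estimators since monomorphic sites contribute zero.
    """
    config = config or truth.config
    rng = np.random.default_rng((config.seed, seed_offset))
    if sites == "variant":
        positions = truth.all_variant_positions()
    elif sites == "all":
        positions = np.arange(config.genome_length)
    else:
        raise ValueError("sites must be 'variant' or 'all'")
    site_keys = [truth.pos_to_site(int(p)) for p in positions]
    samples = truth.samples
    counts = np.zeros((len(positions), len(samples), 4), dtype=np.int64)
    e = config.seq_error
    for sj, sample in enumerate(samples):
        p = truth.true_site_freqs(sample, positions)
        p_err = p * (1.0 - e) + (1.0 - p) * (e / 3.0)
        p_err /= p_err.sum(axis=1, keepdims=True)
        cov = rng.poisson(config.coverage, size=len(positions))
        counts[:, sj, :] = rng.multinomial(cov, p_err)
    return AlleleCountMatrix(site_keys, samples, counts, config.genome_length)


def simulate_gene_abundances(
    n_core_genes: int = 800,
    n_cag_groups: int = 4,
    n_samples: int = 10,
    noise_sd: float = 0.05,
    outlier_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GeneAbundanceMatrix, dict]:
    """Gene × sample coverages with planted co-abundant groups and outliers.

    One group of ``n_core_genes`` (≥ 700, so an MGS exists) plus
    ``n_cag_groups`` smaller groups (3–60 genes) each share a latent
    per-sample lognormal abundance profile; gene coverages are the profile
    times multiplicative lognormal noise of relative sd ``noise_sd``.  A
    fraction ``outlier_rate`` of the core genes is shifted by 30 MADs in one
    random sample to exercise the 24-MAD filter.

    Returns the matrix and a truth dict with ``labels`` (gene → group),
    ``outliers`` (gene ids) and ``profiles``.
    """
    if n_core_genes < 700:
        raise ValueError("n_core_genes must be at least 700 so that an MGS exists")
    rng = np.random.default_rng(seed)
    samples = [f"S{k + 1:02d}" for k in range(n_samples)]
    group_sizes = {"mgs": n_core_genes}
    for g in range(n_cag_groups):
        group_sizes[f"cag{g + 1}"] = int(rng.integers(3, 61))
    profiles = {}
    rows = []
    labels = {}
    for gname, size in group_sizes.items():
        profile = np.exp(rng.normal(3.0, 1.0, size=n_samples))
        profiles[gname] = profile
        for k in range(size):
            gid = f"{gname}_g{k + 1:05d}"
            noise = np.exp(rng.normal(0.0, noise_sd, size=n_samples)) if noise_sd > 0 else 1.0
            rows.append(pd.Series(profile * noise, index=samples, name=gid))
            labels[gid] = gname
    df = pd.DataFrame(rows)

    outliers = []
    n_out = int(round(outlier_rate * n_core_genes))
    if n_out:
        core_ids = [g for g, l in labels.items() if l == "mgs"]
        chosen = [str(g) for g in rng.choice(core_ids, size=n_out, replace=False)]
        for gid in chosen:
            s = samples[rng.integers(0, n_samples)]
            core_col = df.loc[core_ids, s]
            med = core_col.median()
            mad = (core_col - med).abs().median()
            shift = 30.0 * mad if mad > 0 else med + 10.0
            df.loc[gid, s] = med + shift
            outliers.append(gid)
    truth = {"labels": labels, "outliers": sorted(outliers), "profiles": pd.DataFrame(profiles, index=samples).T}
    return GeneAbundanceMatrix(df), truth
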