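"""SNV data model, coverage normalization, hard filtering and classification.

The backbone container is :class:`AlleleCountMatrix`: per-site, per-sample read
counts of the four nucleotides over a core-genome gene set, as obtained from
mapped-read pileups.  Sites are keyed by ``(gene_id, pos)`` with ``pos``
1-based within the gene, following VCF convention.

Coverage normalization emulates read downsampling to the smallest per-sample
median coverage by binomial thinning of the allele counts, which keeps counts
integral and leaves expected allele frequencies unchanged.  Hard filtering
applies GATK-style per-annotation thresholds to called variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class AlleleCountMatrix:
    """Read counts of A/C/G/T per SNV site and sample.

    Parameters
    ----------
    sites : sequence of (gene_id, pos)
        Site keys; ``pos`` is 1-based within the gene.
    samples : sequence of str
        Sample identifiers.
    counts : ndarray, shape (n_sites, n_samples, 4)
        Non-negative read counts in base order A, C, G, T.
    genome_length : int
        Length |G| of the analyzed core genome in bp.  Used as the
        normalizing constant of the diversity estimators; it includes
        monomorphic sites that are not stored in the matrix.
    """

    def __init__(self, sites, samples, counts, genome_length):
        counts = np.asarray(counts, dtype=np.int64)
        sites = [(str(g), int(p)) for g, p in sites]
        samples = [str(s) for s in samples]
        if counts.shape != (len(sites), len(samples), 4):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(sites)} sites x {len(samples)} samples x 4 bases"
            )
        if (counts < 0).any():
            raise ValueError("negative read counts")
        if genome_length < len(sites):
            raise ValueError("genome_length smaller than the number of sites")
        self.sites = sites
        self.samples = samples
        self.counts = counts
        self.genome_length = int(genome_length)
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._site_index = {s: i for i, s in enumerate(sites)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_counts(self, sample: str) -> np.ndarray:
        """Counts for one sample, shape (n_sites, 4)."""
        return self.counts[:, self._sample_index[sample], :]

    def coverage(self) -> np.ndarray:
        """Per-site, per-sample coverage (sum over bases)."""
        return self.counts.sum(axis=2)

    def frequencies(self, sample: str) -> np.ndarray:
        """Per-site allele frequencies for one sample; NaN at zero coverage."""
        x = self.sample_counts(sample).astype(float)
        cov = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, x / cov, np.nan)

    def site_loc(self, site) -> int:
        return self._site_index[(str(site[0]), int(site[1]))]

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: gene_id, pos, sample, nA, nC, nG, nT."""
        rows = []
        for si, (g, p) in enumerate(self.sites):
            for sj, s in enumerate(self.samples):
                rows.append((g, p, s, *self.counts[si, sj, :]))
        return pd.DataFrame(rows, columns=["gene_id", "pos", "sample", "nA", "nC", "nG", "nT"])

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# genome_length={self.genome_length}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, genome_length: int) -> "AlleleCountMatrix":
        sites = list(dict.fromkeys(zip(df["gene_id"].astype(str), df["pos"].astype(int))))
        samples = list(dict.fromkeys(df["sample"].astype(str)))
        site_ix = {s: i for i, s in enumerate(sites)}
        samp_ix = {s: i for i, s in enumerate(samples)}
        counts = np.zeros((len(sites), len(samples), 4), dtype=np.int64)
        cols = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
        for k, (g, p, s) in enumerate(zip(df["gene_id"].astype(str), df["pos"].astype(int), df["sample"].astype(str))):
            counts[site_ix[(g, p)], samp_ix[s], :] = cols[k]
        return cls(sites, samples, counts, genome_length)

    @classmethod
    def from_tsv(cls, path, genome_length: int | None = None) -> "AlleleCountMatrix":
        meta_len = None
        with open(path) as fh:
            header_lines = []
            for line in fh:
                if line.startswith("#"):
                    header_lines.append(line)
                    if "genome_length=" in line:
                        meta_len = int(line.split("genome_length=")[1].strip())
                else:
                    break
        if genome_length is None:
            if meta_len is None:
                raise ValueError("genome_length not given and not found in file header")
            genome_length = meta_len
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(df, genome_length)

    def __eq__(self, other) -> bool:  # mainly for round-trip tests
        return (
            isinstance(other, AlleleCountMatrix)
            and self.sites == other.sites
            and self.samples == other.samples
            and self.genome_length == other.genome_length
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# Coverage normalization
# ---------------------------------------------------------------------------

def normalize_coverage(m: AlleleCountMatrix, seed: int | np.random.Generator = 0) -> AlleleCountMatrix:
    """Downsample samples to the smallest per-sample median site coverage.

    The target T is the minimum over samples of the median site coverage.
    Each sample with median M > T has every allele count thinned by an
    independent Binomial(count, T/M) draw, the count-level analogue of read
    downsampling.  Thinning is frequency-unbiased: expected allele fractions
    are unchanged.
    """
    if m.n_sites == 0:
        raise ValueError("empty count matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = m.coverage()
    medians = np.median(cov, axis=0)
    if (medians <= 0).any():
        bad = [m.samples[i] for i in np.where(medians <= 0)[0]]
        raise ValueError(f"samples with zero median coverage: {bad}")
    target = medians.min()
    out = m.counts.copy()
    for j, med in enumerate(medians):
        if med > target:
            p = target / med
            out[:, j, :] = rng.binomial(m.counts[:, j, :], p)
    return AlleleCountMatrix(m.sites, m.samples, out, m.genome_length)


# ---------------------------------------------------------------------------
# SNV records and hard filtering
# ---------------------------------------------------------------------------

@dataclass
class SNVRecord:
    """A called single-nucleotide variant with per-sample alt frequencies."""

    gene_id: str
    pos: int  # 1-based within gene
    ref: str
    alts: tuple[str, ...]
    freqs: dict = field(default_factory=dict)  # sample -> alt frequency (sum over alts), NaN if no coverage
    annotations: dict = field(default_factory=dict)  # QD, FS, MQ, BaseQRMS, MQRankSum, ReadPosRankSum

    def __post_init__(self):
        self.alts = tuple(self.alts)
        if self.ref in self.alts:
            raise ValueError(f"ref allele {self.ref} listed among alts {self.alts}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.gene_id, self.pos)

    @property
    def biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class HardFilterThresholds:
    """GATK-convention hard-filter thresholds (keep directions as attributes)."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    baseq_min: float = 30.0
    mqrs_min: float = -12.5
    rprs_min: float = -8.0


_FILTER_RULES = (
    ("QD", "qd_min", "ge"),
    ("FS", "fs_max", "le"),
    ("MQ", "mq_min", "ge"),
    ("BaseQRMS", "baseq_min", "ge"),
    ("MQRankSum", "mqrs_min", "ge"),
    ("ReadPosRankSum", "rprs_min", "ge"),
)


def record_passes(rec: SNVRecord, t: HardFilterThresholds) -> bool:
    for key, attr, direction in _FILTER_RULES:
        val = rec.annotations.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            logger.debug("annotation %s missing on %s:%d; treated as pass", key, rec.gene_id, rec.pos)
            continue
        thr = getattr(t, attr)
        ok = val >= thr if direction == "ge" else val <= thr
        if not ok:
            return False
    return True


def hard_filter(records: Iterable[SNVRecord], t: HardFilterThresholds | None = None) -> list[SNVRecord]:
    """Keep records passing all annotation thresholds; missing annotations pass.

    Idempotent and order-independent: each record is judged in isolation.
    """
    t = t or HardFilterThresholds()
    kept = []
    for rec in records:
        missing = [k for k, _, _ in _FILTER_RULES if rec.annotations.get(k) is None]
        if len(missing) == len(_FILTER_RULES):
            warnings.warn(
                f"all filter annotations missing on {rec.gene_id}:{rec.pos}; kept (vacuous pass)",
                stacklevel=2,
            )
        if record_passes(rec, t):
            kept.append(rec)
    return kept


class SNVClass(str, Enum):
    POLYMORPHIC = "polymorphic"
    FIXED = "fixed"
    ABSENT = "absent"


def classify_polymorphic(record: SNVRecord, sample: str, lo: float = 0.05, hi: float = 0.95) -> SNVClass | None:
    """Classify a variant in one sample by its alternative-allele frequency.

    Polymorphic iff lo <= f <= hi (bounds inclusive); fixed iff f > hi;
    absent iff f < lo.  Returns None with a warning where the frequency is
    undefined (no coverage at the site in this sample).
    """
    f = record.freqs.get(sample)
    if f is None or (isinstance(f, float) and np.isnan(f)):
        warnings.warn(
            f"no coverage for {record.gene_id}:{record.pos} in sample {sample}; classification undefined",
            stacklevel=2,
        )
        return None
    if lo <= f <= hi:
        return SNVClass.POLYMORPHIC
    return SNVClass.FIXED if f > hi else SNVClass.ABSENT


# ---------------------------------------------------------------------------
# SNV calling from counts (consensus-relative)
# ---------------------------------------------------------------------------

def call_snvs(
    m: AlleleCountMatrix,
    ref_alleles: Mapping[tuple[str, int], str] | None = None,
    min_freq: float = 0.05,
) -> list[SNVRecord]:
    """Derive SNV records from a count matrix relative to reference alleles.

    The reference allele per site defaults to the majority base of the pooled
    counts across samples (the core-genome consensus).  A non-reference base
    is reported as an alternative allele if its pooled frequency reaches
    ``min_freq`` or it is (nearly) fixed in at least one sample.  Sites where
    no alternative allele qualifies produce no record.
    """
    records = []
    pooled = m.counts.sum(axis=1)  # (n_sites, 4)
    for si, site in enumerate(m.sites):
        if ref_alleles is not None:
            ref = ref_alleles[site]
        else:
            ref = BASES[int(np.argmax(pooled[si]))]
        ri = _BASE_INDEX[ref]
        tot = pooled[si].sum()
        if tot == 0:
            continue
        alts = []
        for bi, base in enumerate(BASES):
            if bi == ri:
                continue
            pooled_f = pooled[si, bi] / tot
            per_sample = m.counts[si, :, :]
            cov = per_sample.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                fs = np.where(cov > 0, per_sample[:, bi] / np.maximum(cov, 1), 0.0)
            if pooled_f >= min_freq or (fs >= min_freq).any():
                alts.append(base)
        if not alts:
            continue
        alt_ix = [_BASE_INDEX[a] for a in alts]
        freqs = {}
        for sj, s in enumerate(m.samples):
            cov = m.counts[si, sj, :].sum()
            freqs[s] = float(m.counts[si, sj, alt_ix].sum() / cov) if cov > 0 else float("nan")
        records.append(SNVRecord(site[0], site[1], ref, tuple(alts), freqs=freqs))
    return records


def biallelic(records: Sequence[SNVRecord]) -> list[SNVRecord]:
    """Subset to biallelic SNVs (single alternative allele)."""
    return [r for r in records if r.biallelic]
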