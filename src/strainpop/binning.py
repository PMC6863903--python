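"""Co-abundance gene binning (canopy clustering) and MAD core-genome filtering.

Genes whose mean coverages covary across samples are clustered into bins:
metagenomic species (MGS, ≥ 700 genes — a symbiont core genome) and smaller
co-abundant gene groups (CAG, 3–699 genes).  The canopy procedure, in order:

1. grow canopies around seed genes, collecting members with Pearson
   correlation (PCC) > 0.9 to the canopy profile, the profile being the
   per-sample median coverage of current members, iterated to a fixed point;
2. merge canopies whose median profiles correlate at PCC > 0.97;
3. drop canopies whose coverage signal originates from fewer than three
   samples;
4. prune members with Spearman correlation < 0.7 to the bin median profile;
5. resolve overlaps by keeping each gene only in the largest bin.

Core genomes are then cleaned by removing genes lying at least 24 unscaled
MADs from the per-sample member median in at least one sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class GeneAbundanceMatrix:
    """Gene × sample mean coverages (reads per bp, ≥ 0; at least 3 samples)."""

    def __init__(self, df: pd.DataFrame):
        if df.isna().any().any():
            raise ValueError("missing cells in abundance matrix")
        if (df.values < 0).any():
            raise ValueError("negative coverages")
        if df.shape[1] < 3:
            raise ValueError("at least 3 samples required")
        self.df = df.astype(float)

    @property
    def genes(self) -> list:
        return list(self.df.index)

    @property
    def samples(self) -> list:
        return list(self.df.columns)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "GeneAbundanceMatrix":
        return cls(pd.read_csv(path, sep="\t", comment="#", index_col="gene_id"))


@dataclass
class Bin:
    """A co-abundance bin: member genes and their per-sample median profile."""

    bin_id: str
    members: list
    profile: np.ndarray
    size_class: str | None = None  # "MGS" or "CAG" after classification

    @property
    def size(self) -> int:
        return len(self.members)


def _pearson_to_profile(x: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Vectorized Pearson correlation of each row of x with a profile vector."""
    xm = x - x.mean(axis=1, keepdims=True)
    pm = profile - profile.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (pm**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ pm) / denom
    return np.where(denom > 0, r, np.nan)


def canopy_cluster(
    m: GeneAbundanceMatrix,
    pcc_member: float = 0.9,
    pcc_merge: float = 0.97,
    spearman_min: float = 0.7,
    min_signal_samples: int = 3,
    seed: int = 0,
    max_iter: int = 100,
) -> list[Bin]:
    """Cluster genes into co-abundance bins by canopy clustering.

    Canopy seeds are visited in a seeded random order; each seed not yet in a
    canopy starts one, membership is re-collected against the per-sample
    median profile until convergence (or ``max_iter`` passes).  Genes with
    zero coverage variance across samples are excluded up front (their
    correlation is undefined).
    """
    rng = np.random.default_rng(seed)
    x = m.df.to_numpy()
    genes = np.array(m.genes, dtype=object)
    variable = x.std(axis=1) > 0
    if (~variable).any():
        logger.warning(
            "excluding %d zero-variance genes from canopy clustering", int((~variable).sum())
        )
    idx_all = np.where(variable)[0]
    order = rng.permutation(idx_all)

    canopies: list[np.ndarray] = []  # member row indices
    in_canopy = np.zeros(len(genes), dtype=bool)
    for seed_idx in order:
        if in_canopy[seed_idx]:
            continue
        profile = x[seed_idx].astype(float)
        members = np.array([seed_idx])
        for _ in range(max_iter):
            r = _pearson_to_profile(x[idx_all], profile)
            new_members = idx_all[r > pcc_member]
            if new_members.size == 0:
                new_members = np.array([seed_idx])
            new_profile = np.median(x[new_members], axis=0)
            if new_members.size == members.size and np.array_equal(np.sort(new_members), np.sort(members)) and np.allclose(new_profile, profile):
                break
            members, profile = new_members, new_profile
        canopies.append(np.sort(members))
        in_canopy[members] = True

    # merge canopies with highly correlated median profiles
    merged = _merge_canopies(canopies, x, pcc_merge)

    bins: list[Bin] = []
    for members in merged:
        profile = np.median(x[members], axis=0)
        # signal filter: profile nonzero in >= min_signal_samples samples
        if (profile > 0).sum() < min_signal_samples:
            continue
        # Spearman member pruning against the median profile
        keep = []
        for gi in members:
            rho = stats.spearmanr(x[gi], profile).statistic
            if np.isnan(rho) or rho >= spearman_min:
                keep.append(gi)
        if not keep:
            continue
        members = np.array(keep)
        profile = np.median(x[members], axis=0)
        bins.append(Bin("", list(genes[members]), profile))

    # overlap removal: keep a gene only in the largest bin (ties by bin id)
    bins.sort(key=lambda b: min(b.members))
    for k, b in enumerate(bins):
        b.bin_id = f"bin_{k + 1:05d}"
    assigned: dict = {}
    for b in sorted(bins, key=lambda b: (-b.size, b.bin_id)):
        for g in b.members:
            assigned.setdefault(g, b.bin_id)
    out = []
    for b in bins:
        kept = [g for g in b.members if assigned[g] == b.bin_id]
        if kept:
            rows = [np.where(genes == g)[0][0] for g in kept]
            out.append(Bin(b.bin_id, kept, np.median(x[rows], axis=0)))
    return out


def _merge_canopies(canopies: list[np.ndarray], x: np.ndarray, pcc_merge: float) -> list[np.ndarray]:
    """Agglomerate canopies whose median profiles correlate above pcc_merge."""
    groups = [np.asarray(c) for c in canopies]
    changed = True
    while changed and len(groups) > 1:
        changed = False
        profiles = [np.median(x[g], axis=0) for g in groups]
        n = len(groups)
        done = False
        for i in range(n):
            for j in range(i + 1, n):
                r = _pearson_to_profile(profiles[i][None, :], profiles[j])[0]
                if r > pcc_merge:
                    groups[i] = np.unique(np.concatenate([groups[i], groups[j]]))
                    del groups[j]
                    changed = done = True
                    break
            if done:
                break
    return groups


def classify_bins(bins: list[Bin], mgs_min: int = 700, cag_min: int = 3) -> list[Bin]:
    """Label bins MGS (≥ 700 genes) or CAG (3–699); smaller groups discarded."""
    out = []
    for b in bins:
        if b.size >= mgs_min:
            b.size_class = "MGS"
        elif b.size >= cag_min:
            b.size_class = "CAG"
        else:
            continue
        out.append(b)
    return out


def mad_core_filter(
    b: Bin, m: GeneAbundanceMatrix, k: float = 24.0
) -> tuple[list, list]:
    """Remove bin members lying ≥ k unscaled MADs from the member median.

    A gene is removed iff in at least one sample its coverage deviates from
    the per-sample median of the bin members by at least k times the MAD
    (median absolute deviation, unscaled).  Where the MAD is zero in a sample
    only exact-median genes satisfy that sample's criterion (warning logged).
    Returns (core gene ids, removed gene ids).
    """
    sub = m.df.loc[b.members]
    med = sub.median(axis=0)
    dev = (sub - med).abs()
    mad = dev.median(axis=0)
    if (mad == 0).any():
        warnings.warn(
            f"MAD = 0 in samples {list(mad.index[mad == 0])} for {b.bin_id or 'bin'}; "
            "only exact-median genes pass there",
            stacklevel=2,
        )
    removed_mask = pd.Series(False, index=sub.index)
    for s in sub.columns:
        if mad[s] > 0:
            removed_mask |= dev[s] >= k * mad[s]
        else:
            removed_mask |= dev[s] > 0
    removed = list(sub.index[removed_mask])
    core = list(sub.index[~removed_mask])
    return core, removed


def bins_to_frame(bins: list[Bin]) -> pd.DataFrame:
    """Long-format membership table (gene_id, bin_id, size_class)."""
    rows = [
        {"gene_id": g, "bin_id": b.bin_id, "bin_size": b.size, "size_class": b.size_class}
        for b in bins
        for g in b.members
    ]
    return pd.DataFrame(rows, columns=["gene_id", "bin_id", "bin_size", "size_class"])
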