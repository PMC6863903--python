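"""Strain haplotype handling: distances, clades, dominance, spectra.

A strain is a genome-wide haplotype over the core-genome SNV sites, inferred
(by external deconvolution tools or the bundled simulator) to co-occur across
samples.  This module works on the biallelic site × strain allele-state
matrix, the strain tree, and per-sample strain frequency vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .snv import AlleleCountMatrix, BASES


@dataclass
class StrainHaplotypeSet:
    """Biallelic SNV sites × strain allele states plus tree and clade map.

    ``states`` holds 0 (ref) / 1 (alt) per site (rows) and strain (columns).
    ``alignment_length`` is the strain-alignment length in bp used to convert
    SNV distances into percent identities; it is at least the site count.
    """

    sites: pd.DataFrame  # columns: gene_id, pos, ref, alt
    strains: list
    states: np.ndarray  # (n_sites, n_strains) of 0/1
    alignment_length: int
    tree_newick: str | None = None
    clade_map: dict | None = None
    _site_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sites), len(self.strains)):
            raise ValueError("states shape does not match sites x strains")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("allele states must be 0 (ref) or 1 (alt)")
        if self.alignment_length < len(self.sites):
            raise ValueError("alignment_length smaller than the number of sites")
        self._site_index = {
            (str(g), int(p)): i
            for i, (g, p) in enumerate(zip(self.sites["gene_id"], self.sites["pos"]))
        }

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def has_site(self, site) -> bool:
        return (str(site[0]), int(site[1])) in self._site_index

    def site_states(self, site) -> np.ndarray:
        return self.states[self._site_index[(str(site[0]), int(site[1]))]]

    def site_alleles(self, site) -> tuple[str, str]:
        i = self._site_index[(str(site[0]), int(site[1]))]
        return str(self.sites["ref"].iloc[i]), str(self.sites["alt"].iloc[i])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.strains):
            df[s] = self.states[:, j]
        with open(path, "w") as fh:
            fh.write(f"# alignment_length={self.alignment_length}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, alignment_length: int | None = None, tree_newick=None, clade_map=None):
        with open(path) as fh:
            first = fh.readline()
        if alignment_length is None and first.startswith("#") and "alignment_length=" in first:
            alignment_length = int(first.split("alignment_length=")[1].strip())
        df = pd.read_csv(path, sep="\t", comment="#")
        strain_cols = [c for c in df.columns if c not in ("gene_id", "pos", "ref", "alt")]
        return cls(
            df[["gene_id", "pos", "ref", "alt"]].reset_index(drop=True),
            strain_cols,
            df[strain_cols].to_numpy(),
            alignment_length,
            tree_newick=tree_newick,
            clade_map=clade_map,
        )


# ---------------------------------------------------------------------------
# Distances and identities
# ---------------------------------------------------------------------------

def pairwise_snv_distance(h: StrainHaplotypeSet) -> pd.DataFrame:
    """Hamming distance (SNV count) between every pair of strain haplotypes."""
    x = h.states.astype(np.int32)
    # dist[i,j] = number of sites where columns i and j differ
    d = (x[:, :, None] != x[:, None, :]).sum(axis=0)
    return pd.DataFrame(d, index=h.strains, columns=h.strains)


def percent_identity(n_diff: int, alignment_length: int) -> float:
    """Percent sequence identity from a SNV count, rounded to 2 decimals."""
    if alignment_length <= 0:
        raise ValueError("alignment_length must be positive")
    if n_diff > alignment_length:
        raise ValueError("more differences than alignment positions")
    return round(100.0 * (1.0 - n_diff / alignment_length), 2)


def identity_matrix(h: StrainHaplotypeSet) -> pd.DataFrame:
    d = pairwise_snv_distance(h)
    return d.map(lambda n: percent_identity(int(n), h.alignment_length))


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

def _largest_gap_threshold(d: pd.DataFrame) -> float:
    """Midpoint of the largest gap in the sorted pairwise distance distribution."""
    vals = np.sort(d.values[np.triu_indices(len(d), k=1)].astype(float))
    if len(vals) < 2:
        return float(vals[0] + 1) if len(vals) else 1.0
    gaps = np.diff(vals)
    k = int(np.argmax(gaps))
    return float((vals[k] + vals[k + 1]) / 2.0)


def assign_clades(distances: pd.DataFrame, threshold: float | None = None) -> dict:
    """Group strains into clades by single linkage at a distance threshold.

    Strains joined by any chain of pairwise distances strictly below the
    threshold share a clade.  With ``threshold=None`` the midpoint of the
    largest gap in the sorted distance distribution is used, mirroring the
    visual separation of clades by long internal branches.  Clade labels are
    deterministic: clades ordered by their lexicographically smallest member
    and labeled "clade_1", "clade_2", ...
    """
    if threshold is None:
        threshold = _largest_gap_threshold(distances)
    elif threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(distances.index)
    strains = list(distances.index)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            if distances.loc[a, b] < threshold:
                g.add_edge(a, b)
    comps = sorted((sorted(c, key=str) for c in nx.connected_components(g)), key=lambda c: str(c[0]))
    return {s: f"clade_{k + 1}" for k, comp in enumerate(comps) for s in comp}


# ---------------------------------------------------------------------------
# Presence, dominance, dominant haplotypes
# ---------------------------------------------------------------------------

def strain_presence_and_dominance(
    frequencies: pd.DataFrame, present_min: float = 0.05, dominant_min: float = 0.90
) -> pd.DataFrame:
    """Per-sample present strain set and dominant strain (or None).

    ``frequencies`` is samples × strains with rows summing to 1.  A strain is
    present at frequency ≥ present_min; the dominant strain is the unique
    strain at frequency ≥ dominant_min (inclusive bounds).
    """
    rows = []
    for sample, row in frequencies.iterrows():
        if abs(row.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies for sample {sample} do not sum to 1")
        present = [s for s, f in row.items() if f >= present_min]
        dominant_candidates = [s for s, f in row.items() if f >= dominant_min]
        dominant = dominant_candidates[0] if len(dominant_candidates) == 1 else None
        rows.append({"sample": sample, "present": present, "n_present": len(present), "dominant": dominant})
    return pd.DataFrame(rows).set_index("sample")


def dominant_haplotype(m: AlleleCountMatrix, sample: str, major_min: float = 0.90) -> dict:
    """Per-site major allele at frequency ≥ major_min; sites below are undefined.

    Returns a dict site -> base, with undefined sites mapped to None
    (including zero-coverage sites).
    """
    freqs = m.frequencies(sample)
    out = {}
    for i, site in enumerate(m.sites):
        f = freqs[i]
        if np.isnan(f).any():
            out[site] = None
            continue
        j = int(np.argmax(f))
        out[site] = BASES[j] if f[j] >= major_min else None
    return out


def differential_snvs(h1: Mapping, h2: Mapping) -> tuple[int, int]:
    """Count sites where two dominant haplotypes carry different defined alleles.

    Sites undefined (None/missing) in either haplotype are excluded; the
    number of excluded sites is reported alongside.
    """
    sites = set(h1) | set(h2)
    n_diff = n_excluded = 0
    for site in sites:
        a, b = h1.get(site), h2.get(site)
        if a is None or b is None:
            n_excluded += 1
        elif a != b:
            n_diff += 1
    return n_diff, n_excluded


# ---------------------------------------------------------------------------
# Ancestral states and allele frequency spectra
# ---------------------------------------------------------------------------

def ancestral_states(h: StrainHaplotypeSet, tie_break_tip: str) -> dict:
    """Per-site ancestral allele: the state carried by the majority of strains.

    Ties are resolved by assigning one tip of the strain tree as ancestral,
    i.e. taking the tie-break strain's state.
    """
    if tie_break_tip not in h.strains:
        raise ValueError(f"unknown tie-break strain {tie_break_tip!r}")
    tb = h.strains.index(tie_break_tip)
    out = {}
    for i in range(h.n_sites):
        states = h.states[i]
        n_alt = int(states.sum())
        n_ref = len(states) - n_alt
        if n_alt > n_ref:
            anc = 1
        elif n_ref > n_alt:
            anc = 0
        else:
            anc = int(states[tb])
        site = (str(h.sites["gene_id"].iloc[i]), int(h.sites["pos"].iloc[i]))
        ref, alt = str(h.sites["ref"].iloc[i]), str(h.sites["alt"].iloc[i])
        out[site] = alt if anc == 1 else ref
    return out


def derived_afs(
    m: AlleleCountMatrix,
    sample: str,
    ancestral: Mapping,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Unfolded allele-frequency spectrum of one sample.

    For every biallelic site with a defined ancestral state and nonzero
    coverage, the derived-allele frequency is 1 minus the ancestral-allele
    frequency in the sample.  Frequencies are histogrammed over [0, 1] in
    ``n_bins`` equal-width right-closed bins (the first bin includes 0).

    Returns (counts, bin_edges).
    """
    freqs = m.frequencies(sample)
    pooled = m.counts.sum(axis=1)
    derived = []
    for i, site in enumerate(m.sites):
        anc = ancestral.get(site)
        if anc is None:
            continue
        if (pooled[i] > 0).sum() > 2:
            continue  # multi-state site: excluded from the unfolded spectrum
        f = freqs[i]
        if np.isnan(f).any():
            continue
        derived.append(1.0 - f[BASES.index(anc)])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for fd in derived:
        # right-closed bins: (e[k-1], e[k]], first bin includes 0
        k = int(np.ceil(fd * n_bins)) - 1
        counts[max(0, min(k, n_bins - 1))] += 1
    return counts, edges
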