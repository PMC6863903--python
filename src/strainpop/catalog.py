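"""Nonredundant gene catalog construction from precomputed similarity hits.

Ab initio predicted genes from per-sample assemblies are clustered by
single linkage over a filtered similarity-hit table (BLAST outfmt-6-like),
and each cluster is represented by a majority-consensus sequence.  Hit
filters guard against spurious links through widespread protein domains:
minimum identity over most of the shorter sequence, a cap on the length
ratio of the two genes, and no links between partial and complete genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    sample_id: str
    sequence: str
    is_partial: bool = False

    def __post_init__(self):
        if not self.sequence or any(b not in "ACGTN" for b in self.sequence.upper()):
            raise ValueError(f"gene {self.gene_id}: sequence must be non-empty over ACGTN")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float

    def __post_init__(self):
        if not (0 <= self.pct_identity <= 100):
            raise ValueError("pct_identity must be within [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be at least 1")


def read_genes_fasta(path) -> dict:
    """Read genes from FASTA; ``partial=TRUE/FALSE`` and ``sample=<id>`` in headers."""
    genes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        genes[rec.id] = GeneRecord(
            gene_id=rec.id,
            sample_id=fields.get("sample", ""),
            sequence=str(rec.seq).upper(),
            is_partial=fields.get("partial", "FALSE").upper() == "TRUE",
        )
    return genes


def read_hits_tsv(path) -> list[SimilarityHit]:
    """Read a BLAST outfmt-6-like hit table (qseqid sseqid pident length ... evalue ...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        SimilarityHit(str(r[0]), str(r[1]), float(r[2]), int(r[3]), float(r[10]))
        for r in df.itertuples(index=False)
    ]


def filter_hits(
    hits: Iterable[SimilarityHit],
    genes: Mapping[str, GeneRecord],
    id_min: float = 95.0,
    cov_min: float = 0.9,
    evalue_max: float = 1e-6,
    len_ratio_max: float = 4.0,
) -> set:
    """Accept hits as undirected clustering edges.

    A hit is kept iff identity ≥ id_min, the alignment covers at least
    cov_min of the shorter gene, evalue ≤ evalue_max, the gene length ratio
    is at most len_ratio_max, and both genes share partiality status.
    Self-hits are dropped; directed duplicates collapse to one edge.
    """
    edges = set()
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in genes:
                raise KeyError(f"hit references unknown gene id {gid!r}")
        if h.query_id == h.subject_id:
            continue
        q, s = genes[h.query_id], genes[h.subject_id]
        lq, ls = len(q), len(s)
        if (
            h.pct_identity >= id_min
            and h.aln_len >= cov_min * min(lq, ls)
            and h.evalue <= evalue_max
            and max(lq, ls) / min(lq, ls) <= len_ratio_max
            and q.is_partial == s.is_partial
        ):
            edges.add(frozenset((h.query_id, h.subject_id)))
    return edges


def single_linkage_cluster(edges: Iterable[frozenset], genes: Iterable[str]) -> dict:
    """Connected components over accepted edges; edge-less genes are singletons.

    Returns gene_id → cluster_id, where the cluster id is the
    lexicographically smallest member.  Order-independent by construction.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for e in edges:
        a, b = tuple(e)
        g.add_edge(a, b)
    out = {}
    for comp in nx.connected_components(g):
        cid = min(comp)
        for gid in comp:
            out[gid] = cid
    return out


def two_stage_cluster(
    hits: Sequence[SimilarityHit],
    genes: Mapping[str, GeneRecord],
    **filter_kwargs,
) -> dict:
    """Intra-sample clustering followed by cross-sample clustering.

    Stage one builds sample-specific catalogs from within-sample edges;
    stage two links stage-one clusters through cross-sample edges.  On
    inputs without borderline hits this partition coincides with one-stage
    clustering over the union of accepted edges.
    """
    edges = filter_hits(hits, genes, **filter_kwargs)
    intra = {e for e in edges if len({genes[g].sample_id for g in e}) == 1}
    cross = edges - intra
    stage1 = single_linkage_cluster(intra, genes.keys())
    # collapse stage-one clusters, then link them by cross-sample edges
    meta = nx.Graph()
    meta.add_nodes_from(set(stage1.values()))
    for e in cross:
        a, b = tuple(e)
        meta.add_edge(stage1[a], stage1[b])
    out = {}
    for comp in nx.connected_components(meta):
        cid = min(comp)
        for sub in comp:
            for gid, c in stage1.items():
                if c == sub:
                    out[gid] = cid
    return out


def consensus_sequence(members: Sequence[str], seed: int | np.random.Generator = 0) -> str:
    """Majority-consensus of a cluster, voting position-wise.

    Member sequences of the modal length are aligned by position and the
    modal nucleotide taken at each position; ties are resolved by a seeded
    uniform choice among the tied states.  Members of other lengths are
    excluded from the vote (the smallest modal length wins a length-count
    tie).
    """
    if not members:
        raise ValueError("empty cluster")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = pd.Series([len(s) for s in members])
    counts = lengths.value_counts()
    mode_len = int(min(counts.index[counts == counts.max()]))
    voters = [s.upper() for s in members if len(s) == mode_len]
    out = []
    for i in range(mode_len):
        col = [s[i] for s in voters]
        tally = pd.Series(col).value_counts()
        best = sorted(tally.index[tally == tally.max()])
        out.append(best[0] if len(best) == 1 else best[rng.integers(0, len(best))])
    return "".join(out)


def cluster_catalog(
    genes: Mapping[str, GeneRecord],
    hits: Sequence[SimilarityHit],
    seed: int = 0,
    **filter_kwargs,
) -> tuple[dict, dict]:
    """One-stage catalog: cluster assignment and consensus representatives."""
    edges = filter_hits(hits, genes, **filter_kwargs)
    assignment = single_linkage_cluster(edges, genes.keys())
    rng = np.random.default_rng(seed)
    reps = {}
    clusters: dict = {}
    for gid, cid in assignment.items():
        clusters.setdefault(cid, []).append(gid)
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        reps[cid] = consensus_sequence([genes[g].sequence for g in members], rng)
    return assignment, reps
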