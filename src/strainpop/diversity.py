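"""Strain-level α-diversity (PSE), β-diversity (weighted UniFrac), associations.

Phylogenetic species evenness (PSE) is an abundance-weighted α-diversity
that discounts closely related strains through the phylogenetic correlation
matrix C (shared root-to-tip branch length, standardized to unit diagonal):

    PSE = (N · Σ_i c_ii m_i − mᵀ C m) / (N² − N m̄)

over the strains present in the sample, with m the abundance vector,
N = Σ m_i and m̄ their mean.  A star phylogeny with equal abundances gives
PSE = 1; uneven abundances or correlated strains lower it.  β-diversity is
the normalized weighted UniFrac distance between two frequency vectors
placed on the strain tree.
"""

from __future__ import annotations

import io as _io
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.beta import weighted_unifrac as _skbio_wu


def read_tree(tree) -> TreeNode:
    """Accept a TreeNode, a newick string, or a path to a newick file."""
    if isinstance(tree, TreeNode):
        return tree
    text = str(tree)
    if "(" not in text:  # a path rather than newick text
        with open(text) as fh:
            text = fh.read()
    t = TreeNode.read(_io.StringIO(text))
    for node in t.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return t


def phylo_correlation(tree) -> pd.DataFrame:
    """Strain × strain phylogenetic correlation from shared branch lengths.

    Entry (i, j) is the root-to-MRCA branch length of tips i and j,
    standardized by the root-to-tip lengths to a unit diagonal.
    """
    t = read_tree(tree)
    tips = [tip.name for tip in t.tips()]
    depth = {}
    for node in t.preorder():
        parent_depth = depth.get(id(node.parent), 0.0)
        depth[id(node)] = parent_depth + (node.length or 0.0)
    n = len(tips)
    v = np.zeros((n, n))
    tip_nodes = list(t.tips())
    for i in range(n):
        v[i, i] = depth[id(tip_nodes[i])]
        for j in range(i + 1, n):
            lca = t.lowest_common_ancestor([tip_nodes[i], tip_nodes[j]])
            v[i, j] = v[j, i] = depth[id(lca)]
    d = np.sqrt(np.diag(v))
    if (d == 0).any():
        raise ValueError("tips at zero distance from the root; correlation undefined")
    c = v / np.outer(d, d)
    return pd.DataFrame(c, index=tips, columns=tips)


def _as_series(abundances, tips) -> pd.Series:
    s = pd.Series(abundances, dtype=float)
    unknown = set(s.index) - set(tips)
    if unknown:
        raise ValueError(f"abundances name tips absent from the tree: {sorted(unknown)}")
    return s.reindex(tips, fill_value=0.0)


def pse(tree, abundances) -> float:
    """Phylogenetic species evenness of one sample.

    ``abundances`` maps strain (tip) names to nonnegative abundances or
    frequencies (scale-invariant).  Undefined (NaN, warning) when fewer than
    two strains are present.
    """
    t = read_tree(tree)
    tips = [tip.name for tip in t.tips()]
    m = _as_series(abundances, tips)
    if (m < 0).any():
        raise ValueError("abundances must be nonnegative")
    if m.sum() <= 0:
        raise ValueError("at least one abundance must be positive")
    present = m[m > 0]
    if len(present) < 2:
        warnings.warn("fewer than two strains present; PSE undefined", stacklevel=2)
        return float("nan")
    c = phylo_correlation(t).loc[present.index, present.index].to_numpy()
    mv = present.to_numpy()
    n_tot = mv.sum()
    num = n_tot * float(np.diag(c) @ mv) - float(mv @ c @ mv)
    den = n_tot**2 - n_tot * mv.mean()
    return num / den


def psv(tree, present_tips=None) -> float:
    """Phylogenetic species variability: PSE at equal abundances."""
    t = read_tree(tree)
    tips = [tip.name for tip in t.tips()] if present_tips is None else list(present_tips)
    c = phylo_correlation(t).loc[tips, tips].to_numpy()
    n = len(tips)
    if n < 2:
        return float("nan")
    return (n * np.trace(c) - c.sum()) / (n * (n - 1))


def weighted_unifrac(tree, a, b) -> float:
    """Normalized weighted UniFrac distance between two strain communities.

    ``a`` and ``b`` map tip names to relative frequencies summing to 1.
    Equals Σ_b l_b |p_a(b) − p_b(b)| / Σ_b l_b (p_a(b) + p_b(b)) over
    branches, where p_x(b) is the community fraction descending from branch
    b; 0 for identical communities, 1 for communities on disjoint subtrees.
    """
    t = read_tree(tree)
    if len(t.children) > 2:
        # bifurcate a multifurcating root with a zero-length internal node;
        # a zero-length branch contributes nothing to either UniFrac sum
        extra = t.children[1:]
        group = TreeNode(length=0.0)
        for child in extra:
            t.remove(child)
            group.append(child)
        t.append(group)
    tips = [tip.name for tip in t.tips()]
    total = sum((node.length or 0.0) for node in t.traverse())
    if total == 0:
        raise ValueError("zero-length tree")
    va = _as_series(a, tips)
    vb = _as_series(b, tips)
    for name, v in (("a", va), ("b", vb)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequency vector {name} does not sum to 1")
    # the array-based UniFrac works on integer counts; the normalized distance
    # depends only on within-community proportions, so a fixed large total is
    # exact to ~1e-9
    ca = np.round(va.to_numpy() * 1_000_000_000).astype(np.int64)
    cb = np.round(vb.to_numpy() * 1_000_000_000).astype(np.int64)
    return float(_skbio_wu(ca, cb, taxa=tips, tree=t, normalized=True))


def rank_association(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation of paired vectors: (ρ, ρ², p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("paired vectors of equal length >= 4 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector; rank correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    return rho, rho**2, float(res.pvalue)


def matrix_association(
    d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Mantel-style permutation test between two paired distance matrices.

    The statistic is the Spearman correlation of the off-diagonal entries;
    significance is assessed by permuting the sample labels of the second
    matrix, with p = (1 + #{perm ≥ obs}) / (1 + n_perm) (one-sided, positive
    association).
    """
    if list(d1.index) != list(d2.index) or list(d1.columns) != list(d2.columns):
        raise ValueError("distance matrices must share the same sample set and order")
    n = len(d1)
    if n < 4:
        raise ValueError("at least 4 samples required")
    for name, d in (("d1", d1), ("d2", d2)):
        if not np.allclose(d.values, d.values.T, equal_nan=True):
            raise ValueError(f"{name} is not symmetric")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    x = d1.to_numpy()[iu]

    def statistic(mat):
        return stats.spearmanr(x, mat[iu]).statistic

    m2 = d2.to_numpy()
    obs = statistic(m2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if statistic(m2[np.ix_(perm, perm)]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)
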