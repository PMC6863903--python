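"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: π oracles enumerate read
pairs explicitly, the UniFrac oracle traverses the tree per branch.
"""

import io
import itertools

import numpy as np
from skbio import TreeNode


def pi_intra_site_oracle(counts4) -> float:
    """Fraction of differing unordered read pairs at one site.

    ``counts4`` are the A/C/G/T read counts; requires coverage >= 2.
    """
    reads = []
    for b, n in zip("ACGT", counts4):
        reads.extend([b] * int(n))
    pairs = list(itertools.combinations(reads, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def pi_inter_site_oracle(counts4_a, counts4_b) -> float:
    """Probability that one read from each sample differs, by full enumeration."""
    ca, cb = np.asarray(counts4_a, float), np.asarray(counts4_b, float)
    fa, fb = ca / ca.sum(), cb / cb.sum()
    return float(sum(fa[i] * fb[j] for i in range(4) for j in range(4) if i != j))


def weighted_unifrac_oracle(newick: str, a: dict, b: dict) -> float:
    """Normalized weighted UniFrac by per-branch summation over a traversal."""
    t = TreeNode.read(io.StringIO(newick))
    num = den = 0.0
    for node in t.traverse(include_self=False):
        tips = [x.name for x in node.tips()] or [node.name]
        pa = sum(a.get(n, 0.0) for n in tips)
        pb = sum(b.get(n, 0.0) for n in tips)
        length = node.length or 0.0
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den


def random_binary_newick(rng, n_tips: int) -> tuple[str, list]:
    """A random rooted binary tree with uniform branch lengths in (0.1, 1)."""
    names = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{n}:{rng.uniform(0.1, 1.0):.4f}" for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1.0):.4f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]});", names
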