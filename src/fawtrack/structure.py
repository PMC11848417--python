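"""Ordination and tree summaries of genetic structure.

Three views of the same dosage matrix:

* PCA with Patterson normalization — each locus is centered by twice
  its allele frequency and scaled by the binomial standard deviation
  sqrt(2p(1-p)), missing dosages mean-imputed, eigendecomposition of
  the sample-sample covariance;
* identity-by-state (allele-sharing) distances,
  d(i,j) = mean |dosage_i - dosage_j| / 2 over co-called loci;
* Saitou-Nei neighbor joining on those distances, with optional
  outgroup rooting and bootstrap support from locus resampling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from fawtrack.core import GenotypeMatrix


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray          # samples x components (PC scores)
    explained_fraction: np.ndarray   # per-component fraction of variance


def dosage_pca(
    matrix: GenotypeMatrix, maf_min: float = 0.05, n_components: int | None = None
) -> PcaResult:
    """Patterson-normalized PCA of the dosage matrix.

    Loci with minor-allele frequency below ``maf_min`` (computed on
    called genotypes) are excluded. Scores are eigenvectors scaled by
    the square root of their eigenvalues; axis signs are arbitrary.
    """
    X = matrix.dosages
    n, L = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_called = (~np.isnan(X)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep = (n_called > 0) & (maf >= maf_min) & (maf > 0.0)
    if not keep.any():
        raise ValueError(
            f"no polymorphic loci remain after the MAF >= {maf_min} filter"
        )
    X = X[:, keep]
    p = p[keep]

    X = np.where(np.isnan(X), 2.0 * p, X)        # mean imputation
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    M = Z @ Z.T / Z.shape[1]
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    explained = eigval / eigval.sum()
    k = n_components if n_components is not None else min(n - 1, Z.shape[1])
    k = min(k, n)
    return PcaResult(
        samples=list(matrix.samples),
        coordinates=eigvec[:, :k] * np.sqrt(eigval[:k]),
        explained_fraction=explained[:k],
    )


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray    # symmetric, zero diagonal


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance over co-called loci, in [0, 1].

    A pair with no co-called locus is an error: the distance is
    undefined and any tree built on it would be arbitrary.
    """
    X = matrix.dosages
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    called = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no called loci"
                )
            D[i, j] = D[j, i] = float(
                np.abs(X[i, both] - X[j, both]).mean() / 2.0
            )
    return DistanceMatrix(samples=list(matrix.samples), values=D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "length", "children", "leaves", "support")

    def __init__(self, name=None, length=0.0, children=None, leaves=None):
        self.name = name
        self.length = length
        self.children = children or []
        self.leaves = leaves or frozenset([name])
        self.support = None

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.17g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.17g}"


def _nj_tree(names: list[str], D: np.ndarray) -> _Node:
    """Canonical Saitou-Nei NJ. Ties in the Q matrix go to the
    lowest-index pair; a negative branch length is clamped to 0 with
    the deficit shifted to its sister branch."""
    nodes = [_Node(name=nm) for nm in names]
    D = D.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair on ties: argmin of flattened array scans row-major
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        new = _Node(
            children=[nodes[i], nodes[j]],
            leaves=nodes[i].leaves | nodes[j].leaves,
        )
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2
    if len(nodes) == 3:
        a, b, c = D[0, 1], D[0, 2], D[1, 2]
        lens = [(a + b - c) / 2.0, (a + c - b) / 2.0, (b + c - a) / 2.0]
        lens = [max(0.0, x) for x in lens]
        for node, ln in zip(nodes, lens):
            node.length = ln
    elif len(nodes) == 2:
        nodes[0].length = 0.0
        nodes[1].length = D[0, 1]
    root = _Node(children=nodes, leaves=frozenset().union(*(n.leaves for n in nodes)))
    root.length = 0.0
    return root


def _bipartitions(root: _Node, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted tree, each encoded as
    the lexicographically smaller side."""
    out = set()
    stack = list(root.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if not node.children:
            continue
        side = node.leaves
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(key)
    return out


def neighbor_joining(
    dist: DistanceMatrix, outgroup: list[str] | None = None
) -> str:
    """NJ tree in newick. With an outgroup, the tree is rooted on the
    edge separating the outgroup from the remaining samples."""
    if len(dist.samples) < 3:
        raise ValueError("NJ needs at least 3 samples")
    root = _nj_tree(dist.samples, dist.values)
    nwk = root.newick()
    if not outgroup:
        return nwk
    missing = set(outgroup) - set(dist.samples)
    if missing:
        raise KeyError(f"outgroup samples not in matrix: {sorted(missing)}")
    return _root_on_outgroup(nwk, outgroup)


def _root_on_outgroup(nwk: str, outgroup: list[str]) -> str:
    tree = TreeNode.read(io.StringIO(nwk))
    if len(outgroup) == 1:
        target = tree.find(outgroup[0])
    else:
        tips = [tree.find(nm) for nm in outgroup]
        target = tree.lca(tips)
        if target is tree.root():
            # outgroup spans the current root; root relative to the rest
            rest = [t for t in tree.tips() if t.name not in set(outgroup)]
            target = tree.lca(rest) if len(rest) > 1 else rest[0]
    rooted = tree.root_at(target, above=True, branch_attrs=[])
    return str(rooted).strip()


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    outgroup: list[str] | None = None,
) -> str:
    """NJ tree with bootstrap support (fraction of locus-resampled
    replicates containing each internal bipartition) as internal node
    labels."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dist = ibs_distance(matrix)
    root = _nj_tree(dist.samples, dist.values)
    all_leaves = root.leaves

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        rep = matrix.take_loci(idx)
        rep_root = _nj_tree(dist.samples, ibs_distance(rep).values)
        for bp in _bipartitions(rep_root, all_leaves):
            counts[bp] = counts.get(bp, 0) + 1

    stack = list(root.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.children:
            side = node.leaves
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                key = min(side, other, key=lambda s: (len(s), sorted(s)))
                node.support = counts.get(key, 0) / n_reps
    nwk = root.newick()
    if outgroup:
        nwk = _root_on_outgroup(nwk, outgroup)
    return nwk
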