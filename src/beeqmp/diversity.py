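"""Alpha diversity, dissimilarity matrices, neighbor joining, weighted
UniFrac, and NMDS ordination.

Distance outputs are :class:`skbio.DistanceMatrix` objects (symmetric, zero
diagonal); Bray-Curtis, quantitative Jaccard and normalized weighted UniFrac
entries lie in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from sklearn.manifold import MDS

from .datamodel import CountMatrix

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "jaccard_quant",
    "nj_tree",
    "weighted_unifrac",
    "nmds",
    "NMDSResult",
]


def alpha_diversity(abund: CountMatrix, base: float | None = None) -> pd.DataFrame:
    """Shannon (H), Simpson (D = 1 - sum p^2), and Pielou evenness (J = H/ln S).

    ``base`` changes the Shannon logarithm (natural log by default, the
    ecology-toolchain convention); J is base-invariant.  S is observed
    richness (taxa with positive abundance); J is undefined (NaN) for
    single-taxon samples.
    """
    X = abund.values
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(abund.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    P = X / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(P), 0.0)
    H = -(P * logp).sum(axis=1)
    D = 1.0 - (P**2).sum(axis=1)
    S = (X > 0).sum(axis=1)
    logS = np.log(np.where(S > 1, S, 2.0))
    J = np.where(S > 1, H / logS, np.nan)
    if base is not None:
        H = H / np.log(base)
    return pd.DataFrame(
        {"H": H, "D": D, "J": J, "S_obs": S}, index=abund.data.index
    )


def _pairwise_bc(abund: CountMatrix) -> np.ndarray:
    X = abund.values
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn(
            "all-zero sample pair(s); their Bray-Curtis distance is defined as 0",
            stacklevel=3,
        )
        d = np.nan_to_num(d, nan=0.0)
    return d


def bray_curtis(abund: CountMatrix) -> DistanceMatrix:
    """BC(x, y) = sum|x_a - y_a| / sum(x_a + y_a)."""
    return DistanceMatrix(_pairwise_bc(abund), ids=abund.sample_ids)


def jaccard_quant(abund: CountMatrix) -> DistanceMatrix:
    """Quantitative (abundance-weighted) Jaccard: 2 BC / (1 + BC)."""
    bc = _pairwise_bc(abund)
    return DistanceMatrix(2.0 * bc / (1.0 + bc), ids=abund.sample_ids)


def nj_tree(d: DistanceMatrix, midpoint_root: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining from a distance matrix.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sibling edge, preserving the pairwise path length.  The unrooted
    tree is midpoint-rooted by default (required downstream by UniFrac).
    Agglomeration ties break on taxon name order, so the result is invariant
    to input taxon order.
    """
    ids = list(d.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = {a: {b: float(d[a, b]) for b in ids} for a in ids}
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in ids}
    active = sorted(ids)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[a][b] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        counter += 1
        new = f"__internal{counter}"
        nodes[a].length = la
        nodes[b].length = lb
        nodes[new] = TreeNode(children=[nodes[a], nodes[b]])
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = dc
            D[c][new] = dc
        active = sorted(c for c in active if c not in (a, b)) + [new]
        active.sort()
    # join the final three nodes at an unrooted center
    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    lengths = [la, lb, lc]
    for i in range(3):
        if lengths[i] < 0:  # clamp; spread deficit over the other two edges
            deficit = lengths[i]
            lengths[i] = 0.0
            for j in range(3):
                if j != i:
                    lengths[j] += deficit / 2.0
    for node, length in zip((a, b, c), lengths):
        nodes[node].length = max(length, 0.0)
    tree = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return tree


def _branch_profile(tree: TreeNode, abund: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch descendant abundance fractions.

    Returns ``(lengths, P)`` with ``P`` of shape (n_branches, n_samples):
    the fraction of each sample's total abundance descending from each
    branch.  Tree leaves must cover the ASV set; extra leaves get zero
    abundance.
    """
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(abund.asv_ids) - tips)
    if missing:
        raise ValueError(f"tree is missing leaves for ASV(s): {missing}")
    X = abund.values
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(abund.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    rel = X / totals[:, None]
    col = {a: i for i, a in enumerate(abund.asv_ids)}
    lengths, profiles = [], []
    node_profile: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            p = (
                rel[:, col[node.name]]
                if node.name in col
                else np.zeros(rel.shape[0])
            )
        else:
            p = np.zeros(rel.shape[0])
            for child in node.children:
                p = p + node_profile[id(child)]
        node_profile[id(node)] = p
        if node.parent is not None:
            length = node.length if node.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length at node {node.name!r}")
            lengths.append(length)
            profiles.append(p)
    return np.asarray(lengths), np.asarray(profiles)


def weighted_unifrac(
    abund: CountMatrix, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac: sum_b l_b |p_b^A - p_b^B| over branches.

    ``p_b`` is the fraction of a sample's total abundance descending from
    branch *b*; the normalized variant divides by sum_b l_b (p_b^A + p_b^B),
    bounding entries in [0, 1].
    """
    lengths, P = _branch_profile(tree, abund)
    n = P.shape[1]
    W = lengths[:, None] * P
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(W[:, i : i + 1] - W[:, i + 1 :]).sum(axis=0)
        if normalized:
            den = (W[:, i : i + 1] + W[:, i + 1 :]).sum(axis=0)
            diff = np.divide(diff, den, out=np.zeros_like(diff), where=den > 0)
        out[i, i + 1 :] = diff
        out[i + 1 :, i] = diff
    return DistanceMatrix(out, ids=abund.sample_ids)


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 16,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-7,
) -> NMDSResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs ``n_starts`` random initializations of iterative monotone-regression
    (SMACOF) and returns the best embedding with its stress.
    """
    n = len(d.ids)
    if k >= n - 1:
        raise ValueError(f"k={k} requires at least {k + 2} samples, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(
            n_components=k,
            metric_mds=False,
            n_init=int(n_starts),
            max_iter=int(max_iter),
            eps=eps,
            random_state=int(seed) % (2**31),
            metric="precomputed",
            normalized_stress=True,
            init="random",
        )
        coords = model.fit_transform(np.asarray(d.data))
    df = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NMDSResult(coordinates=df, stress=float(model.stress_))
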