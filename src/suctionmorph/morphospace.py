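"""Skull-shape morphospace and the C1 convergence test.

The skull-shape characters are z-scored per character (mean 0, SD 1 with
the n-1 denominator) and decomposed by PCA; taxa are projected into the
resulting morphospace and the phylogeny is drawn through it by placing
internal nodes at their ML Brownian-motion ancestral estimates
(a phylomorphospace).

Convergence between two tips is quantified by Stayton's C1:

    C1 = 1 - Dtip / Dmax

where Dtip is the Euclidean distance between the two tips over all
retained axes and Dmax is the maximum distance between any pair of
states — reconstructed ancestors or the tips themselves, one taken from
each lineage — along the two paths from their most recent common
ancestor. C1 = 1 means the tips have closed all the morphological
distance their lineages ever opened; C1 <= 0 means they are no closer
than their most divergent ancestors. For a focal set of putative
convergers the statistic is the mean pairwise C1, and its significance is
assessed against tip data re-simulated under multivariate Brownian
motion with the rate matrix estimated from the observed scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import CharacterMatrix
from .phylo import Phylogeny


@dataclass
class MorphospaceResult:
    """Standardized PCA of a character matrix."""

    taxa: list[str]
    scores: np.ndarray          # (n, r) taxon coordinates
    loadings: np.ndarray        # (k, r) character loadings (eigenvectors)
    variance_fraction: np.ndarray  # (r,) sums to 1 over retained axes
    dropped: list[str]          # zero-variance characters removed
    means: np.ndarray
    sds: np.ndarray
    characters: list[str]


@dataclass
class ConvergenceResult:
    """Mean pairwise C1 over a focal set with its simulation p-value."""

    focal: list[str]
    pairs: list[tuple[str, str]]
    c1: np.ndarray
    dtip: np.ndarray
    dmax: np.ndarray
    mean_c1: float
    p: float
    n_sim: int
    seed: int


def standardized_pca(
    matrix: CharacterMatrix, impute_mean: bool = False
) -> MorphospaceResult:
    """PCA of the per-character z-scored matrix.

    Zero-variance characters are dropped with a warning; missing values
    are an error unless ``impute_mean`` fills them with the character
    mean. Axis signs are fixed so each axis's largest-magnitude loading
    is positive, making reports reproducible across platforms.
    """
    X = matrix.scores.astype(float).copy()
    names = list(matrix.character_names)
    if not np.isfinite(X).all():
        if not impute_mean:
            raise ValueError(
                "missing values in the skull matrix; pass impute_mean=True "
                "to fill with character means")
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(~np.isfinite(X))
        X[idx] = col_mean[idx[1]]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance characters: {dropped}",
                      stacklevel=2)
    if not keep.any():
        raise ValueError("all characters are constant")
    Z = (X[:, keep] - means[keep]) / sds[keep]
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s.max() * max(Z.shape) * np.finfo(float).eps
    r = int((s > tol).sum())
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    # deterministic sign: largest |loading| positive per axis
    for j in range(r):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigvals = s**2 / (n - 1)
    return MorphospaceResult(
        taxa=list(matrix.taxa),
        scores=U * s,
        loadings=Vt.T,
        variance_fraction=eigvals / eigvals.sum(),
        dropped=dropped,
        means=means[keep],
        sds=sds[keep],
        characters=[n_ for n_, k in zip(names, keep) if k],
    )


def phylomorphospace(
    tree: Phylogeny, result: MorphospaceResult, axes: tuple[int, int] = (0, 1)
) -> dict:
    """Tip and ancestral coordinates on two axes, with the edge list.

    Internal nodes sit at their ML Brownian-motion ancestral estimates,
    so tree edges can be drawn through the morphospace.
    """
    coords = {t: result.scores[i, list(axes)]
              for i, t in enumerate(result.taxa)}
    Y = tree.tip_order(coords)
    anc = tree.ancestral_states(Y)
    node_xy: dict[int | str, np.ndarray] = {
        lbl: Y[i] for i, lbl in enumerate(tree.tip_labels)}
    for r in range(anc.shape[0]):
        node_xy[tree.n_tips + r] = anc[r]
    edges = []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            child = tree.tip_labels[i] if i < tree.n_tips else i
            edges.append((int(p), child))
    return {"nodes": node_xy, "edges": edges, "root": int(tree.root)}


def _lineage_paths(tree: Phylogeny, a: int, b: int) -> tuple[int, list[int], list[int]]:
    """MRCA and the node paths (MRCA .. tip) down each lineage."""
    mrca = tree.mrca(a, b)
    def path(tip: int) -> list[int]:
        up = []
        nd = tip
        while nd != mrca:
            up.append(nd)
            nd = int(tree.parent[nd])
        up.append(mrca)
        return up[::-1]
    return mrca, path(a), path(b)


def _node_states(tree: Phylogeny, tips: np.ndarray, anc: np.ndarray,
                 nodes: list[int]) -> np.ndarray:
    return np.stack([
        tips[nd] if nd < tree.n_tips else anc[nd - tree.n_tips]
        for nd in nodes
    ])


def c1_pair(
    tree: Phylogeny,
    full_scores: np.ndarray | dict,
    tip_a: str,
    tip_b: str,
    ancestors_only: bool = False,
    clamp: bool = False,
) -> tuple[float, float, float]:
    """Stayton's C1 for one pair of tips over all supplied axes.

    ``ancestors_only`` restricts the Dmax candidates to reconstructed
    internal nodes (the looser 'distance between ancestral nodes'
    reading); the default includes the tips themselves, one candidate
    taken from each lineage. Negative C1 (divergence beyond the ancestral
    maximum) is reported as-is unless ``clamp``.
    """
    Y = (full_scores if isinstance(full_scores, np.ndarray)
         else tree.tip_order(full_scores))
    ia, ib = tree.tip_index(tip_a), tree.tip_index(tip_b)
    if ia == ib:
        raise ValueError("c1_pair needs two distinct tips")
    anc = tree.ancestral_states(Y)
    return _c1_from_states(tree, Y, anc, ia, ib, ancestors_only, clamp)


def _c1_from_states(tree, tips, anc, ia, ib, ancestors_only=False,
                    clamp=False) -> tuple[float, float, float]:
    _, pa, pb = _lineage_paths(tree, ia, ib)
    if ancestors_only:
        pa = pa[:-1]
        pb = pb[:-1]
    A = _node_states(tree, tips, anc, pa)
    B = _node_states(tree, tips, anc, pb)
    diff = A[:, None, :] - B[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    dmax = float(D.max())
    dtip = float(np.linalg.norm(tips[ia] - tips[ib]))
    scale = max(1.0, float(np.abs(A).max()), float(np.abs(B).max()))
    if dmax <= 1e-12 * scale:
        warnings.warn("Dmax = 0 (no divergence along either lineage); "
                      "C1 set to 0", stacklevel=2)
        return 0.0, dtip, 0.0
    c1 = 1.0 - dtip / dmax
    if clamp:
        c1 = max(c1, 0.0)
    return c1, dtip, dmax


def _mean_c1(tree, tips, anc, pairs_idx, ancestors_only=False) -> float:
    vals = [
        _c1_from_states(tree, tips, anc, ia, ib, ancestors_only)[0]
        for ia, ib in pairs_idx
    ]
    return float(np.mean(vals))


def c1_group_test(
    tree: Phylogeny,
    full_scores: np.ndarray | dict,
    focal: list[str],
    n_sim: int = 1000,
    seed: int = 0,
    ancestors_only: bool = False,
    diagonal_rate: bool = False,
) -> ConvergenceResult:
    """Mean pairwise C1 over a focal set, with a BM simulation null.

    The observed statistic is the mean C1 over all focal pairs. The null
    re-simulates tip values under multivariate Brownian motion with the
    rate matrix estimated from the observed scores (root at the GLS
    ancestral mean) and recomputes the statistic per replicate;
    p = (1 + #{sim >= observed}) / (n_sim + 1).
    """
    if len(focal) < 2:
        raise ValueError("focal set needs at least 2 taxa")
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} gives coarse p-value resolution",
                      stacklevel=2)
    Y = (full_scores if isinstance(full_scores, np.ndarray)
         else tree.tip_order(full_scores))
    idx = [tree.tip_index(t) for t in focal]
    pairs_idx = [(idx[i], idx[j]) for i in range(len(idx))
                 for j in range(i + 1, len(idx))]
    anc = tree.ancestral_states(Y)
    per_pair = [
        _c1_from_states(tree, Y, anc, ia, ib, ancestors_only)
        for ia, ib in pairs_idx
    ]
    observed = float(np.mean([v[0] for v in per_pair]))

    R = tree.estimate_rate_matrix(Y)
    if diagonal_rate:
        R = np.diag(np.diag(R))
    root = tree.phylogenetic_mean(Y)
    sims = tree.simulate_bm(R, root, n_sim, seed)
    S = tree._ancestral_solver()
    count = 0
    for r in range(n_sim):
        tips_r = sims[r]
        anc_r = S @ tips_r
        if _mean_c1(tree, tips_r, anc_r, pairs_idx, ancestors_only) >= observed:
            count += 1
    return ConvergenceResult(
        focal=list(focal),
        pairs=[(focal[i], focal[j]) for i in range(len(focal))
               for j in range(i + 1, len(focal))],
        c1=np.array([v[0] for v in per_pair]),
        dtip=np.array([v[1] for v in per_pair]),
        dmax=np.array([v[2] for v in per_pair]),
        mean_c1=observed,
        p=(1.0 + count) / (n_sim + 1),
        n_sim=n_sim,
        seed=seed,
    )


def plot_phylomorphospace(tree, result, labels=None, path=None,
                          axes=(0, 1)):
    """Minimal phylomorphospace scatter (SVG/PNG via matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pm = phylomorphospace(tree, result, axes)
    fig, ax = plt.subplots(figsize=(6, 5))
    for p, child in pm["edges"]:
        a = pm["nodes"][p]
        b = pm["nodes"][child]
        ax.plot([a[0], b[0]], [a[1], b[1]], color="0.7", lw=0.8, zorder=1)
    for lbl in tree.tip_labels:
        x, y = pm["nodes"][lbl]
        color = "tab:red" if labels is not None and labels[lbl] == "Suction" \
            else "tab:blue"
        ax.scatter([x], [y], s=18, color=color, zorder=2)
    vf = result.variance_fraction
    ax.set_xlabel(f"PC{axes[0]+1} ({100*vf[axes[0]]:.1f}%)")
    ax.set_ylabel(f"PC{axes[1]+1} ({100*vf[axes[1]]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
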