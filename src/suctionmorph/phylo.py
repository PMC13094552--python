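"""Tree handling and Brownian-motion machinery.

A :class:`Phylogeny` wraps a rooted, branch-lengthed tree (parsed with
dendropy) in flat arrays convenient for the comparative methods used
downstream:

* the phylogenetic variance-covariance matrix V, with V[i, j] the shared
  root-to-MRCA path length of tips i and j (the expected trait covariance
  under Brownian motion with unit rate);
* maximum-likelihood ancestral state reconstruction under BM, obtained by
  solving the weighted squared-change parsimony linear system (for a
  Gaussian process the joint mode equals the marginal means, so this is
  exactly the ML/GLS reconstruction, and the root estimate is the GLS
  phylogenetic mean);
* the multivariate BM rate-matrix estimator on phylogenetic GLS
  residuals; and
* a seeded multivariate BM simulator drawing independent increments edge
  by edge, so tip values follow MVN(root, kron(R, V)).

Polytomies are accepted; zero-length branches are handled by an epsilon
proportional to tree depth wherever a reciprocal branch length or an
inverse of V is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_io import normalize_name

_EPS_REL = 1e-8  # zero-branch epsilon, as a fraction of tree depth


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass
class CovarianceStructure:
    """Phylogenetic covariance V (n x n) with its taxon order."""

    V: np.ndarray
    taxa: list[str]


@dataclass
class PruneReport:
    """Names dropped on each side when intersecting a tree with a table."""

    kept: list[str]
    dropped_from_tree: list[str]
    dropped_from_table: list[str]


class Phylogeny:
    """Rooted tree with branch lengths, flat-array representation.

    Nodes are indexed 0..m-1 with tips first (0..n_tips-1, in the order of
    ``tip_labels``); the root is last in ``preorder``. ``parent[i]`` is -1
    for the root; ``blen[i]`` is the length of the branch above node i
    (0 for the root).
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self._dendropy = tree
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        labels = []
        for nd in tips:
            lbl = nd.taxon.label if nd.taxon is not None else None
            if not lbl:
                raise NewickError("tree contains an unlabeled tip")
            labels.append(lbl)
        keys = [normalize_name(l) for l in labels]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")

        order = tips + internals[::-1]  # tips, then internals with root last
        index = {id(nd): i for i, nd in enumerate(order)}
        m = len(order)
        self.n_tips = len(tips)
        self.n_nodes = m
        self.tip_labels = labels
        self._tip_index = {k: i for i, k in enumerate(keys)}
        self.parent = np.full(m, -1, dtype=int)
        self.blen = np.zeros(m)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise NewickError(
                        f"missing branch length above node "
                        f"{labels[i] if i < self.n_tips else i!r}"
                    )
                if nd.edge.length < 0:
                    raise NewickError("negative branch length")
                self.blen[i] = float(nd.edge.length)
        self.root = index[id(tree.seed_node)]
        # children lists and a preorder over indices
        self.children: list[list[int]] = [[] for _ in range(m)]
        for i in range(m):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.preorder = [index[id(nd)] for nd in nodes]
        self.depth = np.zeros(m)
        for i in self.preorder:
            p = self.parent[i]
            if p >= 0:
                self.depth[i] = self.depth[p] + self.blen[i]
        self._vcv: np.ndarray | None = None
        self._anc_solver: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text(encoding="utf-8"))

    def to_newick(self) -> str:
        return self._dendropy.as_string(schema="newick").strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")

    # -- basic queries -----------------------------------------------------
    def tip_index(self, label: str) -> int:
        return self._tip_index[normalize_name(label)]

    def tip_order(self, values: Mapping[str, float | np.ndarray]) -> np.ndarray:
        """Stack a taxon -> value mapping into tip order (n_tips, k)."""
        keyed = {normalize_name(t): np.atleast_1d(np.asarray(v, dtype=float))
                 for t, v in values.items()}
        missing = [l for l in self.tip_labels if normalize_name(l) not in keyed]
        if missing:
            raise KeyError(f"no values for tips: {missing}")
        return np.stack([keyed[normalize_name(l)] for l in self.tip_labels])

    def tree_depth(self) -> float:
        return float(self.depth[: self.n_tips].max())

    def path_to_root(self, node: int) -> list[int]:
        out = [node]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, a: int, b: int) -> int:
        anc_a = set(self.path_to_root(a))
        for nd in self.path_to_root(b):
            if nd in anc_a:
                return nd
        raise RuntimeError("disconnected tree")  # unreachable on valid trees

    # -- pruning -----------------------------------------------------------
    def prune_to(self, taxa: Sequence[str]) -> tuple["Phylogeny", PruneReport]:
        """Restrict the tree to taxa shared with ``taxa``.

        Degree-2 nodes created by pruning are collapsed with branch
        lengths summed, so root-to-tip depths of kept tips are preserved.
        """
        wanted = {normalize_name(t): t for t in taxa}
        kept = [l for l in self.tip_labels if normalize_name(l) in wanted]
        dropped_tree = [l for l in self.tip_labels if normalize_name(l) not in wanted]
        tree_keys = {normalize_name(l) for l in self.tip_labels}
        dropped_table = [t for k, t in wanted.items() if k not in tree_keys]
        if len(kept) < 3:
            raise ValueError(
                f"fewer than 3 taxa shared between tree and table "
                f"(tree-only: {dropped_tree}; table-only: {dropped_table})"
            )
        report = PruneReport(kept, dropped_tree, dropped_table)
        if not dropped_tree:
            return self, report
        tree = self._dendropy.clone(depth=1)
        keep_keys = {normalize_name(l) for l in kept}
        keep_taxa = [t for t in tree.taxon_namespace
                     if normalize_name(t.label) in keep_keys]
        tree.retain_taxa(keep_taxa)  # collapses unifurcations, sums lengths
        return Phylogeny(tree), report

    # -- covariance --------------------------------------------------------
    def vcv(self) -> CovarianceStructure:
        """V[i, j] = root-to-MRCA(i, j) path length (tips i, j)."""
        if self._vcv is None:
            n = self.n_tips
            V = np.zeros((n, n))
            tipsets: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for nd in reversed(self.preorder):  # postorder
                if nd < n:
                    tipsets[nd] = [nd]
                else:
                    kids = self.children[nd]
                    for a in range(len(kids)):
                        for b in range(a + 1, len(kids)):
                            ta = tipsets[kids[a]]
                            tb = tipsets[kids[b]]
                            V[np.ix_(ta, tb)] = self.depth[nd]
                            V[np.ix_(tb, ta)] = self.depth[nd]
                    tipsets[nd] = [t for k in kids for t in tipsets[k]]
            np.fill_diagonal(V, self.depth[:n])
            self._vcv = V
        return CovarianceStructure(self._vcv.copy(), list(self.tip_labels))

    def _regularized_vcv(self) -> np.ndarray:
        V = self.vcv().V
        eps = _EPS_REL * max(self.tree_depth(), 1.0)
        return V + eps * np.eye(self.n_tips)

    # -- ancestral states --------------------------------------------------
    def _ancestral_solver(self) -> np.ndarray:
        """Matrix S with internal states = S @ tip values.

        Rows follow internal-node index order (n_tips..n_nodes-1). Solves
        the weighted squared-change system: at each internal node the
        state is the 1/branch-length-weighted average of its neighbours.
        """
        if self._anc_solver is None:
            n, m = self.n_tips, self.n_nodes
            eps = _EPS_REL * max(self.tree_depth(), 1.0)
            w = 1.0 / np.maximum(self.blen, eps)  # weight of edge above node
            n_int = m - n
            A = np.zeros((n_int, n_int))
            B = np.zeros((n_int, n))
            for i in range(n, m):
                r = i - n
                for c in self.children[i]:
                    A[r, r] += w[c]
                    if c < n:
                        B[r, c] += w[c]
                    else:
                        A[r, c - n] -= w[c]
                p = self.parent[i]
                if p >= 0:
                    A[r, r] += w[i]
                    A[r, p - n] -= w[i]
            self._anc_solver = np.linalg.solve(A, B)
        return self._anc_solver

    def ancestral_states(
        self, tip_values: Mapping[str, float | np.ndarray] | np.ndarray
    ) -> np.ndarray:
        """ML ancestral states under BM, shape (n_internal, k).

        Rows follow internal node indices ``n_tips .. n_nodes-1``; the
        root's row is ``self.root - self.n_tips``. The root estimate is
        the GLS phylogenetic mean per trait.
        """
        Y = (tip_values if isinstance(tip_values, np.ndarray)
             else self.tip_order(tip_values))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.n_tips:
            Y = Y.T
        if Y.shape[0] != self.n_tips:
            raise ValueError("tip_values shape does not match tip count")
        return self._ancestral_solver() @ Y

    def phylogenetic_mean(self, tip_values) -> np.ndarray:
        """GLS mean per trait: (1' V^-1 Y) / (1' V^-1 1)."""
        anc = self.ancestral_states(tip_values)
        return anc[self.root - self.n_tips]

    # -- rate estimation ---------------------------------------------------
    def estimate_rate_matrix(self, tip_values) -> np.ndarray:
        """Multivariate BM rate estimator on GLS residuals.

        R_hat = (Y - 1 a')' V^-1 (Y - 1 a') / (n - 1), with a the GLS
        phylogenetic mean. For k=1 on a star tree with equal depths c this
        reduces to the sample variance divided by c.
        """
        Y = (tip_values if isinstance(tip_values, np.ndarray)
             else self.tip_order(tip_values))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.n_tips:
            Y = Y.T
        n, k = Y.shape
        if n <= k:
            import warnings

            warnings.warn(
                f"rate matrix from n={n} tips for k={k} traits is rank "
                "deficient; interpret with care", stacklevel=2)
        V = self._regularized_vcv()
        c, low = cho_factor(V)
        a = self.phylogenetic_mean(Y)
        resid = Y - a
        return resid.T @ cho_solve((c, low), resid) / (n - 1)

    # -- simulation --------------------------------------------------------
    def simulate_bm(
        self,
        rate: np.ndarray | float,
        root_state: np.ndarray | float = 0.0,
        n_reps: int = 1,
        seed: int | np.random.SeedSequence = 0,
    ) -> np.ndarray:
        """Simulate BM tip values; returns array (n_reps, n_tips, k).

        Each replicate draws independent Gaussian increments per edge with
        covariance rate * branch_length, so across tips the values are
        MVN(root_state, kron(R, V)). Replicate r uses an independent
        spawned stream of the seed, so results are reproducible and
        order-independent.
        """
        R = np.atleast_2d(np.asarray(rate, dtype=float))
        k = R.shape[0]
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise ValueError("rate matrix must be positive semi-definite")
        # PSD square root (tolerates exact zeros)
        vals, vecs = np.linalg.eigh(R)
        Rhalf = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
        root_vec = np.broadcast_to(
            np.atleast_1d(np.asarray(root_state, dtype=float)), (k,)
        )
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        streams = ss.spawn(n_reps)
        m = self.n_nodes
        out = np.empty((n_reps, self.n_tips, k))
        sqb = np.sqrt(self.blen)
        for r in range(n_reps):
            rng = np.random.default_rng(streams[r])
            z = rng.standard_normal((m, k))
            inc = (z * sqb[:, None]) @ Rhalf.T
            states = np.empty((m, k))
            states[self.root] = root_vec
            for i in self.preorder:
                p = self.parent[i]
                if p >= 0:
                    states[i] = states[p] + inc[i]
            out[r] = states[: self.n_tips]
        return out


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree with branch lengths."""
    return Phylogeny.from_newick(text)


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_file(path)


def prune_and_match(tree: Phylogeny, taxa: Sequence[str]):
    """Intersect a tree with a taxon list; see Phylogeny.prune_to."""
    return tree.prune_to(taxa)


def phylo_vcv(tree: Phylogeny) -> CovarianceStructure:
    return tree.vcv()


def ancestral_states_bm(tree: Phylogeny, tip_values) -> dict[int, np.ndarray]:
    """ML/BM ancestral states keyed by internal node index."""
    anc = tree.ancestral_states(tip_values)
    return {tree.n_tips + r: anc[r] for r in range(anc.shape[0])}


def estimate_rate_matrix(tree: Phylogeny, tip_values) -> np.ndarray:
    return tree.estimate_rate_matrix(tip_values)


def simulate_bm(tree: Phylogeny, rate, root_state=0.0, n_reps=1, seed=0):
    return tree.simulate_bm(rate, root_state, n_reps, seed)
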