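"""Correlation-stage statistics: Kruskal-Wallis, Blomberg's K, PGLS.

Three complementary looks at whether suction-related character scores
track feeding mode:

* Kruskal-Wallis rank-sum tests treat species as exchangeable and ask
  whether score distributions differ between Suction and Other feeders;
* Blomberg's K measures phylogenetic signal in each score (K = 1 is the
  Brownian-motion expectation), with a tip-shuffling permutation p-value;
* PGLS refits the score ~ feeding-mode regression with residual
  covariance proportional to shared branch lengths (Brownian motion),
  against an OLS fit with independent residuals for comparison.

Species are not independent data points: a significant Kruskal-Wallis
result together with high K and a weak PGLS slope is the signature of a
trait structured by shared ancestry rather than by feeding mode per se.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .data_io import OTHER_LABEL, SUCTION_LABEL
from .phylo import Phylogeny


@dataclass
class GroupComparison:
    """Kruskal-Wallis rank-sum test result."""

    H: float
    df: int
    p: float
    tie_correction: float


@dataclass
class PhyloSignal:
    """Blomberg's K with its permutation test."""

    K: float
    p_perm: float
    n_perm: int
    seed: int


@dataclass
class RegressionFit:
    """OLS or PGLS coefficient table."""

    model: str  # "OLS" or "PGLS_BM"
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    loglik: float
    n: int


def kruskal_wallis(values, groups) -> GroupComparison:
    """Kruskal-Wallis H with mid-rank ties and chi-square p-value.

    The tie-correction divisor 1 - sum(t^3 - t)/(N^3 - N) is reported
    alongside; all-identical samples yield H = 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for i, g in enumerate(groups) if g not in groups[:i]]
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least two non-empty groups")
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - float(((counts**3 - counts).sum()) / (N**3 - N))
    if np.all(values == values[0]):
        warnings.warn(
            "all values identical; H = 0 by convention (tie correction "
            "degenerate)", stacklevel=2)
        return GroupComparison(0.0, len(samples) - 1, 1.0, tie_corr)
    H, p = stats.kruskal(*samples)
    return GroupComparison(float(H), len(samples) - 1, float(p), tie_corr)


def blomberg_k(
    tree: Phylogeny, values, n_perm: int = 1000, seed: int = 0
) -> PhyloSignal:
    """Blomberg's K with a tip-shuffling permutation p-value.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, with MSE0 the variance
    of the data about the GLS phylogenetic mean a, MSE the phylogenetic
    mean square (y-a)' V^-1 (y-a)/(n-1), and the BM expectation of the
    ratio equal to [tr(V) - n / sum(V^-1)] / (n-1). The permutation test
    shuffles values across tips and counts permutations with MSE at most
    the observed (smaller MSE = stronger signal):
    p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1).
    """
    y = (values if isinstance(values, np.ndarray)
         else tree.tip_order(values)).reshape(-1)
    n = tree.n_tips
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if y.shape[0] != n:
        raise ValueError("values do not match tip count")
    V = tree._regularized_vcv()
    c, low = cho_factor(V)
    Vinv_1 = cho_solve((c, low), np.ones(n))
    s_inv = float(Vinv_1.sum())
    expected = (np.trace(V) - n / s_inv) / (n - 1)

    def ratio(Y: np.ndarray) -> np.ndarray:
        # Y: (n, B) columns of permuted data; returns MSE0/MSE per column
        a = (Vinv_1 @ Y) / s_inv
        R = Y - a
        mse0 = (R * R).sum(axis=0) / (n - 1)
        mse = (R * cho_solve((c, low), R)).sum(axis=0) / (n - 1)
        return mse0 / mse, mse

    (obs_ratio,), (obs_mse,) = ratio(y[:, None])
    K = float(obs_ratio / expected)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    _, mse_perm = ratio(perms)
    p = (1.0 + int((mse_perm <= obs_mse).sum())) / (n_perm + 1)
    return PhyloSignal(K, float(p), n_perm, seed)


def _design(predictor, taxa: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build [1, x] design; two-level labels coded Other=0, Suction=1."""
    vals = [predictor[t] for t in taxa]
    if all(isinstance(v, str) for v in vals):
        levels = sorted(set(vals))
        if set(levels) - {SUCTION_LABEL, OTHER_LABEL} == set():
            x = np.array([1.0 if v == SUCTION_LABEL else 0.0 for v in vals])
            name = f"{SUCTION_LABEL}_vs_{OTHER_LABEL}"
        elif len(levels) == 2:
            x = np.array([1.0 if v == levels[1] else 0.0 for v in vals])
            name = f"{levels[1]}_vs_{levels[0]}"
        else:
            raise ValueError("label predictor must have exactly two levels")
    else:
        x = np.asarray(vals, dtype=float)
        name = "slope"
    X = np.column_stack([np.ones(len(taxa)), x])
    return X, ["intercept", name]


def pgls_fit(tree: Phylogeny | None, response, predictor) -> RegressionFit:
    """GLS regression of response on predictor.

    With a tree, residual covariance is the Brownian-motion V from shared
    branch lengths (PGLS); with ``tree=None`` the covariance is the
    identity and the fit is ordinary least squares. Inference is by
    t-tests on coefficients with n - p degrees of freedom.
    """
    if tree is not None:
        taxa = list(tree.tip_labels)
        y = (response if isinstance(response, np.ndarray)
             else tree.tip_order(response)).reshape(-1)
        V = tree._regularized_vcv()
    else:
        if isinstance(response, np.ndarray):
            raise ValueError("without a tree, pass response as a mapping")
        taxa = list(response.keys())
        y = np.array([float(response[t]) for t in taxa])
        V = None
    X, terms = _design(predictor, taxa)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    if V is None:
        res = sm.OLS(y, X).fit()
        model = "OLS"
    else:
        res = sm.GLS(y, X, sigma=V).fit()
        model = "PGLS_BM"
    return RegressionFit(
        model=model,
        terms=terms,
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        t=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        sigma2=float(res.scale),
        loglik=float(res.llf),
        n=len(y),
    )


def correlate_characters(
    matrix, labels, tree: Phylogeny | None, ssi_table=None,
    n_perm: int = 1000, seed: int = 0,
) -> dict[str, dict]:
    """Run the full correlation battery per character (and SSI columns).

    For every character: Kruskal-Wallis between feeding modes, Blomberg's
    K (if a tree is given), and paired OLS/PGLS fits of score ~ mode.
    ``ssi_table`` adds rows for the composite indices (char_mean and
    adjusted_ssi).
    """
    out: dict[str, dict] = {}
    series = {c: dict(zip(matrix.taxa, matrix.column(c)))
              for c in matrix.character_names}
    if ssi_table is not None:
        series["SSI"] = ssi_table["char_mean"].to_dict()
        series["adjusted_SSI"] = ssi_table["adjusted_ssi"].to_dict()

    pruned = None
    if tree is not None:
        pruned, _ = tree.prune_to(matrix.taxa)

    for name, vals in series.items():
        taxa = [t for t in vals if np.isfinite(vals[t])]
        v = np.array([vals[t] for t in taxa])
        g = np.array([labels[t] for t in taxa], dtype=object)
        entry: dict = {"kruskal_wallis": kruskal_wallis(v, g)}
        entry["ols"] = pgls_fit(None, {t: vals[t] for t in taxa},
                                {t: labels[t] for t in taxa})
        if pruned is not None:
            sub = pruned
            if set(map(str, taxa)) != set(sub.tip_labels):
                sub, _ = pruned.prune_to(taxa)
            entry["blomberg_k"] = blomberg_k(
                sub, {t: vals[t] for t in sub.tip_labels}, n_perm, seed)
            entry["pgls"] = pgls_fit(
                sub, {t: vals[t] for t in sub.tip_labels},
                {t: labels[t] for t in sub.tip_labels})
        out[name] = entry
    return out
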