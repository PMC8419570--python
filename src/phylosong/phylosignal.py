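"""Blomberg's K and Pagel's lambda over single trees and tree ensembles.

Both statistics quantify phylogenetic signal in a continuous tip trait
against a Brownian-motion (BM) expectation on the tree, parameterized by the
phylogenetic variance-covariance matrix V whose entries are shared
root-to-MRCA path lengths.

* **Blomberg's K** compares the observed ratio of tip variance to
  phylogenetically corrected (GLS) variance with the ratio expected under BM
  on that tree; K = 1 matches the BM expectation, K > 1 indicates more
  resemblance among relatives than BM predicts, K near 0 indicates none.
  Significance comes from permuting trait values across tips: signal makes
  the phylogenetically corrected mean squared error smaller than for
  permuted data.

* **Pagel's lambda** multiplies the off-diagonal entries of V by a factor
  lambda in [0, lambda_max] and maximizes the profile BM likelihood;
  lambda = 0 means the tree adds nothing (star phylogeny), lambda = 1 is
  BM-consistent covariance. Significance is a likelihood-ratio test of
  lambda-hat against lambda = 0 on a chi-squared(1) reference.

For a bootstrap ensemble, both statistics are computed per feature per tree
and summarized as mean +/- sd plus the proportion of trees with p < 0.05.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .exceptions import (
    DegenerateTraitError,
    InvalidTreeError,
    LabelAlignmentError,
    UnidentifiableError,
)

logger = logging.getLogger(__name__)

_RIDGE_FACTOR = 1e-8
_LAMBDA_XATOL = 1e-6
_GRID_POINTS = 25


@dataclass(frozen=True)
class PhyloVCV:
    """Phylogenetic variance-covariance matrix of a rooted tree.

    V_ij is the shared path length from the root to the MRCA of tips i and j;
    the diagonal holds root-to-tip depths.
    """

    labels: tuple
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)


def phylo_vcv(tree) -> PhyloVCV:
    """Build the phylogenetic VCV of a rooted tree with branch lengths."""
    root = tree.seed_node
    if root is None or len(root.child_nodes()) == 0:
        raise InvalidTreeError("tree has no rooted structure")
    depth = {}
    for node in tree.preorder_node_iter():
        if node is root:
            depth[node] = node.edge.length or 0.0
            continue
        if node.edge.length is None:
            raise InvalidTreeError("missing branch length in tree")
        depth[node] = depth[node.parent_node] + node.edge.length
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = tuple(leaf.taxon.label for leaf in leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for leaf, i in index.items():
        V[i, i] = depth[leaf]
    # postorder: at each internal node, cross-subtree tip pairs share exactly
    # this node as MRCA
    tips_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [index[node]]
            continue
        children = [tips_below[c] for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.array(children[a])
                ib = np.array(children[b])
                V[np.ix_(ia, ib)] = d
                V[np.ix_(ib, ia)] = d
        tips_below[node] = [i for sub in children for i in sub]
    return PhyloVCV(labels, V)


def _align_trait(labels, x) -> np.ndarray:
    """Order a trait mapping/Series to the given tip labels."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, dict):
        x = {str(k): v for k, v in x.items()}
        missing = [l for l in labels if l not in x]
        extra = sorted(set(x) - set(labels))
        if missing or extra:
            raise LabelAlignmentError(
                f"trait labels do not match tips (missing: {missing}, "
                f"extra: {extra})",
                missing=missing,
                extra=extra,
            )
        return np.array([float(x[l]) for l in labels])
    x = np.asarray(x, dtype=float)
    if x.shape != (len(labels),):
        raise LabelAlignmentError(
            f"trait vector length {x.shape} does not match {len(labels)} tips"
        )
    return x


def _as_vcv(tree_or_vcv) -> PhyloVCV:
    if isinstance(tree_or_vcv, PhyloVCV):
        return tree_or_vcv
    return phylo_vcv(tree_or_vcv)


def _safe_cho_factor(V):
    try:
        return scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError:
        ridge = _RIDGE_FACTOR * np.mean(np.diag(V))
        logger.warning("VCV numerically singular; adding ridge %.3g", ridge)
        return scipy.linalg.cho_factor(V + ridge * np.eye(len(V)), lower=True)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def _k_ingredients(vcv: PhyloVCV):
    n = vcv.n
    cho = _safe_cho_factor(vcv.values)
    ones = np.ones(n)
    Vinv_ones = scipy.linalg.cho_solve(cho, ones)
    denom_expected = (np.trace(vcv.values) - n / (ones @ Vinv_ones)) / (n - 1)
    return cho, Vinv_ones, ones @ Vinv_ones, denom_expected


def blomberg_k(tree_or_vcv, x) -> float:
    """Blomberg's K of a tip trait on a rooted tree.

    With a-hat the GLS phylogenetic mean, K is the ratio of
    (observed MSE0/MSE) to its BM expectation on the tree, where
    MSE0 = (x-a)'(x-a)/(n-1) and MSE = (x-a)'V^-1(x-a)/(n-1).
    """
    vcv = _as_vcv(tree_or_vcv)
    x = _align_trait(vcv.labels, x)
    if vcv.n < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    cho, Vinv_ones, s_ones, denom_expected = _k_ingredients(vcv)
    ahat = (Vinv_ones @ x) / s_ones
    resid = x - ahat
    mse0 = resid @ resid / (vcv.n - 1)
    mse = resid @ scipy.linalg.cho_solve(cho, resid) / (vcv.n - 1)
    return float((mse0 / mse) / denom_expected)


def blomberg_k_test(tree_or_vcv, x, n_perm: int = 1000, seed: int = 0):
    """Blomberg's K with a tip-permutation p-value.

    Trait values are permuted across tips ``n_perm`` times; the p-value is
    the proportion of permutations (observed arrangement included, so the
    denominator is n_perm + 1) whose phylogenetically corrected MSE is <=
    the observed MSE. Returns (K, p).
    """
    vcv = _as_vcv(tree_or_vcv)
    xv = _align_trait(vcv.labels, x)
    if vcv.n < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    if np.ptp(xv) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    cho, Vinv_ones, s_ones, denom_expected = _k_ingredients(vcv)

    def corrected_mse(X):
        # X: (n, m) columns of trait arrangements
        ahat = (Vinv_ones @ X) / s_ones
        resid = X - ahat
        return np.einsum("im,im->m", resid, scipy.linalg.cho_solve(cho, resid)) / (
            vcv.n - 1
        )

    obs_mse = corrected_mse(xv[:, None])[0]
    resid = xv - (Vinv_ones @ xv) / s_ones
    mse0 = resid @ resid / (vcv.n - 1)
    k_obs = float((mse0 / obs_mse) / denom_expected)

    rng = np.random.default_rng(seed)
    perms = np.empty((vcv.n, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(xv)
    perm_mse = corrected_mse(perms)
    p = (1 + int(np.sum(perm_mse <= obs_mse))) / (n_perm + 1)
    return k_obs, float(p)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaResult:
    lambda_hat: float
    loglik_hat: float
    loglik0: float
    p_lambda: float


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = V * lam
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _bm_profile_loglik(V: np.ndarray, x: np.ndarray) -> float:
    """Profile log-likelihood of BM with GLS mean and sigma2 profiled out.

    Returns -inf when V is not positive definite (outside the feasible
    lambda region on non-ultrametric trees).
    """
    n = len(x)
    try:
        cho = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError:
        return -np.inf
    ones = np.ones(n)
    Vinv_ones = scipy.linalg.cho_solve(cho, ones)
    ahat = (Vinv_ones @ x) / (ones @ Vinv_ones)
    resid = x - ahat
    q = resid @ scipy.linalg.cho_solve(cho, resid)
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(tree_or_vcv, x) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda with a LRT against lambda = 0.

    lambda scales the off-diagonal of V; the search interval is
    [0, lambda_max] with lambda_max = max(diag V)/max(offdiag V) (the largest
    value keeping V(lambda) a valid covariance on an ultrametric tree). The
    p-value uses 2*(ll(lambda-hat) - ll(0)) against chi-squared(1).
    """
    vcv = _as_vcv(tree_or_vcv)
    x = _align_trait(vcv.labels, x)
    if vcv.n < 3:
        raise ValueError("Pagel's lambda needs at least 3 tips")
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    V = vcv.values
    off = V[~np.eye(vcv.n, dtype=bool)]
    if np.max(off) <= 0:
        raise UnidentifiableError(
            "star tree: all off-diagonal covariances are zero, lambda is "
            "unidentifiable"
        )
    lam_max = float(np.max(np.diag(V)) / np.max(off))

    def negll(lam):
        ll = _bm_profile_loglik(_lambda_vcv(V, lam), x)
        # large finite penalty keeps the bounded optimizer well-behaved
        return -ll if np.isfinite(ll) else 1e300

    grid = np.linspace(0.0, lam_max, _GRID_POINTS)
    grid_vals = np.array([negll(g) for g in grid])
    best = int(np.argmin(grid_vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, _GRID_POINTS - 1)]
    if lo == hi:
        lam_hat = float(grid[best])
    else:
        res = scipy.optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": _LAMBDA_XATOL},
        )
        lam_hat = float(res.x)
        if negll(lam_hat) > grid_vals[best]:
            lam_hat = float(grid[best])
    ll_hat = _bm_profile_loglik(_lambda_vcv(V, lam_hat), x)
    ll0 = _bm_profile_loglik(_lambda_vcv(V, 0.0), x)
    if ll_hat < ll0:   # 0 is in the interval; never report a worse optimum
        lam_hat, ll_hat = 0.0, ll0
    lrt = 2.0 * (ll_hat - ll0)
    p = float(scipy.stats.chi2.sf(max(lrt, 0.0), df=1))
    return LambdaResult(lam_hat, ll_hat, ll0, p)


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalSummary:
    """Per-(feature, tree) statistics and their across-tree summary.

    ``per_tree``: long DataFrame (feature, tree_index, K, p_K, lambda, p_lambda).
    ``summary``: per feature, mean/sd of K and lambda across trees plus the
    proportion of trees with p < 0.05 for each statistic.
    """

    per_tree: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)


def _derive_seed(master: int, feature: str, tree_index: int) -> int:
    key = f"{master}|{feature}|{tree_index}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (
        2**31
    )


def ensemble_signal(
    ensemble,
    table,
    n_perm: int = 1000,
    seed: int = 0,
    features=None,
    alpha: float = 0.05,
) -> SignalSummary:
    """K and lambda per feature per tree, summarized across the ensemble.

    ``ensemble`` is a sequence of rooted trees over the same tip set;
    ``table`` a SpeciesFeatureTable (or DataFrame indexed by species). The
    per-(feature, tree) permutation seed is derived by stable hashing, so the
    result is independent of execution order.
    """
    df = getattr(table, "data", table)
    if features is None:
        features = list(df.columns)
    trees = list(ensemble)
    if not trees:
        raise ValueError("empty tree ensemble")
    vcvs = [phylo_vcv(t) for t in trees]
    species = set(df.index.astype(str))
    for vcv in vcvs:
        tips = set(vcv.labels)
        if tips != species:
            raise LabelAlignmentError(
                f"species table and tree tips differ "
                f"(only in table: {sorted(species - tips)}, "
                f"only in tree: {sorted(tips - species)})",
                missing=sorted(species - tips),
                extra=sorted(tips - species),
            )
    rows = []
    for feature in features:
        x = df[feature]
        for ti, vcv in enumerate(vcvs):
            k, p_k = blomberg_k_test(
                vcv, x, n_perm=n_perm, seed=_derive_seed(seed, feature, ti)
            )
            lam = pagel_lambda(vcv, x)
            rows.append(
                {
                    "feature": feature,
                    "tree_index": ti,
                    "K": k,
                    "p_K": p_k,
                    "lambda": lam.lambda_hat,
                    "p_lambda": lam.p_lambda,
                }
            )
    per_tree = pd.DataFrame(rows)
    grouped = per_tree.groupby("feature", sort=False)
    summary = pd.DataFrame(
        {
            "mean_K": grouped["K"].mean(),
            "sd_K": grouped["K"].std(ddof=1).fillna(0.0),
            "prop_signif_K": grouped["p_K"].apply(lambda p: float(np.mean(p < alpha))),
            "mean_lambda": grouped["lambda"].mean(),
            "sd_lambda": grouped["lambda"].std(ddof=1).fillna(0.0),
            "prop_signif_lambda": grouped["p_lambda"].apply(
                lambda p: float(np.mean(p < alpha))
            ),
        }
    )
    return SignalSummary(per_tree, summary)
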