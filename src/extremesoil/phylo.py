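"""Phylogenetic signal of disturbance responses (Pagel's lambda via PGLS).

Given a tree over the modelled taxa and a per-taxon trait — here the
estimated S1 displacement ("impact", resistance) or the post-disturbance
slope ("resilience") from the per-taxon mixed models — phylogenetic signal is
quantified by Pagel's lambda: the off-diagonal of the Brownian-motion tip
covariance matrix is scaled by lambda in [0, 1] and the scaling that
maximizes the Gaussian likelihood of an intercept-only generalized
least-squares model is reported, with a profile-likelihood confidence
interval.  lambda = 0 means tip values are independent of the tree; lambda =
1 means pure Brownian covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

__all__ = ["tree_vcv", "PagelLambdaGLS", "PagelLambdaResults", "signal_for_traits"]


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance of a tree: C[i, j] is the root-to-MRCA
    path length of tips i and j; the diagonal is each tip's root-to-tip depth.

    Branch lengths must be non-negative; a missing root edge counts as 0.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    c = np.zeros((n, n))

    def depth_of(node) -> float:
        d = 0.0
        while node is not None:
            if node.edge.length is not None:
                if node.edge.length < 0:
                    raise ValueError("negative branch length")
                d += node.edge.length
            node = node.parent_node
        return d

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            c[i, i] = depth_of(node)
            continue
        d = depth_of(node)
        children = node.child_nodes()
        tip_sets = [
            [index[lf.taxon.label] for lf in ch.leaf_iter()] for ch in children
        ]
        for a in range(len(tip_sets)):
            for b in range(a + 1, len(tip_sets)):
                for i in tip_sets[a]:
                    for j in tip_sets[b]:
                        c[i, j] = c[j, i] = d
    return tips, c


def _lambda_cov(c: np.ndarray, lam: float) -> np.ndarray:
    v = lam * c
    np.fill_diagonal(v, np.diagonal(c))
    return v


def _gls_loglik(y: np.ndarray, v: np.ndarray) -> float:
    """Maximized Gaussian log-likelihood of an intercept-only GLS model with
    covariance sigma^2 * v (sigma^2 profiled out by its ML estimate)."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0 or not np.isfinite(logdet):
        return -np.inf
    try:
        vi = np.linalg.solve(v, np.column_stack([np.ones(n), y]))
    except np.linalg.LinAlgError:
        return -np.inf
    vi1, viy = vi[:, 0], vi[:, 1]
    denom = vi1 @ np.ones(n)
    if not np.isfinite(denom) or denom <= 0:
        return -np.inf
    beta = (vi1 @ y) / denom
    r = y - beta
    sigma2 = float(r @ (viy - beta * vi1)) / n
    if not np.isfinite(sigma2) or sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


@dataclass
class PagelLambdaResults:
    trait: str
    lambda_: float
    loglik: float
    ci: tuple[float, float]
    n: int
    profile: pd.DataFrame

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"Pagel's lambda for {self.trait!r}: "
            f"{self.lambda_:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
            f"logL = {self.loglik:.2f}, n = {self.n} tips"
        )


class PagelLambdaGLS:
    """Intercept-only phylogenetic GLS estimating Pagel's lambda.

    Parameters
    ----------
    tree : dendropy.Tree
        Tree whose tip labels cover the trait index; ultrametricity is not
        required.
    trait : pd.Series
        Per-taxon values indexed by tip label.  Tips without a trait value
        are dropped with a warning; at least 10 informative tips are needed.
    """

    GRID = 21  # lambda pre-scan before bounded refinement (profile can be multimodal)

    def __init__(self, tree: dendropy.Tree, trait: pd.Series, name: str = "trait"):
        tips, c = tree_vcv(tree)
        trait = trait.dropna()
        keep = [t for t in tips if t in trait.index]
        missing_tips = len(tips) - len(keep)
        if missing_tips:
            warnings.warn(f"{missing_tips} tips without trait values dropped", stacklevel=2)
        extra = set(trait.index) - set(tips)
        if extra:
            raise ValueError(f"trait ids missing from tree: {sorted(extra)[:5]} ...")
        if len(keep) < 10:
            raise ValueError("need at least 10 tips with non-missing trait")
        idx = [tips.index(t) for t in keep]
        self.name = name
        self.tips = keep
        self.c = c[np.ix_(idx, idx)]
        self.y = trait.loc[keep].to_numpy(dtype=float)
        if np.var(self.y) == 0:
            raise ValueError("trait has zero variance")

    def loglik(self, lam: float) -> float:
        return _gls_loglik(self.y, _lambda_cov(self.c, lam))

    def fit(self, ci_level: float = 0.95) -> PagelLambdaResults:
        grid = np.linspace(0.0, 1.0, self.GRID)
        ll = np.array([self.loglik(l) for l in grid])
        k = int(np.argmax(ll))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda l: -self.loglik(l), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat, ll_hat = float(res.x), -float(res.fun)
            if ll[k] > ll_hat:  # flat or boundary profile
                lam_hat, ll_hat = float(grid[k]), float(ll[k])
        else:  # pragma: no cover - single-point grid
            lam_hat, ll_hat = float(grid[k]), float(ll[k])
        ci = self._profile_ci(lam_hat, ll_hat, ci_level)
        return PagelLambdaResults(
            trait=self.name,
            lambda_=lam_hat,
            loglik=ll_hat,
            ci=ci,
            n=len(self.y),
            profile=pd.DataFrame({"lambda": grid, "loglik": ll}),
        )

    def _profile_ci(
        self, lam_hat: float, ll_hat: float, level: float
    ) -> tuple[float, float]:
        """Profile-likelihood interval {lambda : 2(L_hat - L) <= chi2_1}."""
        cut = ll_hat - 0.5 * chi2.ppf(level, df=1)

        def g(l: float) -> float:
            return self.loglik(l) - cut

        lo = 0.0
        if g(0.0) < 0:
            lo = brentq(g, 0.0, lam_hat, xtol=1e-6) if lam_hat > 0 else 0.0
        hi = 1.0
        if g(1.0) < 0:
            hi = brentq(g, lam_hat, 1.0, xtol=1e-6) if lam_hat < 1 else 1.0
        return (min(lo, lam_hat), max(hi, lam_hat))


def signal_for_traits(
    tree: dendropy.Tree, fits: pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Pagel's lambda per treatment for both response traits.

    ``fits`` is the per-taxon model table (columns taxon, treatment, beta,
    slope, converged); non-converged taxa are excluded listwise.  Returns one
    row per (treatment, trait_kind) with lambda, CI, log-likelihood and tip
    count.
    """
    rows = []
    ok = fits[fits["converged"]] if "converged" in fits.columns else fits
    for treatment, sub in ok.groupby("treatment"):
        for kind, col in (("impact", "beta"), ("slope", "slope")):
            trait = pd.Series(sub[col].to_numpy(), index=sub["taxon"])
            res = PagelLambdaGLS(tree, trait, name=f"{treatment}:{kind}").fit(ci_level)
            rows.append(
                {
                    "treatment": treatment,
                    "trait_kind": kind,
                    "lambda": res.lambda_,
                    "ci_lo": res.ci[0],
                    "ci_hi": res.ci[1],
                    "loglik": res.loglik,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
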