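"""Phylogenetically controlled correlation and comparison statistics.

Cross-species trait correlations cannot treat species as independent
observations; shared ancestry induces covariance. Under Brownian-motion
trait evolution the expected covariance between two tips is the length of
their shared root path, and Pagel's lambda scales the off-diagonal
(shared) part of that covariance: lambda = 0 recovers ordinary least
squares, lambda = 1 the full Brownian structure. This module provides

* PGLS regression with lambda estimated by profile maximum likelihood,
* a tip-input-order robustness report (median statistics over permuted
  input orders; a well-conditioned fit is order-invariant),
* Felsenstein's phylogenetically independent contrasts and a
  sign-agreement test between two contrast sets (an exact binomial test
  of whether two traits tend to change in the same direction on the tree,
  regardless of magnitude),
* Brownian maximum-likelihood ancestral state estimation,
* ANCOVA of a gene-level statistic between genomic compartments with exon
  and intron length covariates, and
* bootstrap percentile confidence intervals for medians.

Trees are read as newick via dendropy; polytomies (e.g. an unresolved
species trichotomy) are handled natively by the covariance matrix in PGLS
and resolved to zero-length branches for contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class TraitTree:
    """A rooted phylogeny with branch lengths and per-tip trait values."""

    tree: dendropy.Tree
    traits: pd.DataFrame  # indexed by tip label

    @classmethod
    def from_files(cls, newick_path, traits_path) -> "TraitTree":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
        traits = pd.read_csv(traits_path, sep="\t", index_col=0)
        return cls(tree=tree, traits=traits)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass
class PGLSResult:
    slope: float
    intercept: float
    t: float
    df: int
    r: float
    p: float
    lam: float
    log_likelihood: float = np.nan
    n: int = 0


def _edge_length(node) -> float:
    ln = node.edge.length
    if ln is None:
        return 0.0
    if ln < 0:
        raise ValueError(f"negative branch length at node {node}")
    return float(ln)


def _tree_structure(tree: dendropy.Tree):
    """Tip labels, tip root-depths, and shared-path depth matrix."""
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent is not None else 0.0) + (
            _edge_length(node) if parent is not None else 0.0
        )
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    shared = np.zeros((n, n))
    leafset = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = [index[node]]
            continue
        kids = [leafset[ch] for ch in node.child_nodes()]
        for a, b in itertools.combinations(range(len(kids)), 2):
            for i in kids[a]:
                for j in kids[b]:
                    shared[i, j] = shared[j, i] = depth[node]
        leafset[node] = [i for kid in kids for i in kid]
    tip_depth = np.array([depth[lf] for lf in leaves])
    return labels, tip_depth, shared, depth, leafset


def phylo_covariance(
    tree: dendropy.Tree,
    lam: float = 1.0,
    tip_order: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pagel-lambda tip covariance: diagonal root-to-tip distances,
    off-diagonal lambda times shared path length."""
    labels, tip_depth, shared, _, _ = _tree_structure(tree)
    C = lam * shared + np.diag(tip_depth)
    if tip_order is not None:
        perm = [labels.index(l) for l in tip_order]
        C = C[np.ix_(perm, perm)]
        labels = list(tip_order)
    return labels, C


def _gls_fit(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Whitened OLS under covariance C: returns beta, resid' C^-1 resid,
    (X' C^-1 X)^-1, and log|C|."""
    L = np.linalg.cholesky(C)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, xtx_inv, logdet


def pgls(
    tree: dendropy.Tree,
    x,
    y,
    lam: float | None = None,
    lambda_bounds: tuple[float, float] = (0.0, 1.0),
    tip_order: list[str] | None = None,
) -> PGLSResult:
    """Phylogenetic GLS regression of y on x with Pagel's lambda.

    ``x`` and ``y`` are mappings/Series keyed by tip label. lambda is
    estimated by profile maximum likelihood on [lambda_bounds] unless
    given; the slope t-test uses n - 2 degrees of freedom and
    r = sign(slope) * sqrt(t^2 / (t^2 + df)).
    """
    x, y = pd.Series(x, dtype=float), pd.Series(y, dtype=float)
    labels, tip_depth, shared, _, _ = _tree_structure(tree)
    order = tip_order if tip_order is not None else labels
    common = [l for l in order if l in x.index and l in y.index]
    if len(common) < 4:
        raise ValueError("pgls requires at least 4 tips with both traits")
    perm = [labels.index(l) for l in common]
    D = tip_depth[perm]
    S = shared[np.ix_(perm, perm)]
    xv = x.loc[common].to_numpy()
    yv = y.loc[common].to_numpy()
    n = len(common)
    X = np.column_stack([np.ones(n), xv])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design: predictor is constant")

    def cov(l: float) -> np.ndarray:
        return l * S + np.diag(D)

    def neg_ll(l: float) -> float:
        try:
            _, rss, _, logdet = _gls_fit(cov(l), X, yv)
        except np.linalg.LinAlgError:
            return np.inf
        sigma2 = rss / n
        if sigma2 <= 0:
            return np.inf
        return 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)

    if lam is None:
        res = optimize.minimize_scalar(
            neg_ll, bounds=lambda_bounds, method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [res.x, lambda_bounds[0], lambda_bounds[1]]
        lam = min(candidates, key=neg_ll)
    beta, rss, xtx_inv, _ = _gls_fit(cov(lam), X, yv)
    df = n - 2
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.inf * np.sign(beta[1])
    p = float(2.0 * stats.t.sf(abs(t), df))
    r = float(np.sign(beta[1]) * np.sqrt(t * t / (t * t + df))) if np.isfinite(t) else np.sign(beta[1])
    return PGLSResult(
        slope=float(beta[1]), intercept=float(beta[0]), t=t, df=df,
        r=r, p=p, lam=float(lam), log_likelihood=-neg_ll(lam), n=n,
    )


def order_robustness(
    tree: dendropy.Tree,
    x,
    y,
    n_orders: int | None = None,
    seed: int | None = None,
    **pgls_kwargs,
) -> dict:
    """PGLS repeated under permuted tip-input orders.

    Reports median t, r, p and lambda together with the max-min spread of
    t across orders — a robustness report; a well-conditioned fit is
    order-invariant to numerical tolerance. Enumerates all n! orders for
    small trees unless ``n_orders`` caps the number of sampled orders.
    """
    x, y = pd.Series(x, dtype=float), pd.Series(y, dtype=float)
    labels, *_ = _tree_structure(tree)
    tips = [l for l in labels if l in x.index and l in y.index]
    if n_orders == 1:
        orders = [tuple(tips)]
    elif n_orders is None and len(tips) <= 7:
        orders = list(itertools.permutations(tips))
    else:
        rng = np.random.default_rng(seed)
        k = n_orders or 720
        orders = [tuple(rng.permutation(tips)) for _ in range(k)]
    rows = []
    for order in orders:
        res = pgls(tree, x, y, tip_order=list(order), **pgls_kwargs)
        rows.append({"t": res.t, "r": res.r, "p": res.p, "lambda": res.lam,
                     "slope": res.slope})
    frame = pd.DataFrame(rows)
    return {
        "n_orders": len(orders),
        "median_t": float(frame["t"].median()),
        "median_r": float(frame["r"].median()),
        "median_p": float(frame["p"].median()),
        "median_lambda": float(frame["lambda"].median()),
        "median_slope": float(frame["slope"].median()),
        "spread_t": float(frame["t"].max() - frame["t"].min()),
        "results": frame,
    }


def independent_contrasts(tree: dendropy.Tree, trait) -> pd.DataFrame:
    """Felsenstein's phylogenetically independent contrasts.

    Polytomies are resolved into zero-length bifurcations (logged). For n
    tips with complete trait data the result has n - 1 rows with columns
    ``node``, ``contrast`` (standardized difference) and ``expected_sd``.
    A node whose two daughter branches sum to zero length is an error.
    """
    trait = pd.Series(trait, dtype=float)
    work = tree.clone(depth=1)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_internal_node_iter()):
        logger.info("independent_contrasts: resolving polytomies with zero-length branches")
        work.resolve_polytomies(limit=2, update_bipartitions=False)
    values: dict = {}
    lengths: dict = {}
    rows = []
    counter = iter(range(10 ** 9))
    for node in work.postorder_node_iter():
        if node.is_leaf():
            values[node] = float(trait[node.taxon.label])
            lengths[node] = _edge_length(node)
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("contrasts require a bifurcating tree after resolution")
        (c1, c2) = kids
        v1, v2 = lengths[c1], lengths[c2]
        vsum = v1 + v2
        name = node.label or f"node{next(counter)}"
        if vsum <= 0:
            raise ValueError(f"zero summed branch length at node {name}")
        rows.append({
            "node": name,
            "contrast": (values[c1] - values[c2]) / np.sqrt(vsum),
            "expected_sd": np.sqrt(vsum),
        })
        values[node] = (values[c1] / v1 + values[c2] / v2) / (1.0 / v1 + 1.0 / v2) \
            if v1 > 0 and v2 > 0 else (values[c1] if v2 > 0 else values[c2])
        lengths[node] = _edge_length(node) + v1 * v2 / vsum
    return pd.DataFrame(rows)


def contrast_sign_test(contrasts_x, contrasts_y) -> tuple[int, int, float]:
    """Sign-agreement test between two aligned contrast sets.

    Each node is oriented so its x-contrast is positive (zero x-contrasts
    dropped, logged); the count of nodes whose y-contrast is then also
    positive is tested against Binomial(n, 1/2), two-sided exact.
    """
    cx = np.asarray(contrasts_x, dtype=float)
    cy = np.asarray(contrasts_y, dtype=float)
    if cx.shape != cy.shape:
        raise ValueError("contrast vectors must align node-by-node")
    keep = cx != 0
    if (~keep).any():
        logger.info("contrast_sign_test: dropped %d zero x-contrasts", int((~keep).sum()))
    cx, cy = cx[keep], cy[keep]
    oriented = cy * np.sign(cx)
    n_agree = int((oriented > 0).sum())
    n_total = int(len(oriented))
    p = float(stats.binomtest(n_agree, n_total, 0.5).pvalue) if n_total else np.nan
    return n_agree, n_total, p


def ancestral_states(tree: dendropy.Tree, trait) -> pd.Series:
    """Brownian-motion ML estimates of trait values at internal nodes.

    Computed by generalized least squares: the root state is the GLS mean
    of the tips under the Brownian covariance, and each internal node's
    estimate conditions on the tips through its node-tip shared-path
    covariances. Equal daughter branch lengths at a two-tip tree give the
    tip average at the root.
    """
    trait = pd.Series(trait, dtype=float)
    labels, tip_depth, shared, depth, leafset = _tree_structure(tree)
    y = trait.loc[labels].to_numpy()
    n = len(labels)
    C = shared + np.diag(tip_depth)
    ones = np.ones(n)
    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, ones)
    mu = float(ones @ Cinv_y) / float(ones @ Cinv_1)
    resid_w = np.linalg.solve(C, y - mu * ones)
    out = {}
    counter = iter(range(10 ** 9))
    internal = [nd for nd in tree.preorder_internal_node_iter()]
    for node in internal:
        below = set(leafset[node])
        # shared path length between this node and each tip
        c = np.empty(n)
        for i in range(n):
            if i in below:
                c[i] = depth[node]
            else:
                anc = node.parent_node
                while anc is not None and i not in set(leafset[anc]):
                    anc = anc.parent_node
                c[i] = depth[anc] if anc is not None else 0.0
        name = node.label or f"node{next(counter)}"
        out[name] = mu + float(c @ resid_w)
    return pd.Series(out)


@dataclass
class AncovaResult:
    effect: float  # group coefficient (second level minus first)
    t: float
    p: float
    group_levels: tuple
    n: int
    f_p: float = np.nan  # overall group F-test p (useful for >2 groups)


def compartment_ancova(
    table: pd.DataFrame,
    value: str = "encp",
    group: str = "group",
    covariates: tuple[str, ...] = ("exon_length", "intron_length"),
) -> AncovaResult:
    """ANCOVA of a per-gene statistic between genomic compartments.

    Fits ``value ~ group + covariates`` by OLS and reports the group
    effect (t-test of the group coefficient for two groups; overall
    F-test p also returned). Raises for a single group.
    """
    df = table.dropna(subset=[value, group, *covariates]).copy()
    levels = tuple(sorted(df[group].astype(str).unique()))
    if len(levels) < 2:
        raise ValueError("compartment_ancova requires at least two groups")
    df[group] = pd.Categorical(df[group].astype(str), categories=levels)
    formula = f"{value} ~ C({group}) + " + " + ".join(covariates)
    fit = smf.ols(formula, data=df).fit()
    coef_name = f"C({group})[T.{levels[1]}]"
    effect = float(fit.params[coef_name])
    t = float(fit.tvalues[coef_name])
    p = float(fit.pvalues[coef_name])
    anova = sm.stats.anova_lm(fit, typ=2)
    f_p = float(anova.loc[f"C({group})", "PR(>F)"])
    return AncovaResult(effect=effect, t=t, p=p, group_levels=levels,
                        n=len(df), f_p=f_p)


def bootstrap_median_ci(
    values,
    reps: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap confidence interval for the median."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(reps, len(v)))
    meds = np.median(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(np.median(v)), float(lo), float(hi)
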