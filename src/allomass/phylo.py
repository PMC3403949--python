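"""Phylogenetic comparative methods: independent contrasts and PGLS.

Species data are not independent observations: close relatives resemble
each other through shared ancestry.  Felsenstein's independent contrasts
remove that structure by differencing trait values at the nodes of a
rooted, fully bifurcating tree and standardizing each difference by its
expected standard deviation under Brownian motion (the square root of the
corrected branch-length sum).  Phylogenetic generalized least squares
(PGLS) instead fits a regression whose residual covariance is
proportional to shared path length from the root (the Brownian-motion
covariance).  Branch lengths here are in millions of years; following the
standardization diagnostic, trees may be used with their raw lengths or
with natural-log transformed lengths.

Trees are :class:`dendropy.Tree` objects throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .sma import SMAFit, slope_ci_from_summary

__all__ = [
    "ContrastSet",
    "StandardizationReport",
    "GLSFit",
    "read_newick",
    "transform_branch_lengths",
    "compute_contrasts",
    "check_standardization",
    "fit_sma_origin",
    "fit_ols_origin",
    "brownian_covariance",
    "fit_pgls",
]


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Raises on malformed input, duplicate tip names, or missing/non-positive
    branch lengths.  Polytomies load but trigger a warning (contrast
    computation will refuse them).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate tip names in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or not math.isfinite(edge.length) or edge.length <= 0:
            raise ValueError(
                f"edge above {_node_label(edge.head_node)} has invalid length "
                f"{edge.length!r}; all branch lengths must be finite and > 0"
            )
    if any(
        len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()
    ):
        warnings.warn("tree contains polytomies; contrasts will refuse it", stacklevel=2)
    return tree


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node (id {id(node) & 0xFFFF})"


def transform_branch_lengths(tree: dendropy.Tree, mode: str) -> dendropy.Tree:
    """Return a copy of the tree with edge-wise transformed branch lengths.

    Modes: ``none`` (identity), ``natural_log`` (requires every length > 1,
    since ln of a length <= 1 gives a non-positive contrast variance), and
    ``natural_log_plus_1`` (ln(length + 1), valid for any positive length).
    """
    if mode not in ("none", "natural_log", "natural_log_plus_1"):
        raise ValueError(f"unknown transform mode {mode!r}")
    out = tree.clone(depth=1)
    if mode == "none":
        return out
    for edge in out.preorder_edge_iter():
        if edge.head_node is out.seed_node or edge.length is None:
            continue
        if mode == "natural_log":
            if edge.length <= 1:
                raise ValueError(
                    f"natural_log transform undefined for edge above "
                    f"{_node_label(edge.head_node)} with length {edge.length}"
                )
            edge.length = math.log(edge.length)
        else:
            edge.length = math.log1p(edge.length)
    return out


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait."""

    contrasts: np.ndarray
    expected_sd: np.ndarray
    node_ids: list[str]
    transform_used: str = "none"

    def __len__(self) -> int:
        return len(self.contrasts)


def compute_contrasts(
    tree: dendropy.Tree,
    trait: dict[str, float],
    transform_used: str = "none",
) -> ContrastSet:
    """Felsenstein pruning on a fully bifurcating tree.

    At each internal node with daughter values x1, x2 on (corrected)
    branch lengths v1, v2: the standardized contrast is
    (x1 - x2)/sqrt(v1 + v2); the ancestral value is the 1/v-weighted
    average; and the node's own branch is lengthened by v1*v2/(v1+v2).
    Contrasts are emitted in post-order.
    """
    missing = [
        lf.taxon.label for lf in tree.leaf_node_iter()
        if lf.taxon.label not in trait
    ]
    if missing:
        raise KeyError(f"no trait value for tips: {missing}")
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    sds: list[float] = []
    node_ids: list[str] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = float(trait[node.taxon.label])
            lengths[id(node)] = float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"{_node_label(node)} has {len(children)} children; "
                "contrasts require a fully bifurcating tree - resolve "
                "polytomies before calling"
            )
        c1, c2 = children
        v1, v2 = lengths[id(c1)], lengths[id(c2)]
        x1, x2 = values[id(c1)], values[id(c2)]
        sd = math.sqrt(v1 + v2)
        contrasts.append((x1 - x2) / sd)
        sds.append(sd)
        node_ids.append(f"{_first_tip(c1)}|{_first_tip(c2)}")
        values[id(node)] = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        lengths[id(node)] = float(node.edge.length or 0.0) + v1 * v2 / (v1 + v2)
    return ContrastSet(
        np.asarray(contrasts), np.asarray(sds), node_ids, transform_used
    )


def _first_tip(node: dendropy.Node) -> str:
    for lf in node.leaf_iter():
        return lf.taxon.label
    return "?"


@dataclass
class StandardizationReport:
    """Diagnostic: are |contrasts| unrelated to their expected SDs?"""

    correlation: float
    p: float
    passed: bool


def check_standardization(contrasts: ContrastSet) -> StandardizationReport:
    """Correlate |contrast| with expected SD (adequate standardization test).

    Branch lengths standardize the contrasts adequately when the Pearson
    correlation of absolute contrasts with their expected standard
    deviations is non-significant (p >= 0.05).  A constant column makes the
    correlation undefined; that carries no evidence of trend, so it is
    reported as correlation 0 with a warning.
    """
    if len(contrasts) < 3:
        raise ValueError("need at least 3 contrasts")
    a = np.abs(contrasts.contrasts)
    s = contrasts.expected_sd
    if np.std(a) == 0 or np.std(s) == 0:
        warnings.warn(
            "constant column in standardization check; correlation undefined",
            stacklevel=2,
        )
        return StandardizationReport(0.0, 1.0, True)
    r, p = stats.pearsonr(a, s)
    return StandardizationReport(float(r), float(p), bool(p >= 0.05))


def fit_sma_origin(
    x_contrasts: np.ndarray, y_contrasts: np.ndarray, alpha: float = 0.05
) -> SMAFit:
    """SMA line through the origin, as required for contrast regressions.

    |m| = sqrt(sum y^2 / sum x^2) with the sign of sum(x*y); the CI uses
    the same F-based construction as the ordinary SMA with df = n - 1.
    """
    x = np.asarray(x_contrasts, dtype=float)
    y = np.asarray(y_contrasts, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 aligned contrast pairs")
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero sum of squares on an axis")
    if sxy == 0:
        raise ValueError("sum(x*y) = 0: SMA slope sign undefined")
    n = len(x)
    m = math.copysign(math.sqrt(syy / sxx), sxy)
    r = sxy / math.sqrt(sxx * syy)
    lo, hi = slope_ci_from_summary(m, n, r * r, alpha, df=n - 1)
    return SMAFit(
        n=n, m=m, b=0.0, r=r, R2=r * r, ci_lower=lo, ci_upper=hi,
        mean_x=0.0, mean_y=0.0,
        var_x=sxx / (n - 1), var_y=syy / (n - 1),
        min_x=float(np.min(x)), alpha=alpha,
    )


def fit_ols_origin(x_contrasts, y_contrasts) -> tuple[float, float]:
    """OLS slope through the origin on contrasts, with its standard error.

    This is the Brownian-motion maximum-likelihood slope and coincides
    with the PGLS slope computed on the same tree.
    """
    x = np.asarray(x_contrasts, dtype=float)
    y = np.asarray(y_contrasts, dtype=float)
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("zero sum of squares in x contrasts")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    df = len(x) - 1
    se = math.sqrt(float(resid @ resid) / df / sxx) if df > 0 else math.nan
    return slope, se


def brownian_covariance(
    tree: dendropy.Tree, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix: shared path length from the root.

    C[i, j] is the depth (sum of branch lengths from the root) of the most
    recent common ancestor of tips i and j; C[i, i] is the tip's depth.
    """
    depths: dict[int, float] = {}
    tip_order: list[str] = []
    index: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = depths[id(parent)] if parent is not None else 0.0
        depths[id(node)] = base + float(node.edge.length or 0.0)
        if node.is_leaf():
            index[node.taxon.label] = len(tip_order)
            tip_order.append(node.taxon.label)
    n = len(tip_order)
    C = np.zeros((n, n))
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depths[id(node)]
            tips_below[id(node)] = [i]
            continue
        blocks = [tips_below[id(c)] for c in node.child_nodes()]
        d = depths[id(node)]
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                ia = np.array(blocks[a])[:, None]
                ib = np.array(blocks[b])[None, :]
                C[ia, ib] = d
                C[ib.T, ia.T] = d
        tips_below[id(node)] = [i for blk in blocks for i in blk]
    if taxa is not None:
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa absent from tree: {missing}")
        order = [index[t] for t in taxa]
        return C[np.ix_(order, order)], list(taxa)
    return C, tip_order


@dataclass
class GLSFit:
    """Generalized least squares fit under a Brownian covariance."""

    predictor_names: list[str]
    coefficients: np.ndarray  # without intercept
    intercept: float
    se: np.ndarray  # intercept first, then coefficients
    loglik: float
    n: int
    sigma2: float  # unbiased residual variance estimate
    covariance_model: str = "Brownian"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def slope_ci(self, which: int = 0, alpha: float = 0.05) -> tuple[float, float]:
        """t-based CI for one coefficient (df = n - k - 1)."""
        k = len(self.coefficients)
        tcrit = stats.t.ppf(1 - alpha / 2, self.n - k - 1)
        m = self.coefficients[which]
        s = self.se[1 + which]
        return (float(m - tcrit * s), float(m + tcrit * s))


def fit_pgls(
    tree: dendropy.Tree,
    predictors: dict[str, dict[str, float]],
    response: dict[str, float],
) -> GLSFit:
    """PGLS regression of a tip response on tip predictors.

    Fits beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept column, where C
    is the Brownian covariance of the taxa shared by the tree, every
    predictor map, and the response map.  Standard errors use the unbiased
    sigma^2 = RSS_gls/(n - k - 1); the reported log-likelihood is the
    Gaussian ML value.
    """
    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    taxa = [
        t for t in sorted(response)
        if t in tree_tips and all(t in p for p in predictors.values())
    ]
    if len(taxa) < len(predictors) + 2:
        raise ValueError("too few taxa shared by tree, predictors and response")
    C, taxa = brownian_covariance(tree, taxa)
    y = np.array([response[t] for t in taxa])
    names = list(predictors)
    X = np.column_stack(
        [np.ones(len(taxa))] + [[predictors[nm][t] for t in taxa] for nm in names]
    )
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"Brownian covariance not positive definite "
            f"(condition number {np.linalg.cond(C):.3g})"
        ) from exc
    Xt = np.linalg.solve(L, X)
    yt = np.linalg.solve(L, y)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    n, k = len(taxa), X.shape[1] - 1
    sigma2 = rss / (n - k - 1)
    xtx_inv = np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet_C + n)
    return GLSFit(
        predictor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        se=se,
        loglik=loglik,
        n=n,
        sigma2=sigma2,
    )
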