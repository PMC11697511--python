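"""Phylogenetic comparative statistics.

Under Brownian motion the trait vector across tips is multivariate normal
with covariance σ²V, where V[i, j] is the branch length shared by tips i and
j on their root-to-tip paths. PGLS exploits this: β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y.
Three Pagel branch-length transforms relax pure Brownian motion:

* λ ∈ [0, 1] scales the off-diagonal of V (phylogenetic signal; λ = 0 is an
  ordinary regression on a star phylogeny),
* δ ∈ (0, 3] raises node depths to a power (accelerating/decelerating
  evolution through time),
* κ ∈ [0, 3] raises individual branch lengths to a power (κ = 0 is the
  punctuational limit where every branch counts equally).

Exactly one parameter is free per model and is estimated by maximizing the
profile log-likelihood (σ̂² = eᵀV⁻¹e/n profiled out); the four candidates
(no transform, +λ, +δ, +κ) compete by AICc. Felsenstein's independent
contrasts and fast ML ancestral states complete the toolkit; the fixed-tree
PGLS slope equals the through-origin regression of contrasts, which the test
suite verifies to 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .tree import PhyloTree

TRANSFORM_BOUNDS = {"lambda": (0.0, 1.0), "delta": (1e-4, 3.0), "kappa": (0.0, 3.0)}
MODEL_ORDER = ("fixed", "lambda", "delta", "kappa")
MODEL_LABEL = {"fixed": "PGLS", "lambda": "PGLS+lambda", "delta": "PGLS+delta", "kappa": "PGLS+kappa"}


# -- covariance and transforms -----------------------------------------


def vcv_from_tree(tree: PhyloTree, taxa=None) -> tuple[list[str], np.ndarray]:
    """Brownian covariance matrix (shared path length to the MRCA)."""
    return tree.vcv(taxa)


class _EdgeBasis:
    """Edge decomposition V = Σ_e l_e · m_e m_eᵀ for fast κ re-evaluation.

    ``masks[e, i]`` is 1 when tip i lies below edge e, so powering the edge
    lengths and re-summing rebuilds the covariance without re-traversal.
    """

    def __init__(self, tree: PhyloTree, taxa: list[str]):
        index = {t: i for i, t in enumerate(taxa)}
        lengths, masks = [], []
        dtree = tree.dendropy_tree
        below: dict[dendropy.Node, np.ndarray] = {}
        for node in dtree.postorder_node_iter():
            m = np.zeros(len(taxa), dtype=bool)
            if node.is_leaf():
                i = index.get(node.taxon.label)
                if i is not None:
                    m[i] = True
            else:
                for c in node.child_nodes():
                    m |= below[c]
            below[node] = m
            length = node.edge.length
            if length is not None and m.any():
                lengths.append(float(length))
                masks.append(m)
        self.lengths = np.array(lengths)
        self.masks = np.array(masks, dtype=float)

    def vcv(self, edge_lengths: np.ndarray | None = None) -> np.ndarray:
        w = self.lengths if edge_lengths is None else edge_lengths
        return (self.masks * w[:, None]).T @ self.masks

    def vcv_kappa(self, kappa: float) -> np.ndarray:
        return self.vcv(np.power(self.lengths, kappa))


def transform_vcv(V: np.ndarray, parameter: str, value: float) -> np.ndarray:
    """Apply a Pagel transform to a covariance matrix.

    λ multiplies off-diagonal entries; δ raises entries (node depths) to the
    power δ and rescales so the maximum depth is preserved. κ acts on
    individual branch lengths and therefore needs the tree — use
    :func:`transform_tree` or :func:`pgls_fit` for κ.
    """
    lo, hi = TRANSFORM_BOUNDS.get(parameter, (None, None))
    if lo is None:
        raise KeyError(f"unknown transform {parameter!r}")
    if not (lo <= value <= hi) and not (parameter == "delta" and value > 0):
        raise ValueError(f"{parameter}={value} outside [{lo}, {hi}]")
    if parameter == "lambda":
        out = V * value
        np.fill_diagonal(out, np.diag(V))
        return out
    if parameter == "delta":
        T = float(np.max(np.diag(V)))
        return np.power(V, value) * T ** (1.0 - value)
    raise ValueError("kappa transform requires the tree; use transform_tree")


def transform_tree(tree: PhyloTree, parameter: str, value: float) -> PhyloTree:
    """Return a tree whose branch lengths realize the requested transform."""
    lo, hi = TRANSFORM_BOUNDS.get(parameter, (None, None))
    if lo is None:
        raise KeyError(f"unknown transform {parameter!r}")
    if not (min(lo, 0.0) <= value <= hi):
        raise ValueError(f"{parameter}={value} outside [{lo}, {hi}]")
    out = tree.copy()
    dtree = out.dendropy_tree
    if parameter == "kappa":
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(np.power(edge.length, value))
        return PhyloTree(dtree)
    if parameter == "delta":
        depths = out.node_depths()
        T = max(d for n, d in depths.items() if n.is_leaf())
        new_depth = {n: (d**value) * T ** (1.0 - value) for n, d in depths.items()}
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_depth[node] - new_depth[node.parent_node]
        return PhyloTree(dtree)
    # lambda on a tree: shrink internal edges, stretch terminal ones to keep depths
    depths = out.tip_depths()
    for node in dtree.preorder_node_iter():
        if node.edge.length is None:
            continue
        if node.is_leaf():
            d = depths[node.taxon.label]
            node.edge.length = node.edge.length * value + d * (1.0 - value)
        else:
            node.edge.length = node.edge.length * value
    return PhyloTree(dtree)


# -- independent contrasts ---------------------------------------------


@dataclass
class Contrasts:
    """Felsenstein's independent contrasts and the pruning by-products."""

    table: pd.DataFrame  # contrast, expected_variance, node_value, augmented_length
    root_value: float
    root_variance: float

    @property
    def values(self) -> np.ndarray:
        return self.table["contrast"].to_numpy()

    @property
    def variances(self) -> np.ndarray:
        return self.table["expected_variance"].to_numpy()


def _bifurcating_copy(tree: PhyloTree) -> dendropy.Tree:
    dtree = tree.copy().dendropy_tree
    dtree.resolve_polytomies(limit=2)
    for edge in dtree.preorder_edge_iter():
        if edge.length is None and edge.head_node.parent_node is not None:
            edge.length = 0.0
    return dtree


def pic(tree: PhyloTree, x: pd.Series) -> Contrasts:
    """Phylogenetic independent contrasts by the pruning recursion.

    Each internal node of a bifurcating tree yields one standardized
    contrast (xᵢ − xⱼ)/√(vᵢ + vⱼ); the node takes the precision-weighted
    mean of its children and its stem branch is augmented by vᵢvⱼ/(vᵢ+vⱼ).
    Polytomies are resolved with zero-length branches first.
    """
    missing = [t for t in tree.tip_labels if t not in x.index or pd.isna(x.get(t))]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    dtree = _bifurcating_copy(tree)
    rows = []
    state: dict[dendropy.Node, tuple[float, float]] = {}  # node -> (value, v)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            state[node] = (float(x[node.taxon.label]), float(node.edge.length or 0.0))
            continue
        (x1, v1), (x2, v2) = (state[c] for c in node.child_nodes())
        vsum = v1 + v2
        if vsum <= 0:  # coincident zero-length children: equal weights
            contrast, value, vnode = 0.0, 0.5 * (x1 + x2), 0.0
        else:
            contrast = (x1 - x2) / np.sqrt(vsum)
            value = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 else (
                x1 if v1 == 0 else x2
            )
            vnode = (v1 * v2 / vsum) if vsum > 0 else 0.0
        stem = float(node.edge.length or 0.0)
        state[node] = (value, stem + vnode)
        rows.append(
            {
                "contrast": contrast,
                "expected_variance": vsum,
                "node_value": value,
                "augmented_length": stem + vnode,
            }
        )
    root_value, root_var = state[dtree.seed_node]
    return Contrasts(pd.DataFrame(rows), root_value, root_var)


# -- PGLS ---------------------------------------------------------------


@dataclass
class PGLSResult:
    """A fitted phylogenetic regression under one evolutionary model."""

    response: str
    predictors: list[str]
    model: str  # fixed | lambda | delta | kappa
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    transform_value: float | None
    sigma2: float  # ML estimate e'V⁻¹e/n
    loglik: float
    aic: float
    aicc: float
    r2: float
    n: int
    k: int  # parameters counted by AICc
    dropped: list[str] = field(default_factory=list)
    qvalue: float | None = None

    @property
    def model_label(self) -> str:
        return MODEL_LABEL[self.model]

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1]) if len(self.params) > 1 else float("nan")

    @property
    def p_slope(self) -> float:
        return float(self.pvalues.iloc[1]) if len(self.pvalues) > 1 else float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        tq = stats.t.ppf(0.5 + level / 2.0, self.n - len(self.params))
        return (
            self.slope - tq * float(self.bse.iloc[1]),
            self.slope + tq * float(self.bse.iloc[1]),
        )


def _gls_profile(L: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Whitened GLS pieces given the Cholesky factor of V."""
    from scipy.linalg import solve_triangular

    z = solve_triangular(L, y, lower=True)
    W = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(W, z, rcond=None)
    e = z - W @ beta
    rss = float(e @ e)
    return z, W, beta, rss


def _loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    _, _, _, rss = _gls_profile(L, X, y)
    if rss <= 0:
        rss = np.finfo(float).tiny
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _optimize_transform(V_of, X, y, bounds, grid_size: int = 64):
    """Grid scan + bounded local refine of the profile likelihood."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, grid_size)
    lls = np.array([_loglik(V_of(v), X, y) for v in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda v: -_loglik(V_of(v), X, y), bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun >= lls[i]:
            return float(res.x), float(-res.fun)
    return float(grid[i]), float(lls[i])


def pgls_fit(
    tree: PhyloTree,
    y: pd.Series,
    x: pd.Series | pd.DataFrame | None = None,
    model: str = "fixed",
    response_name: str | None = None,
    transform_value: float | None = None,
) -> PGLSResult:
    """Fit a phylogenetic regression of ``y`` on ``x`` under one model.

    ``y`` (and the columns of ``x``) are pandas Series/DataFrames indexed by
    taxon; taxa missing any variable are dropped (complete case) and listed
    in ``result.dropped``. ``model`` chooses which Pagel parameter, if any,
    is free; the free parameter is estimated by profile ML unless
    ``transform_value`` pins it (then it does not count as a fitted
    parameter in AICc). ``x=None`` fits the intercept-only model.
    """
    if model not in MODEL_ORDER:
        raise ValueError(f"unknown model {model!r}")
    if x is None:
        X_df = pd.DataFrame(index=y.index)
    elif isinstance(x, pd.Series):
        X_df = x.to_frame(x.name or "x")
    else:
        X_df = x.copy()
    data = pd.concat([y.rename("__y__"), X_df], axis=1)
    data = data.loc[[t for t in tree.tip_labels if t in data.index]]
    complete = data.dropna()
    dropped = sorted(set(data.index) - set(complete.index))
    taxa = list(complete.index)
    n = len(taxa)
    n_coef = 1 + X_df.shape[1]
    if n < max(3, n_coef + 1):
        raise ValueError(f"only {n} complete taxa; need at least {max(3, n_coef + 1)}")

    yv = complete["__y__"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [complete[c].to_numpy(dtype=float) for c in X_df.columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    sub = tree.keep_tips(taxa) if n < tree.n_tips else tree
    basis = _EdgeBasis(sub, taxa)
    V0 = basis.vcv()

    pinned = transform_value is not None
    if model == "fixed":
        V = V0
        transform_value = None
    else:
        if model == "kappa":
            V_of = basis.vcv_kappa
        else:
            V_of = lambda v: transform_vcv(V0, model, v)
        if not pinned:
            transform_value, _ = _optimize_transform(V_of, X, yv, TRANSFORM_BOUNDS[model])
        V = V_of(transform_value)

    L = np.linalg.cholesky(V)
    z, W, beta, rss = _gls_profile(L, X, yv)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2 * np.pi * max(sigma2_ml, np.finfo(float).tiny)) + logdet + n)

    df_resid = n - n_coef
    sigma2_u = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.inv(W.T @ W)
    bse = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2_u, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # R² against the intercept-only GLS fit under the same V
    W0 = W[:, :1]
    b0 = float((W0[:, 0] @ z) / (W0[:, 0] @ W0[:, 0]))
    rss0 = float(np.sum((z - W0[:, 0] * b0) ** 2))
    r2 = 1.0 - rss / rss0 if rss0 > 0 else (1.0 if rss == 0 else np.nan)

    k = n_coef + 1 + (0 if model == "fixed" or pinned else 1)
    aic = -2.0 * loglik + 2.0 * k
    # AICc needs n > k + 1; smaller fits are valid but cannot enter AICc selection
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else None

    names = ["intercept"] + list(X_df.columns)
    return PGLSResult(
        response=response_name or (y.name or "y"),
        predictors=list(X_df.columns),
        model=model,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        transform_value=transform_value,
        sigma2=sigma2_ml,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
        r2=float(r2),
        n=n,
        k=k,
        dropped=dropped,
    )


def fit_all_models(tree, y, x, models=MODEL_ORDER, **kw) -> list[PGLSResult]:
    return [pgls_fit(tree, y, x, model=m, **kw) for m in models]


def model_select(results: list[PGLSResult]) -> PGLSResult:
    """Minimum-AICc candidate; ties break toward fewer parameters, then the
    fixed > λ > δ > κ model order."""
    if not results:
        raise ValueError("no fitted models")
    undefined = [r for r in results if r.aicc is None]
    if undefined:
        r = undefined[0]
        raise ValueError(f"AICc undefined: n={r.n} too small for k={r.k} parameters")
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    return min(results, key=lambda r: (round(r.aicc, 10), r.k, order[r.model]))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- ancestral states ---------------------------------------------------


@dataclass
class AncestralStates:
    """ML ancestral state estimates (Brownian motion) per internal node."""

    table: pd.DataFrame  # index: node id; columns: estimate, variance
    root_id: str

    @property
    def root_estimate(self) -> float:
        return float(self.table.loc[self.root_id, "estimate"])


def ancestral_states(tree: PhyloTree, x: pd.Series, min_branch: float = 1e-9) -> AncestralStates:
    """Fast ML ancestral states under Brownian motion.

    The joint ML solution minimizes Σ_edges (x_child − x_parent)²/l over
    internal-node states — a sparse weighted-Laplacian solve whose root
    component equals the precision-weighted (GLS) mean of the tips.
    Variances scale the inverse precision by the ML σ̂² from the tip data.
    """
    missing = [t for t in tree.tip_labels if t not in x.index or pd.isna(x.get(t))]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    dtree = tree.dendropy_tree
    internal = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    idx = {n: i for i, n in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        w = 1.0 / max(float(node.edge.length or 0.0), min_branch)
        j = idx[parent]
        if node.is_leaf():
            A[j, j] += w
            b[j] += w * float(x[node.taxon.label])
        else:
            i = idx[node]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
    est = np.linalg.solve(A, b)
    Ainv_diag = np.diag(np.linalg.inv(A))

    # ML rate from the tips: σ̂² = (x − μ̂)ᵀ V⁻¹ (x − μ̂) / n with GLS mean μ̂
    taxa, V = tree.vcv()
    xv = x[taxa].to_numpy(dtype=float)
    L = np.linalg.cholesky(V + min_branch * np.eye(len(taxa)))
    _, W, beta, rss = _gls_profile(L, np.ones((len(taxa), 1)), xv)
    sigma2 = rss / len(taxa)

    ids = []
    counter = 0
    for n in internal:
        label = n.taxon.label if n.taxon else None
        ids.append(label or f"node{counter}")
        counter += 1
    table = pd.DataFrame(
        {"estimate": est, "variance": sigma2 * Ainv_diag}, index=ids
    )
    return AncestralStates(table, root_id=ids[0])
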