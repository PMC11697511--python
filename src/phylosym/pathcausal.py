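"""Phylogenetic path analysis: ranking causal DAGs by d-separation tests.

Each candidate DAG over the trait set implies a basis set of conditional
independence claims (non-adjacent pairs, conditioned on the parents of
both). Every claim is tested as a phylogenetic regression — the p-value of
the would-be-independent predictor — under either a Brownian-motion or a
Pagel's-λ evolutionary model. The claims combine into Fisher's
C = −2 Σ ln pᵢ (χ² with 2k df under the model), and models are ranked by
the small-sample information criterion CICc = C + 2q·n/(n − 1 − q), with q
counting one parameter per edge plus one intercept per node. Top models
(ΔCICc within a cutoff) are averaged edge-wise to give the standardized
path coefficients reported to the user.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .comparative import pgls_fit
from .tree import PhyloTree


@dataclass(frozen=True)
class CausalDAG:
    """A directed acyclic graph over named traits."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    dag_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) uses unknown node")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError(f"graph {self.dag_id or self.edges} is cyclic")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def label(self) -> str:
        if self.dag_id:
            return self.dag_id
        return ", ".join(f"{u}->{v}" for u, v in self.edges) or "(no edges)"


@dataclass(frozen=True)
class IndependenceClaim:
    """X ⟂ Y | Z, tested by regressing ``y`` on ``x`` plus ``given``."""

    x: str
    y: str
    given: tuple[str, ...]

    def key(self):
        return (frozenset((self.x, self.y)), frozenset(self.given))


def dsep_basis(dag: CausalDAG) -> list[IndependenceClaim]:
    """Basis set of conditional-independence claims implied by the DAG.

    For every non-adjacent pair, ordered so that X precedes Y in a fixed
    (lexicographic) topological order, one claim X ⟂ Y | parents(X) ∪
    parents(Y); duplicates (same pair, same conditioning set) removed.
    """
    g = dag.graph()
    order = list(nx.lexicographical_topological_sort(g))
    pos = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in dag.edges}
    claims, seen = [], set()
    for a, b in itertools.combinations(order, 2):
        if frozenset((a, b)) in adjacent:
            continue
        x, y = (a, b) if pos[a] < pos[b] else (b, a)
        given = tuple(sorted((set(dag.parents(x)) | set(dag.parents(y))) - {x, y}))
        claim = IndependenceClaim(x, y, given)
        if claim.key() not in seen:
            seen.add(claim.key())
            claims.append(claim)
    return claims


def test_claim(
    claim: IndependenceClaim,
    traits: pd.DataFrame,
    tree: PhyloTree,
    evo_model: str = "BM",
) -> float:
    """p-value of the claim's X coefficient in a phylogenetic regression.

    ``evo_model``: "BM" fixes the Brownian covariance; "lambda" profiles
    Pagel's λ by ML. The later variable (Y) is the response.
    """
    for v in (claim.x, claim.y, *claim.given):
        if v not in traits.columns:
            raise KeyError(f"trait {v!r} missing from table")
    X = traits[[claim.x, *claim.given]]
    model = "fixed" if evo_model.lower() in ("bm", "brownian") else "lambda"
    fit = pgls_fit(tree, traits[claim.y], X, model=model)
    return float(fit.pvalues[claim.x])


def fisher_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C over a model's claim p-values: (C, df, p).

    C = −2 Σ ln pᵢ with df = 2k; p is the upper χ² tail. Zero p-values are
    floored at machine epsilon with a warning. k = 0 (saturated model)
    returns (0, 0, 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if (p < 0).any() or (p > 1).any():
        raise ValueError("claim p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("claim p-value of 0 floored at machine epsilon")
        p = np.maximum(p, np.finfo(float).eps)
    C = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return C, df, float(stats.chi2.sf(C, df))


def cicc(C: float, q: int, n: int) -> float:
    """CICc = C + 2q·n/(n − 1 − q); undefined unless n > q + 1."""
    if n <= q + 1:
        raise ValueError(f"CICc undefined: n={n} must exceed q+1={q + 1}")
    return float(C + 2.0 * q * n / (n - 1.0 - q))


@dataclass
class PathModelFit:
    """One candidate DAG's d-separation test set and information score."""

    dag: CausalDAG
    evo_model: str
    claims: list[IndependenceClaim]
    claim_pvalues: list[float]
    C: float
    df: int
    p: float
    q: int
    n: int
    cicc: float
    coefficients: dict[tuple[str, str], float]
    delta_cicc: float = np.nan


@dataclass
class AveragedPaths:
    """Edge-wise averaged standardized coefficients of the top models."""

    coefficients: dict[tuple[str, str], float]
    contributing: dict[tuple[str, str], list[str]]
    models: list[PathModelFit]
    cutoff: float
    conditional: bool = True


def standardize(traits: pd.DataFrame) -> pd.DataFrame:
    """z-score each column (mean 0, SD 1, sample SD) across genera."""
    return (traits - traits.mean()) / traits.std(ddof=1)


def _path_coefficients(
    dag: CausalDAG, traits: pd.DataFrame, tree: PhyloTree, model: str
) -> dict[tuple[str, str], float]:
    coefs: dict[tuple[str, str], float] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        if not parents:
            continue
        fit = pgls_fit(tree, traits[node], traits[list(parents)], model=model)
        for p in parents:
            coefs[(p, node)] = float(fit.params[p])
    return coefs


def rank_models(
    dags: list[CausalDAG],
    traits: pd.DataFrame,
    tree: PhyloTree,
    evo_model: str = "BM",
    prestandardized: bool = False,
) -> list[PathModelFit]:
    """Fit every DAG and rank ascending by CICc.

    Traits are z-scored across genera first (so path coefficients are
    standardized) and reduced to complete cases over the union of DAG nodes,
    keeping n identical across candidates. Ranking is deterministic: CICc,
    then the DAG's label.
    """
    if not dags:
        raise ValueError("no candidate DAGs")
    node_set = sorted({n for d in dags for n in d.nodes})
    data = traits[node_set].dropna()
    data = data.loc[[t for t in tree.tip_labels if t in data.index]]
    if not prestandardized:
        data = standardize(data)
    reg_model = "fixed" if evo_model.lower() in ("bm", "brownian") else "lambda"
    n = len(data)
    fits = []
    for dag in dags:
        claims = dsep_basis(dag)
        ps = [
            test_claim(c, data, tree, evo_model="BM" if reg_model == "fixed" else "lambda")
            for c in claims
        ]
        C, df, p = fisher_c(ps)
        q = len(dag.edges) + len(dag.nodes)
        fits.append(
            PathModelFit(
                dag=dag,
                evo_model=evo_model,
                claims=claims,
                claim_pvalues=ps,
                C=C,
                df=df,
                p=p,
                q=q,
                n=n,
                cicc=cicc(C, q, n),
                coefficients=_path_coefficients(dag, data, tree, reg_model),
            )
        )
    fits.sort(key=lambda f: (f.cicc, f.dag.label()))
    best = fits[0].cicc
    for f in fits:
        f.delta_cicc = f.cicc - best
    return fits


def average_models(
    fits: list[PathModelFit], cutoff: float = 2.0, conditional: bool = True
) -> AveragedPaths:
    """Average standardized coefficients over models within ΔCICc ≤ cutoff.

    Conditional averaging (default) averages each edge over only the top
    models that contain it; full averaging treats an absent edge as 0.
    """
    if not fits:
        raise ValueError("no fitted models")
    top = [f for f in fits if f.delta_cicc <= cutoff or np.isnan(f.delta_cicc)]
    if not top:
        top = [fits[0]]
    edges = sorted({e for f in top for e in f.coefficients})
    coefs, contrib = {}, {}
    for e in edges:
        holders = [f for f in top if e in f.coefficients]
        vals = [f.coefficients[e] for f in holders]
        denom = len(holders) if conditional else len(top)
        coefs[e] = float(sum(vals) / denom)
        contrib[e] = [f.dag.label() for f in holders]
    return AveragedPaths(coefs, contrib, top, cutoff, conditional)


# -- DAG set construction and file format -------------------------------


def all_dags(nodes) -> list[CausalDAG]:
    """Every DAG on the given labeled nodes (25 for three nodes)."""
    nodes = tuple(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    dags = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        try:
            dags.append(CausalDAG(nodes, tuple(edges), dag_id=f"m{len(dags) + 1:02d}"))
        except ValueError:
            continue  # cyclic orientation
    return dags


def preset_models(focal: str, trait_a: str, trait_b: str) -> list[CausalDAG]:
    """A 14-model set of biologically plausible pathways around a focal microbe.

    The six fully-connected triads, the four two-edge models where the focal
    taxon is adjacent to both host traits, and the four mediation chains
    with the focal taxon at an endpoint. This is a curated approximation of
    a "all plausible pathways" set: every model couples the focal taxon to
    both host traits directly or through a mediator.
    """
    nodes = (focal, trait_a, trait_b)
    e, a, b = focal, trait_a, trait_b
    edge_sets = [
        # fully connected triads (6 acyclic orientations)
        ((e, a), (e, b), (a, b)),
        ((e, a), (e, b), (b, a)),
        ((e, a), (b, e), (b, a)),
        ((a, e), (e, b), (a, b)),
        ((a, e), (b, e), (a, b)),
        ((a, e), (b, e), (b, a)),
        # focal hub: adjacent to both traits, no trait-trait edge
        ((e, a), (e, b)),
        ((e, a), (b, e)),
        ((a, e), (e, b)),
        ((a, e), (b, e)),
        # mediation chains with the focal taxon at an endpoint
        ((e, a), (a, b)),
        ((b, a), (a, e)),
        ((e, b), (b, a)),
        ((a, b), (b, e)),
    ]
    return [
        CausalDAG(nodes, tuple(edges), dag_id=f"p{i + 1:02d}")
        for i, edges in enumerate(edge_sets)
    ]


def parse_dag_file(text: str, nodes) -> list[CausalDAG]:
    """Read a DAG set from edge-list text: one model per line, ``id: A->B, A->C``.

    A line with an id and no edges (``id:``) is the empty model.
    """
    nodes = tuple(nodes)
    dags = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            dag_id, edge_spec = (s.strip() for s in line.split(":", 1))
        else:
            dag_id, edge_spec = f"m{len(dags) + 1:02d}", line
        edges = []
        for token in filter(None, (t.strip() for t in edge_spec.split(","))):
            if "->" not in token:
                raise ValueError(f"bad edge token {token!r} in line {raw!r}")
            u, v = (s.strip() for s in token.split("->", 1))
            edges.append((u, v))
        dags.append(CausalDAG(nodes, tuple(edges), dag_id=dag_id))
    return dags


def format_dag_file(dags: list[CausalDAG]) -> str:
    lines = []
    for d in dags:
        edges = ", ".join(f"{u}->{v}" for u, v in d.edges)
        lines.append(f"{d.dag_id or d.label()}: {edges}")
    return "\n".join(lines) + "\n"
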