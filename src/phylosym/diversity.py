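"""Alpha diversity, dominance, UniFrac/PCoA traits, and focal-taxon abundances.

Dominance is the ecological heart of the analysis: Simpson's Index
D = Σ pᵢ² is the probability that two reads drawn from a sample belong to
the same ASV, so a microbiome taken over by a single symbiont scores near 1.
Evenness is the Gini coefficient of the nonzero relative-abundance vector,
and richness is the analytic expectation of the number of ASVs observed in a
rarefied draw of ``depth`` reads (hypergeometric, no random subsampling).
Community-structure traits come from weighted UniFrac distances projected
onto principal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import weighted_unifrac as _skbio_weighted_unifrac
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import RANKS, UNASSIGNED, FeatureTable
from .tree import PhyloTree, serialize_newick


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() == 0:
        raise ValueError("all-zero count vector: diversity undefined")
    return c


def simpson_index(counts) -> float:
    """Simpson's Index D = Σ pᵢ²; 1.0 iff a single ASV holds all reads.

    Simpson's *Diversity* is 1 − D.
    """
    c = _as_counts(counts)
    p = c / c.sum()
    return float(np.sum(p**2))


def gini_evenness(counts, include_zeros: bool = False) -> float:
    """Gini coefficient of the relative-abundance vector; 0 = perfectly even.

    By default only taxa with nonzero counts enter the vector;
    ``include_zeros=True`` reproduces the zero-padded convention in which
    absent taxa count as maximally-poor members of the community.
    """
    c = _as_counts(counts)
    if not include_zeros:
        c = c[c > 0]
    x = np.sort(c / c.sum())
    s = len(x)
    i = np.arange(1, s + 1)
    return float(np.sum((2 * i - s - 1) * x) / s)


def rarefied_richness(counts, depth: int = 1000) -> float:
    """Expected number of ASVs observed in ``depth`` reads drawn without replacement.

    E[S] = Σᵢ [1 − C(N−Nᵢ, d) / C(N, d)] with N the library size. Deterministic;
    raises if the library is shallower than ``depth``.
    """
    c = np.round(_as_counts(counts)).astype(np.int64)
    c = c[c > 0]
    N = int(c.sum())
    if N < depth:
        raise ValueError(f"library size {N} below rarefaction depth {depth}")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_cN = log_choose(N, depth)
    miss = np.where(N - c >= depth, np.exp(log_choose(N - c, depth) - log_cN), 0.0)
    return float(np.sum(1.0 - miss))


# -- beta diversity ----------------------------------------------------


def _skbio_tree(tree: PhyloTree) -> TreeNode:
    return TreeNode.read(StringIO(serialize_newick(tree)), convert_underscores=False)


def weighted_unifrac(tree: PhyloTree, counts_a, counts_b, taxa=None) -> float:
    """Normalized weighted UniFrac distance between two samples.

    Σ_b l_b·|p_A(b) − p_B(b)| / Σ_b l_b·(p_A(b) + p_B(b)) over branches b,
    where p(b) is the relative abundance subtended by the branch. Both count
    vectors must be indexable by tree tips: pass pandas Series indexed by
    taxon, or arrays plus ``taxa``.
    """
    if taxa is None:
        if not isinstance(counts_a, pd.Series) or not isinstance(counts_b, pd.Series):
            raise ValueError("pass taxa ids or pandas Series indexed by taxon")
        taxa = list(counts_a.index)
        if list(counts_b.index) != taxa:
            counts_b = counts_b.reindex(taxa, fill_value=0)
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    tips = set(tree.tip_labels)
    missing = [t for t, ca, cb in zip(taxa, a, b) if (ca > 0 or cb > 0) and t not in tips]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty sample in weighted UniFrac")
    return float(
        _skbio_weighted_unifrac(a, b, taxa=list(taxa), tree=_skbio_tree(tree), normalized=True)
    )


def unifrac_distance_matrix(tree: PhyloTree, counts: pd.DataFrame) -> pd.DataFrame:
    """All-pairs normalized weighted UniFrac over the columns (samples) of ``counts``."""
    samples = list(counts.columns)
    n = len(samples)
    D = np.zeros((n, n))
    sk_tree = _skbio_tree(tree)
    taxa = list(counts.index)
    arr = counts.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = float(
                _skbio_weighted_unifrac(arr[:, i], arr[:, j], taxa=taxa, tree=sk_tree, normalized=True)
            )
    return pd.DataFrame(D, index=samples, columns=samples)


def pcoa_traits(distances: pd.DataFrame | np.ndarray, k: int = 3) -> pd.DataFrame:
    """Classical MDS of a distance matrix; first ``k`` positive-eigenvalue axes.

    Columns are ``PC1..PCk``; axes are ordered by eigenvalue and axes with
    negative eigenvalues are never returned.
    """
    if isinstance(distances, pd.DataFrame):
        ids = [str(i) for i in distances.index]
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    res = _skbio_pcoa(DistanceMatrix(mat, ids), method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = int(np.sum(eig > 1e-12))
    k_eff = min(k, pos)
    coords = res.samples.iloc[:, :k_eff].to_numpy()
    out = np.zeros((mat.shape[0], k))
    out[:, :k_eff] = coords
    return pd.DataFrame(out, index=ids, columns=[f"PC{i+1}" for i in range(k)])


# -- group summaries ---------------------------------------------------


@dataclass
class DominantTaxonReport:
    host_genus: str
    compartment: str
    taxon: str
    mean_relative_abundance: float
    unclassified_below_order: bool


def alpha_table(table: FeatureTable, depth: int = 1000) -> pd.DataFrame:
    """Per-sample alpha metrics: richness_1000, gini, simpson.

    Samples shallower than ``depth`` reads are excluded and listed in the
    frame's ``attrs['excluded']``.
    """
    rows, excluded = [], []
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        if c.sum() == 0 or c.sum() < depth:
            excluded.append(s)
            continue
        rows.append(
            {
                "sample_id": s,
                "host_genus": table.metadata.loc[s, "host_genus"],
                "compartment": table.metadata.loc[s, "compartment"],
                f"richness_{depth}": rarefied_richness(c, depth),
                "gini": gini_evenness(c),
                "simpson": simpson_index(c),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame()
    out.attrs["excluded"] = excluded
    return out


def dominant_taxon(
    table: FeatureTable, host_genus: str, compartment: str, rank: str = "genus"
) -> DominantTaxonReport:
    """Most abundant taxon on average across the group's samples.

    Abundance is the mean of per-sample relative abundances (not pooled
    counts). Ties break lexicographically; a winner whose lineage lacks an
    order-level assignment is flagged.
    """
    samples = table.samples_in_group(host_genus, compartment)
    if not samples:
        raise ValueError(f"no samples for ({host_genus}, {compartment})")
    collapsed = table.collapse_rank(rank)[samples]
    rel = collapsed.div(collapsed.sum(axis=0).replace(0, np.nan), axis=1)
    means = rel.mean(axis=1).sort_index()
    winner = means.idxmax()  # idxmax returns the first (lexicographic) max
    order_of = (
        table.taxonomy.loc[table.taxonomy[rank] == winner, "order"]
        if winner != UNASSIGNED
        else pd.Series([UNASSIGNED])
    )
    unclassified = bool(winner == UNASSIGNED or (order_of == UNASSIGNED).all())
    return DominantTaxonReport(
        host_genus, compartment, winner, float(means.loc[winner]), unclassified
    )


def taxon_relative_abundance(
    table: FeatureTable,
    focal_genus: str,
    rank: str = "genus",
    per_1000: bool = False,
) -> pd.DataFrame:
    """Mean summed relative abundance of a focal taxon per (host genus, compartment).

    An absent taxon yields 0. ``per_1000`` scales by 1000 for presentation.
    """
    focal_asvs = table.taxonomy.index[table.taxonomy[rank] == focal_genus]
    rel = table.relative_abundance()
    per_sample = (
        rel.loc[rel.index.intersection(focal_asvs)].sum(axis=0)
        if len(focal_asvs)
        else pd.Series(0.0, index=table.sample_ids)
    )
    df = table.metadata.loc[per_sample.index, ["host_genus", "compartment"]].copy()
    df["abundance"] = per_sample * (1000 if per_1000 else 1)
    out = df.groupby(["host_genus", "compartment"], observed=True)["abundance"].agg(
        ["mean", "size"]
    )
    return out.rename(columns={"mean": "mean_relative_abundance", "size": "n_samples"})


@dataclass
class PooledAsvAbundance:
    """Per-sample summed relative abundance of a compartment-preferring ASV pool."""

    focal_genus: str
    compartment: str
    asv_ids: list[str]
    per_sample: pd.Series


def pool_asvs_by_compartment(
    table: FeatureTable,
    focal_genus: str,
    min_total_count: int = 10,
    rank: str = "genus",
) -> dict[str, PooledAsvAbundance]:
    """Partition focal-taxon ASVs by the compartment where each is most abundant.

    ASVs with total count < ``min_total_count`` are removed first. Each
    retained ASV joins the single compartment where its mean relative
    abundance is highest (ties break toward the compartment order mucus,
    tissue, skeleton, then lexicographic ASV id keeps output stable). The
    pools partition the retained ASVs.
    """
    focal_asvs = sorted(table.taxonomy.index[table.taxonomy[rank] == focal_genus])
    focal_asvs = [a for a in focal_asvs if a in table.counts.index]
    totals = table.counts.loc[focal_asvs].sum(axis=1)
    retained = [a for a in focal_asvs if totals[a] >= min_total_count]
    rel = table.relative_abundance()
    comp_of_sample = table.metadata.loc[table.counts.columns, "compartment"]
    pools: dict[str, list[str]] = {c: [] for c in ("mucus", "tissue", "skeleton")}
    for asv in retained:
        means = rel.loc[asv].groupby(comp_of_sample.values).mean()
        best, best_val = None, -np.inf
        for comp in ("mucus", "tissue", "skeleton"):
            v = float(means.get(comp, np.nan))
            if np.isfinite(v) and v > best_val:
                best, best_val = comp, v
        if best is not None:
            pools[best].append(asv)
    out = {}
    for comp, members in pools.items():
        per_sample = (
            rel.loc[members].sum(axis=0) if members else pd.Series(0.0, index=table.sample_ids)
        )
        out[comp] = PooledAsvAbundance(focal_genus, comp, members, per_sample)
    return out


def summarize_by_group(records: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Arithmetic mean of per-sample metrics within (host genus, compartment).

    ``records`` must carry ``host_genus`` and ``compartment`` columns (as
    produced by :func:`alpha_table`); remaining numeric columns are averaged.
    Group sizes are reported as ``n_samples``.
    """
    if records.empty:
        return pd.DataFrame()
    metrics = metrics or [
        c
        for c in records.columns
        if c not in ("host_genus", "compartment") and pd.api.types.is_numeric_dtype(records[c])
    ]
    grouped = records.groupby(["host_genus", "compartment"], observed=True)
    out = grouped[metrics].mean()
    out["n_samples"] = grouped.size()
    return out
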