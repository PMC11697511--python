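"""Synthetic data with known ground truth for every stage of the analysis.

The generator emulates the statistical structure of a multi-genus coral
microbiome survey: a time-calibrated host phylogeny (pure-birth, rescaled to
unit depth), latent host traits evolving by Brownian motion along it and
coupled through a structural-equation DAG, Dirichlet-multinomial 16S count
tables per anatomical compartment whose expected focal-taxon (default
*Endozoicomonas*) relative abundance tracks the latent trait through a
logistic link, binomial disease survey counts per genus and source, and
replicated growth-rate records in mm/yr. A ground-truth sidecar records
every planted parameter so recovery tests can close the loop.

Defaults follow the study conditions the analysis targets: ~40 host genera,
three compartments, per-genus survey sizes large enough that most genera
clear the 100-colony filter while a few do not, and planted path
coefficients E→disease = 0.8, E→growth = 0.6.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .io import RANKS, DiseaseRecords, FeatureTable, TraitTable
from .pathcausal import CausalDAG
from .tree import PhyloTree

COMPARTMENTS = ("mucus", "tissue", "skeleton")


def _spawn(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stream."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode()) % (2**31)])


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth tree on ``n_tips`` labeled tips, rescaled to unit height."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng([seed, 811])
    # Yule construction: start with a cherry, repeatedly split a uniformly
    # chosen extant lineage after an Exp(k·birth_rate) waiting time.
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        child.edge.length = 0.0
        active.append(child)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (len(active) * birth_rate))
        for node in active:
            node.edge.length += wait
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = split.new_child()
            child.edge.length = 0.0
            active.append(child)
    wait = rng.exponential(1.0 / (len(active) * birth_rate))
    for node in active:
        node.edge.length += wait
    labels = [f"t{i + 1}" for i in range(n_tips)]
    for node, label in zip(active, labels):
        node.taxon = taxa.get_taxon(label)
    out = PhyloTree(tree)
    # rescale to unit root-to-tip height
    height = out.max_depth()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return PhyloTree(tree)


def simulate_bm(
    tree: PhyloTree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    lam: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Multivariate-normal tip traits with covariance σ²·V_λ."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be ≥ 0")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    taxa, V = tree.vcv()
    Vl = V * lam
    np.fill_diagonal(Vl, np.diag(V))
    rng = _spawn(seed, "bm")
    if sigma2 == 0:
        return pd.Series(root_value, index=taxa)
    x = rng.multivariate_normal(np.full(len(taxa), root_value), sigma2 * Vl, method="cholesky")
    return pd.Series(x, index=taxa)


def simulate_path_traits(
    tree: PhyloTree,
    dag: CausalDAG,
    coefficients: dict[tuple[str, str], float],
    noise_sd: dict[str, float] | float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
) -> TraitTable:
    """Structural-equation traits on a tree: node = Σ β·z(parent) + BM noise.

    Nodes are generated in topological order; each is z-scored before
    feeding children so the planted coefficients are standardized. Output
    columns are z-scored too.
    """
    import networkx as nx

    order = list(nx.lexicographical_topological_sort(dag.graph()))
    taxa = tree.tip_labels
    values: dict[str, pd.Series] = {}
    for i, node in enumerate(order):
        sd = noise_sd if isinstance(noise_sd, (int, float)) else noise_sd.get(node, 1.0)
        noise = simulate_bm(tree, sigma2=float(sd) ** 2, lam=lam, seed=seed * 1009 + i)
        total = noise.copy()
        for parent in dag.parents(node):
            beta = coefficients.get((parent, node), 0.0)
            z = (values[parent] - values[parent].mean()) / values[parent].std(ddof=1)
            total = total + beta * z
        values[node] = total
    df = pd.DataFrame({n: values[n] for n in dag.nodes}, index=taxa)
    df = (df - df.mean()) / df.std(ddof=1)
    df.index.name = "genus"
    return TraitTable(df)


def simulate_counts(
    focal_target: dict[str, float],
    samples_per_genus: int = 4,
    compartment: str = "tissue",
    n_background_asvs: int = 150,
    n_focal_asvs: int = 4,
    concentration: float = 40.0,
    library_size_log_mean: float = 8.5,
    library_size_log_sd: float = 0.4,
    seed: int = 0,
    sample_prefix: str = "",
    focal_genus: str = "Endozoicomonas",
) -> FeatureTable:
    """Dirichlet-multinomial count table with a planted focal-taxon abundance.

    ``focal_target`` maps host genus → expected relative abundance of the
    focal bacterial genus in that host. The base composition assigns the
    focal mass to ``n_focal_asvs`` ASVs and spreads the remainder over a
    geometric series of background ASVs; per-sample compositions are
    Dirichlet(concentration × base) and counts multinomial with log-normal
    library sizes. Expected focal proportion equals the target, and a higher
    target mechanically raises Simpson's Index.
    """
    if any(not (0.0 <= p < 1.0) for p in focal_target.values()):
        raise ValueError("focal targets must lie in [0, 1)")
    rng = _spawn(seed, f"counts-{compartment}")
    focal_ids = [f"ASV_{focal_genus[:4].lower()}{i + 1}" for i in range(n_focal_asvs)]
    bg_ids = [f"ASV_bg{i + 1:03d}" for i in range(n_background_asvs)]
    asv_ids = focal_ids + bg_ids
    # background base composition: geometric ranks, shared across hosts
    bg_base = 0.85 ** np.arange(n_background_asvs)
    bg_base /= bg_base.sum()
    focal_split = 0.6 ** np.arange(n_focal_asvs)
    focal_split /= focal_split.sum()

    counts = {}
    meta_rows = {}
    for genus in sorted(focal_target):
        target = focal_target[genus]
        base = np.concatenate([target * focal_split, (1.0 - target) * bg_base])
        for s in range(samples_per_genus):
            sample_id = f"{sample_prefix}{genus}_{compartment}_{s + 1}"
            composition = rng.dirichlet(np.maximum(concentration * base, 1e-9))
            composition[base == 0] = 0.0  # absent taxa stay exactly absent
            composition /= composition.sum()
            depth = int(np.ceil(rng.lognormal(library_size_log_mean, library_size_log_sd)))
            counts[sample_id] = rng.multinomial(depth, composition)
            meta_rows[sample_id] = {"host_genus": genus, "compartment": compartment}
    counts_df = pd.DataFrame(counts, index=asv_ids)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    lineages = []
    for a in asv_ids:
        if a in focal_ids:
            lineages.append(
                ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales",
                 "Endozoicomonadaceae", focal_genus, "")
            )
        else:
            k = int(a.split("bg")[1])
            lineages.append(
                ("Bacteria", f"Phylum{k % 8 + 1}", f"Class{k % 12 + 1}",
                 f"Order{k % 20 + 1}" if k % 11 else "",  # some unassigned orders
                 f"Family{k % 30 + 1}", f"Genus{k:03d}", "")
            )
    taxonomy = pd.DataFrame(lineages, index=asv_ids, columns=list(RANKS))
    return FeatureTable(counts_df, meta, taxonomy)


def simulate_disease(
    prevalence: dict[str, float],
    survey_sizes: dict[str, list[int]] | None = None,
    n_sources: int = 2,
    survey_log_mean: float = 5.5,
    survey_log_sd: float = 0.9,
    seed: int = 0,
) -> DiseaseRecords:
    """Binomial survey counts d ~ Bin(n, prevalence) per genus and source.

    Survey sizes default to log-normal draws (median ≈ 245 colonies per
    source), wide enough that a minority of genera fall under the
    100-colony filter — mirroring the long tail of rarely-surveyed taxa.
    """
    rng = _spawn(seed, "disease")
    rows = []
    for genus in sorted(prevalence):
        p = prevalence[genus]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {p} outside [0, 1] for {genus}")
        sizes = (
            survey_sizes[genus]
            if survey_sizes is not None
            else [max(1, int(rng.lognormal(survey_log_mean, survey_log_sd))) for _ in range(n_sources)]
        )
        for j, n in enumerate(sizes):
            d = int(rng.binomial(n, p))
            rows.append({"source": f"survey{j + 1}", "genus": genus, "healthy": n - d, "diseased": d})
    return DiseaseRecords(pd.DataFrame(rows))


@dataclass
class SimScenario:
    """Parameters of one synthetic study; the defaults are the study conditions."""

    n_genera: int = 40
    tips_per_genus: int = 3
    birth_rate: float = 1.0
    # structural equations on latent traits (standardized scale)
    path_edges: tuple[tuple[str, str], ...] = (("E", "D"), ("E", "G"))
    path_coefficients: dict = field(
        default_factory=lambda: {("E", "D"): 0.8, ("E", "G"): 0.6}
    )
    noise_sd: dict = field(default_factory=lambda: {"E": 1.0, "D": 0.6, "G": 0.8})
    trait_lambda: float = 1.0
    # measurement layers
    samples_per_compartment: int = 8
    n_background_asvs: int = 150
    n_focal_asvs: int = 4
    dirichlet_concentration: float = 40.0
    library_size_log_mean: float = 8.5
    library_size_log_sd: float = 0.4
    focal_genus: str = "Endozoicomonas"
    # logistic links latent trait -> observable scale
    focal_abundance_base: float = -2.5   # logit of mean focal RA ≈ 0.076
    focal_abundance_slope: float = 0.9
    disease_base: float = -2.2           # logit of mean prevalence ≈ 0.10
    disease_slope: float = 0.8
    n_disease_sources: int = 2
    survey_log_mean: float = 6.5
    survey_log_sd: float = 0.9
    growth_mean: float = 10.0            # mm/yr, massive-to-branching span
    growth_between_sd: float = 4.0
    growth_within_sd: float = 1.5
    growth_records_min: int = 3
    growth_records_max: int = 10
    seed: int = 0


@dataclass
class MiniGcmpBundle:
    """An internally consistent synthetic study plus its ground truth."""

    species_tree: PhyloTree
    genus_tree: PhyloTree
    genus_of: dict[str, str]
    feature_tables: dict[str, FeatureTable]  # compartment -> table
    disease: DiseaseRecords
    growth_records: pd.DataFrame  # genus, growth_mm_yr
    latent_traits: TraitTable  # E, D, G (z-scored ground truth)
    scenario: SimScenario

    @property
    def truth(self) -> dict:
        return asdict(self.scenario)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def make_mini_gcmp(scenario: SimScenario | None = None, seed: int | None = None) -> MiniGcmpBundle:
    """Generate the full synthetic study bundle.

    Species tree → genus tree (one random representative per genus, depths
    preserved) → latent traits E (focal symbiont load), D (disease
    liability), G (growth potential) by the scenario's structural equations
    → per-compartment count tables, binomial disease surveys, and replicated
    growth records through the measurement links.
    """
    sc = scenario or SimScenario()
    if seed is not None:
        sc = SimScenario(**{**asdict(sc), "seed": seed})
    genera = [f"Genus{i + 1:02d}" for i in range(sc.n_genera)]
    n_species = sc.n_genera * sc.tips_per_genus
    species_tree = simulate_yule_tree(n_species, sc.birth_rate, seed=sc.seed)
    # contiguous tip blocks per genus keep congeners related, as in a real tree
    tips = species_tree.tip_labels
    genus_of = {}
    for i, tip in enumerate(tips):
        g = genera[i // sc.tips_per_genus]
        genus_of[tip] = g
    genus_tree = species_tree.prune_to_genus(genus_of, genera, seed=sc.seed + 1)

    dag = CausalDAG(("E", "D", "G"), sc.path_edges)
    latent = simulate_path_traits(
        genus_tree, dag, sc.path_coefficients, sc.noise_sd, lam=sc.trait_lambda, seed=sc.seed + 2
    )
    E, D, G = (latent.table[c] for c in ("E", "D", "G"))

    # tissue carries the full signal; mucus and skeleton attenuated copies
    attenuation = {"mucus": 0.5, "tissue": 1.0, "skeleton": 0.25}
    rng = _spawn(sc.seed, "links")
    tables = {}
    for comp in COMPARTMENTS:
        target = _logistic(
            sc.focal_abundance_base + sc.focal_abundance_slope * attenuation[comp] * E
        )
        tables[comp] = simulate_counts(
            dict(zip(E.index, target)),
            samples_per_genus=sc.samples_per_compartment,
            compartment=comp,
            n_background_asvs=sc.n_background_asvs,
            n_focal_asvs=sc.n_focal_asvs,
            concentration=sc.dirichlet_concentration,
            library_size_log_mean=sc.library_size_log_mean,
            library_size_log_sd=sc.library_size_log_sd,
            seed=sc.seed + 3,
            focal_genus=sc.focal_genus,
        )

    prevalence = dict(zip(D.index, _logistic(sc.disease_base + sc.disease_slope * D)))
    disease = simulate_disease(
        prevalence,
        n_sources=sc.n_disease_sources,
        survey_log_mean=sc.survey_log_mean,
        survey_log_sd=sc.survey_log_sd,
        seed=sc.seed + 4,
    )

    growth_rng = _spawn(sc.seed, "growth")
    rows = []
    for genus in genera:
        mu = sc.growth_mean + sc.growth_between_sd * float(G[genus])
        n_rec = int(growth_rng.integers(sc.growth_records_min, sc.growth_records_max + 1))
        for _ in range(n_rec):
            rows.append(
                {"genus": genus, "growth_mm_yr": max(0.1, mu + growth_rng.normal(0, sc.growth_within_sd))}
            )
    growth = pd.DataFrame(rows)

    return MiniGcmpBundle(
        species_tree=species_tree,
        genus_tree=genus_tree,
        genus_of=genus_of,
        feature_tables=tables,
        disease=disease,
        growth_records=growth,
        latent_traits=latent,
        scenario=sc,
    )
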