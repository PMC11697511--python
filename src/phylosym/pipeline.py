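"""End-to-end orchestration: inputs → genus trait table → comparative + causal results.

The pipeline mirrors the analysis design: per-sample microbiome summaries
are averaged within (host genus, compartment); disease surveys are summed
within genera and filtered at 100 observed colonies; growth requires ≥5
replicate records per genus; everything joins into one genus × trait table
aligned to a genus-level phylogeny. Comparative tests run the four-model
PGLS battery with AICc selection and per-family BH q-values; the causal
stage ranks DAGs by CICc under both Brownian and Pagel's-λ evolution and
averages the top models' standardized path coefficients.

All outputs are plain TSVs; re-running with the same config and seeds is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative, disease as disease_mod, diversity, pathcausal
from .io import DiseaseRecords, FeatureTable, TraitTable, save_trait_table
from .synth import MiniGcmpBundle
from .tree import PhyloTree

log = logging.getLogger("phylosym.pipeline")


@dataclass
class RunConfig:
    """Knobs of a full analysis run; defaults are the published thresholds."""

    compartments: tuple[str, ...] = ("mucus", "tissue", "skeleton")
    focal_taxon: str = "Endozoicomonas"
    min_disease_n: int = 100
    asv_min_total_count: int = 10
    rarefaction_depth: int = 1000
    growth_min_replicates: int = 5
    pgls_models: tuple[str, ...] = ("fixed", "lambda", "delta", "kappa")
    compute_beta: bool = True
    beta_axes: int = 3
    delta_cicc_cutoff: float = 2.0
    path_evo_models: tuple[str, ...] = ("BM", "lambda")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("compartments", "pgls_models", "path_evo_models"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


def _harmonize(name: str) -> str:
    return str(name).strip().casefold().capitalize()


def build_trait_table(
    feature_tables: dict[str, FeatureTable],
    disease_records: DiseaseRecords | None,
    growth_records: pd.DataFrame | None,
    config: RunConfig = RunConfig(),
    asv_tree: PhyloTree | None = None,
) -> TraitTable:
    """Join per-compartment microbiome summaries, disease, and growth by genus.

    Produces one row per host genus with, per compartment: mean Simpson's
    Index, Gini evenness, rarefied richness, the focal taxon's mean relative
    abundance, the dominant taxon's mean abundance, and (when ``asv_tree``
    is given and ``compute_beta`` is on) means of the first weighted-UniFrac
    principal coordinates. Disease prevalence is included only for genera
    passing the minimum-observation filter; growth only with enough
    replicate records. Per-trait sample sizes ride along as ``*_n`` columns.
    """
    frames: dict[str, pd.Series] = {}
    genera: set[str] = set()

    for comp, table in feature_tables.items():
        if comp not in config.compartments:
            continue
        alpha = diversity.alpha_table(table, depth=config.rarefaction_depth)
        if alpha.attrs.get("excluded"):
            log.info("%s: %d samples below depth %d excluded", comp,
                     len(alpha.attrs["excluded"]), config.rarefaction_depth)
        if alpha.empty:
            continue
        summary = diversity.summarize_by_group(alpha)
        summary = summary.reset_index().set_index("host_genus")
        genera |= set(summary.index)
        frames[f"simpson_{comp}"] = summary["simpson"]
        frames[f"gini_{comp}"] = summary["gini"]
        frames[f"richness{config.rarefaction_depth}_{comp}"] = summary[
            f"richness_{config.rarefaction_depth}"
        ]
        frames[f"alpha_n_{comp}"] = summary["n_samples"]

        focal = diversity.taxon_relative_abundance(table, config.focal_taxon)
        focal = focal.reset_index()
        focal = focal[focal["compartment"] == comp].set_index("host_genus")
        frames[f"{config.focal_taxon.lower()}_ra_{comp}"] = focal["mean_relative_abundance"]

        dominant = {}
        for g in sorted(set(table.metadata["host_genus"])):
            try:
                rep = diversity.dominant_taxon(table, g, comp)
            except ValueError:
                continue
            dominant[g] = rep.mean_relative_abundance
        frames[f"dominance_ra_{comp}"] = pd.Series(dominant)

        if config.compute_beta and asv_tree is not None:
            deep = [s for s in table.sample_ids if s in alpha.index]
            dm = diversity.unifrac_distance_matrix(asv_tree, table.counts[deep])
            pcs = diversity.pcoa_traits(dm, k=config.beta_axes)
            pcs["host_genus"] = table.metadata.loc[pcs.index, "host_genus"].values
            means = pcs.groupby("host_genus").mean()
            for i in range(config.beta_axes):
                frames[f"wu_pc{i + 1}_{comp}"] = means[f"PC{i + 1}"]

    if disease_records is not None:
        summaries = disease_mod.aggregate_disease(disease_records)
        retained, report = disease_mod.filter_genera(summaries, min_n=config.min_disease_n)
        if len(report.dropped):
            log.info("disease filter dropped %d genera (retained %.1f%% of observations)",
                     len(report.dropped), 100 * report.fraction_observations_retained)
        prev = disease_mod.prevalence_table(retained)
        frames["disease_prevalence"] = prev["prevalence"]
        frames["disease_n"] = prev["n"]
        genera |= set(prev.index)

    if growth_records is not None and len(growth_records):
        g = growth_records.copy()
        g["genus"] = g["genus"].map(_harmonize)
        agg = g.groupby("genus")["growth_mm_yr"].agg(["mean", "size"])
        enough = agg[agg["size"] >= config.growth_min_replicates]
        frames["growth_mm_yr"] = enough["mean"]
        frames["growth_n"] = enough["size"]
        genera |= set(enough.index)

    if not genera:
        raise ValueError("no genera shared across input sources")
    table = pd.DataFrame({k: v for k, v in frames.items()}, index=sorted(genera))
    table.index.name = "genus"
    return TraitTable(table)


@dataclass
class ComparativeRun:
    """One (response, predictor) test: the 4-model battery and the winner."""

    results: pd.DataFrame  # tidy table, one row per fitted candidate + winner flag
    fits: dict  # (response, predictor) -> list[PGLSResult]
    best: dict  # (response, predictor) -> PGLSResult


def default_analyses(config: RunConfig, trait_table: TraitTable) -> list[tuple[str, str, str]]:
    """(family, response, predictor) triples covering the standard battery."""
    focal = config.focal_taxon.lower()
    cols = set(trait_table.table.columns)
    out = []
    for comp in config.compartments:
        for metric in ("simpson", "gini", f"richness{config.rarefaction_depth}"):
            name = f"{metric}_{comp}"
            if name in cols and "disease_prevalence" in cols:
                out.append(("alpha_vs_disease", "disease_prevalence", name))
        for i in range(config.beta_axes):
            name = f"wu_pc{i + 1}_{comp}"
            if name in cols and "disease_prevalence" in cols:
                out.append(("beta_vs_disease", "disease_prevalence", name))
        name = f"{focal}_ra_{comp}"
        if name in cols:
            if "disease_prevalence" in cols:
                out.append(("focal_vs_disease", "disease_prevalence", name))
            if "growth_mm_yr" in cols:
                out.append(("focal_vs_growth", "growth_mm_yr", name))
            if f"simpson_{comp}" in cols:
                out.append(("focal_vs_dominance", f"simpson_{comp}", name))
    return out


def run_comparative(
    config: RunConfig,
    trait_table: TraitTable,
    tree: PhyloTree,
    analyses: list[tuple[str, str, str]] | None = None,
) -> ComparativeRun:
    """Fit the PGLS model battery for each configured trait pair.

    Each (response, predictor) pair gets one fit per configured model, an
    AICc winner, and a BH q-value computed within its FDR family over the
    winners' slope p-values. Pairs with <3 complete genera are skipped with
    a log entry.
    """
    analyses = analyses if analyses is not None else default_analyses(config, trait_table)
    rows = []
    fits: dict = {}
    best: dict = {}
    skipped = []
    for family, response, predictor in analyses:
        y = trait_table.table[response]
        x = trait_table.table[predictor]
        try:
            candidates = [
                comparative.pgls_fit(tree, y, x, model=m, response_name=response)
                for m in config.pgls_models
            ]
        except ValueError as exc:
            skipped.append((response, predictor, str(exc)))
            log.info("skipped %s ~ %s: %s", response, predictor, exc)
            continue
        winner = comparative.model_select(candidates)
        fits[(response, predictor)] = candidates
        best[(response, predictor)] = winner
        for fit in candidates:
            rows.append(
                {
                    "family": family,
                    "response": response,
                    "predictor": predictor,
                    "model": fit.model_label,
                    "n": fit.n,
                    "coefficient": fit.slope,
                    "se": float(fit.bse.iloc[1]),
                    "r2": fit.r2,
                    "p": fit.p_slope,
                    "loglik": fit.loglik,
                    "aicc": fit.aicc,
                    "transform": fit.transform_value if fit.transform_value is not None else 1.0,
                    "selected": fit is winner,
                }
            )
    results = pd.DataFrame(rows)
    if len(results):
        results["q"] = np.nan
        sel = results[results["selected"]]
        for family, grp in sel.groupby("family"):
            results.loc[grp.index, "q"] = comparative.fdr_bh(grp["p"].to_numpy())
        for (response, predictor), fit in best.items():
            mask = (
                (results["response"] == response)
                & (results["predictor"] == predictor)
                & results["selected"]
            )
            fit.qvalue = float(results.loc[mask, "q"].iloc[0])
    results.attrs["skipped"] = skipped
    return ComparativeRun(results=results, fits=fits, best=best)


@dataclass
class PathRun:
    rankings: dict[str, list[pathcausal.PathModelFit]]  # evo model -> ranked fits
    averaged: dict[str, pathcausal.AveragedPaths]
    ranking_table: pd.DataFrame
    averaged_table: pd.DataFrame


def run_path_analysis(
    config: RunConfig,
    trait_table: TraitTable,
    tree: PhyloTree,
    variables: dict[str, str] | None = None,
    dags: list[pathcausal.CausalDAG] | None = None,
) -> PathRun:
    """Rank candidate DAGs by CICc under both evolutionary models and average.

    ``variables`` maps DAG node names to trait-table columns; the default
    uses the focal taxon's tissue relative abundance, disease prevalence,
    and growth. ``dags`` defaults to all 25 DAGs on the three nodes.
    """
    focal = config.focal_taxon.lower()
    variables = variables or {
        config.focal_taxon: f"{focal}_ra_tissue",
        "disease": "disease_prevalence",
        "growth": "growth_mm_yr",
    }
    nodes = tuple(variables)
    data = trait_table.table[[variables[n] for n in nodes]].copy()
    data.columns = list(nodes)
    dags = dags if dags is not None else pathcausal.all_dags(nodes)

    rankings, averaged, rank_rows, avg_rows = {}, {}, [], []
    for evo in config.path_evo_models:
        fits = pathcausal.rank_models(dags, data, tree, evo_model=evo)
        rankings[evo] = fits
        averaged[evo] = pathcausal.average_models(fits, cutoff=config.delta_cicc_cutoff)
        for rank, f in enumerate(fits, start=1):
            rank_rows.append(
                {
                    "evo_model": evo,
                    "rank": rank,
                    "dag": f.dag.label(),
                    "edges": ", ".join(f"{u}->{v}" for u, v in f.dag.edges) or "-",
                    "k_claims": len(f.claims),
                    "q": f.q,
                    "n": f.n,
                    "C": f.C,
                    "p": f.p,
                    "CICc": f.cicc,
                    "delta_CICc": f.delta_cicc,
                }
            )
        for (u, v), coef in sorted(averaged[evo].coefficients.items()):
            avg_rows.append(
                {
                    "evo_model": evo,
                    "edge": f"{u}->{v}",
                    "coefficient": coef,
                    "n_models": len(averaged[evo].contributing[(u, v)]),
                }
            )
    return PathRun(
        rankings=rankings,
        averaged=averaged,
        ranking_table=pd.DataFrame(rank_rows),
        averaged_table=pd.DataFrame(avg_rows),
    )


def run_all(
    bundle: MiniGcmpBundle,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> tuple[TraitTable, ComparativeRun, PathRun]:
    """Full pipeline on a synthetic bundle; optionally writes the result TSVs."""
    traits = build_trait_table(
        bundle.feature_tables, bundle.disease, bundle.growth_records, config
    )
    comp_run = run_comparative(config, traits, bundle.genus_tree)
    path_run = run_path_analysis(config, traits, bundle.genus_tree)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_trait_table(traits, out / "trait_table.tsv")
        comp_run.results.to_csv(out / "pgls_results.tsv", sep="\t", index=False, float_format="%.10g")
        path_run.ranking_table.to_csv(out / "path_ranking.tsv", sep="\t", index=False, float_format="%.10g")
        path_run.averaged_table.to_csv(out / "path_averaged.tsv", sep="\t", index=False, float_format="%.10g")
    return traits, comp_run, path_run
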