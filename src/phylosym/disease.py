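"""Genus-level disease susceptibility from multi-source colony surveys.

Surveys record, per source and host genus, how many colonies were healthy
and how many carried each disease. A colony with one or more diseases counts
once as diseased; counts are summed across sources within a genus, and
genera observed fewer than ``min_n`` times are excluded. The default
``min_n = 100`` is justified by a cumulative-binomial power argument: with
100 colonies the chance of seeing at least one case of a disease at 5% true
prevalence is 1 − 0.95¹⁰⁰ ≈ 0.994 > 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DiseaseRecords


@dataclass
class DiseaseSummary:
    """Aggregated counts for one genus: n observed, d diseased, prevalence d/n."""

    genus: str
    n: int
    d: int
    per_source: pd.DataFrame  # source, n, d
    per_disease: pd.Series  # disease column -> summed count

    @property
    def prevalence(self) -> float:
        return self.d / self.n


def _harmonize(genus: str) -> str:
    return str(genus).strip().casefold().capitalize()


def aggregate_disease(records: DiseaseRecords) -> dict[str, DiseaseSummary]:
    """Sum healthy/diseased colony counts within genera across sources.

    Genus names are harmonized (case-folded, whitespace-trimmed) before
    grouping. ``d`` counts each diseased colony once even when a source
    reports several disease categories — categories are assumed to partition
    the diseased colonies, so d = Σ per-disease counts and n = healthy + d.
    """
    df = records.table.copy()
    disease_cols = records.disease_columns
    df["genus"] = df["genus"].map(_harmonize)
    df["_d"] = df[disease_cols].sum(axis=1) if disease_cols else 0
    df["_n"] = df["healthy"] + df["_d"]
    out: dict[str, DiseaseSummary] = {}
    for genus, grp in df.groupby("genus"):
        per_source = (
            grp.groupby("source")[["_n", "_d"]].sum().rename(columns={"_n": "n", "_d": "d"})
        )
        out[genus] = DiseaseSummary(
            genus=genus,
            n=int(grp["_n"].sum()),
            d=int(grp["_d"].sum()),
            per_source=per_source,
            per_disease=grp[disease_cols].sum() if disease_cols else pd.Series(dtype=int),
        )
    return out


def detection_power(n: int, p: float) -> float:
    """P(at least one diseased colony among n), i.e. 1 − (1 − p)ⁿ.

    This is the cumulative-binomial argument behind the ≥100-colony filter.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence {p} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return float(1.0 - (1.0 - p) ** n)


@dataclass
class FilterReport:
    dropped: pd.DataFrame  # genus, n
    fraction_observations_retained: float


def filter_genera(
    summaries: dict[str, DiseaseSummary], min_n: int = 100
) -> tuple[dict[str, DiseaseSummary], FilterReport]:
    """Drop genera with fewer than ``min_n`` observed colonies (strict).

    Returns the retained summaries and a report listing dropped genera with
    their n and the fraction of total observations retained.
    """
    retained = {g: s for g, s in summaries.items() if s.n >= min_n}
    dropped = {g: s for g, s in summaries.items() if s.n < min_n}
    total = sum(s.n for s in summaries.values())
    kept = sum(s.n for s in retained.values())
    report = FilterReport(
        dropped=pd.DataFrame(
            {"genus": list(dropped), "n": [s.n for s in dropped.values()]}
        ).set_index("genus"),
        fraction_observations_retained=(kept / total) if total else float("nan"),
    )
    return retained, report


def prevalence_table(summaries: dict[str, DiseaseSummary], logit: bool = False) -> pd.DataFrame:
    """Genus-level (n, d, prevalence) frame; optional logit-transformed column.

    The logit uses the Haldane–Anscombe 0.5 correction so genera with d = 0
    or d = n stay finite.
    """
    df = pd.DataFrame(
        {
            "n": {g: s.n for g, s in summaries.items()},
            "d": {g: s.d for g, s in summaries.items()},
        }
    )
    df["prevalence"] = df["d"] / df["n"]
    if logit:
        adj = (df["d"] + 0.5) / (df["n"] + 1.0)
        df["prevalence_logit"] = np.log(adj / (1 - adj))
    df.index.name = "genus"
    return df.sort_index()
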