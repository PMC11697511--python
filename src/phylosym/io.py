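"""Tabular inputs: ASV feature tables, disease survey records, trait tables.

All formats are plain TSV. The feature-table dialect follows the common
BIOM-TSV convention: ASVs as rows, samples as columns, with an optional
``#OTU ID`` header cell. Taxonomy lineages are semicolon-delimited with a
fixed seven-rank depth (domain → species); missing ranks are kept as empty
strings so "unassigned below order" style checks stay explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
COMPARTMENTS = ("mucus", "tissue", "skeleton")
UNASSIGNED = ""


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage into exactly 7 ranks.

    Short lineages are right-padded with the unassigned marker; rank
    prefixes like ``g__`` are stripped.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    cleaned = []
    for p in parts[: len(RANKS)]:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        cleaned.append(p.strip())
    cleaned += [UNASSIGNED] * (len(RANKS) - len(cleaned))
    return tuple(cleaned)


@dataclass
class FeatureTable:
    """ASV × sample counts with per-sample metadata and per-ASV taxonomy.

    ``counts``: DataFrame, ASV ids × sample ids, nonnegative integers.
    ``metadata``: DataFrame indexed by sample id with columns
    ``host_genus`` and ``compartment`` (mucus/tissue/skeleton).
    ``taxonomy``: DataFrame indexed by ASV id with the 7 rank columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValueError(f"samples lacking metadata: {missing_meta}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        bad = set(self.metadata["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment value(s): {sorted(bad)}")
        missing_tax = [a for a in self.counts.index if a not in self.taxonomy.index]
        if missing_tax:
            # unknown ASVs get a fully unassigned lineage rather than failing
            pad = pd.DataFrame(
                [[UNASSIGNED] * len(RANKS)] * len(missing_tax),
                index=missing_tax,
                columns=list(RANKS),
            )
            self.taxonomy = pd.concat([self.taxonomy, pad])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1; empty samples NaN)."""
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.replace(0, np.nan), axis=1)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            self.counts[ids], self.metadata.loc[ids], self.taxonomy
        )

    def samples_in_group(self, host_genus: str, compartment: str | None = None) -> list[str]:
        m = self.metadata
        mask = m["host_genus"] == host_genus
        if compartment is not None:
            mask &= m["compartment"] == compartment
        return [s for s in m.index[mask] if s in self.counts.columns]

    def collapse_rank(self, rank: str = "genus") -> pd.DataFrame:
        """Sum counts over ASVs sharing the same taxon at ``rank``.

        Unassigned taxa collapse into the empty-string bucket. The index of
        the returned frame is the taxon name at that rank.
        """
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        labels = self.taxonomy.loc[self.counts.index, rank]
        return self.counts.groupby(labels.values).sum()


def load_feature_table(counts_path, metadata_path, taxonomy_path) -> FeatureTable:
    """Read the three TSV inputs and join them into a :class:`FeatureTable`."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment=None)
    counts.index.name = "asv_id"
    if counts.index.duplicated().any():
        dupes = sorted(counts.index[counts.index.duplicated()].unique())
        raise ValueError(f"duplicate ASV ids in counts: {dupes}")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in counts")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise ValueError("non-integer counts in feature table")
    counts = counts.astype(np.int64)

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    meta = meta.rename(columns=str.lower)

    tax_raw = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    lineage_col = tax_raw.columns[0]
    tax = pd.DataFrame(
        [parse_lineage(l) for l in tax_raw[lineage_col]],
        index=tax_raw.index,
        columns=list(RANKS),
    )
    return FeatureTable(counts, meta, tax)


def save_feature_table(table: FeatureTable, counts_path, metadata_path, taxonomy_path) -> None:
    c = table.counts.copy()
    c.index.name = "#OTU ID"
    c.to_csv(counts_path, sep="\t")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")
    lineages = table.taxonomy.apply(lambda r: ";".join(r), axis=1)
    pd.DataFrame({"lineage": lineages}).to_csv(taxonomy_path, sep="\t", index_label="asv_id")


# -- disease survey records -------------------------------------------


@dataclass
class DiseaseRecords:
    """Rows of (source, genus, healthy count, per-disease counts).

    ``table`` columns: ``source``, ``genus``, ``healthy``, then one column
    per disease category. A genus may appear under several sources; the rows
    are kept separate here and summed downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        count_cols = [c for c in self.table.columns if c not in ("source", "genus")]
        if (self.table[count_cols].to_numpy() < 0).any():
            raise ValueError("negative counts in disease records")
        if (self.table["genus"].astype(str).str.strip() == "").any():
            raise ValueError("empty genus name in disease records")

    @property
    def disease_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("source", "genus", "healthy")]


def load_disease_records(path) -> DiseaseRecords:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("source", "genus", "healthy"):
        if col not in df.columns:
            raise ValueError(f"disease records missing column {col!r}")
    count_cols = [c for c in df.columns if c not in ("source", "genus")]
    df[count_cols] = df[count_cols].astype(np.int64)
    return DiseaseRecords(df)


def save_disease_records(records: DiseaseRecords, path) -> None:
    records.table.to_csv(path, sep="\t", index=False)


# -- trait tables ------------------------------------------------------


@dataclass
class TraitTable:
    """Genus × continuous traits; missing values allowed (NaN)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValueError(f"duplicate genus rows: {dupes}")
        if self.table.columns.duplicated().any():
            raise ValueError("duplicate trait names")

    @property
    def genera(self) -> list[str]:
        return list(self.table.index)

    def trait(self, name: str) -> pd.Series:
        return self.table[name]

    def complete_cases(self, traits) -> pd.DataFrame:
        """Genera with no missing value in any of the named traits."""
        sub = self.table[list(traits)]
        return sub.dropna()


def load_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "genus"
    return TraitTable(df)


def save_trait_table(table: TraitTable, path) -> None:
    table.table.to_csv(path, sep="\t", index_label="genus", float_format="%.12g")
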