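import numpy as np
import pandas as pd
import pytest

import phylosym as ps


@pytest.fixture
def cherry():
    """Two-tip tree, both branches length 1."""
    return ps.parse_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2."""
    return ps.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def three_tip_traits():
    return pd.Series({"A": 2.0, "B": 4.0, "C": 1.0})


@pytest.fixture(scope="session")
def bundle():
    """One synthetic mini-study shared across pipeline tests."""
    return ps.make_mini_gcmp(seed=42)


@pytest.fixture(scope="session")
def bundle_traits(bundle):
    cfg = ps.RunConfig(compute_beta=False)
    return ps.build_trait_table(
        bundle.feature_tables, bundle.disease, bundle.growth_records, cfg
    )


@pytest.fixture
def toy_feature_table():
    """3 host genera x 2 compartments, 5 ASVs, hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "s1": [60, 20, 10, 10, 0],
            "s2": [10, 50, 20, 20, 0],
            "s3": [0, 0, 30, 30, 40],
            "s4": [5, 5, 45, 40, 5],
            "s5": [80, 0, 10, 10, 0],
            "s6": [0, 10, 40, 40, 10],
        },
        index=["asv1", "asv2", "asv3", "asv4", "asv5"],
    )
    meta = pd.DataFrame(
        {
            "host_genus": ["Acropora", "Acropora", "Porites", "Porites", "Acropora", "Porites"],
            "compartment": ["tissue", "tissue", "tissue", "tissue", "mucus", "mucus"],
        },
        index=list(counts.columns),
    )
    tax = pd.DataFrame(
        [
            ("Bacteria", "Proteobacteria", "Gamma", "Oceanospirillales", "Endozoicomonadaceae", "Endozoicomonas", ""),
            ("Bacteria", "Proteobacteria", "Gamma", "Oceanospirillales", "Endozoicomonadaceae", "Endozoicomonas", ""),
            ("Bacteria", "Proteobacteria", "Alpha", "Rhodobacterales", "Rhodobacteraceae", "Ruegeria", ""),
            ("Bacteria", "Bacteroidota", "Bacteroidia", "", "", "Unknowny", ""),
            ("Archaea", "Crenarchaeota", "Nitrososphaeria", "Nitrosopumilales", "Nitrosopumilaceae", "Nitrosopumilus", ""),
        ],
        index=list(counts.index),
        columns=list(ps.RANKS),
    )
    return ps.FeatureTable(counts, meta, tax)
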