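import numpy as np
import pandas as pd
import pytest

import azaleanet as az


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study conditions (one shared realization)."""
    return az.generate_all(az.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline(dataset):
    """The TO-GCN chain run once on the shared dataset."""
    m = az.filter_expressed(dataset.matrix)
    de = az.differential_genes(m)
    tfs = set(dataset.catalog.tf_ids) & de
    genes = de - tfs
    sub = m.subset(de)
    gcn = az.pearson_network(sub, tfs, genes)
    seed_tf = az.select_seed(sub, tfs)
    levels = az.assign_levels(gcn, seed_tf)
    report = az.map_levels_to_stages(levels, sub)
    return {
        "matrix": m,
        "sub": sub,
        "de": de,
        "gcn": gcn,
        "seed": seed_tf,
        "levels": levels,
        "report": report,
    }


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise realization for exact recovery checks."""
    return az.generate_all(az.SyntheticConfig(seed=13, noise_sd=0.0))


def make_catalog(genes):
    """Minimal catalog from (gene_id, chrom, rank) triples."""
    rows = [
        {
            "gene_id": g,
            "chrom": c,
            "start": r * 1000,
            "end": r * 1000 + 500,
            "strand": "+",
            "rank": r,
            "is_tf": False,
            "tf_family": "",
            "pathway_tag": "none",
        }
        for g, c, r in genes
    ]
    return az.GeneCatalog(pd.DataFrame(rows))


def simple_catalog(n_per_chrom, chroms=("chrA", "chrB")):
    triples = [
        (f"{c}_{r:03d}", c, r) for c in chroms for r in range(n_per_chrom)
    ]
    return make_catalog(triples)


def make_matrix(profiles: dict, n_reps: int = 5, tf_flags=()):
    """TimeCourseMatrix from gene -> per-stage TPM vectors (replicated)."""
    cols = None
    rows = {}
    for g, stage_vec in profiles.items():
        stage_vec = np.asarray(stage_vec, dtype=float)
        if cols is None:
            cols = [
                f"T{t}_R{r}"
                for t in range(1, len(stage_vec) + 1)
                for r in range(1, n_reps + 1)
            ]
        rows[g] = np.repeat(stage_vec, n_reps)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return az.TimeCourseMatrix(values, set(tf_flags))
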