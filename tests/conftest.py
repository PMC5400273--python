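from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hypoxiscore.datatypes import ClinicalTable, CtMatrix
from hypoxiscore.io import load_gene_panel
from hypoxiscore.quantify import (
    apply_detection_cutoff,
    compute_delta_ct,
    compute_rq,
    select_references,
)
from hypoxiscore.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return load_gene_panel()


@pytest.fixture(scope="session")
def cohort32():
    """One default synthetic cohort at the study's sample size."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def quantified32(cohort32):
    """Housekeeping-normalized dCt and RQ for the default cohort."""
    cohort, _ = cohort32
    ct = apply_detection_cutoff(cohort.ct)
    refs = select_references("housekeeping", available_genes=ct.genes)
    dct = compute_delta_ct(ct, refs)
    rq = compute_rq(dct)
    return dct, rq


def make_clinical(n=8, times=None, events=None, seed=0, **overrides) -> ClinicalTable:
    """Small hand-rolled clinical table for unit tests."""
    rng = np.random.default_rng(seed)
    idx = [f"P{i:02d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "age_group": rng.choice(["<50", ">=50"], n),
            "er": "pos",
            "pr": "pos",
            "nodes": rng.choice(["neg", "pos"], n),
            "stage": rng.choice([1, 2], n),
            "grade_msbr": rng.choice([2, 4], n),
            "her2": rng.choice(["neg", "pos"], n),
            "relapse": events if events is not None else rng.integers(0, 2, n),
            "rfs_months": times if times is not None else rng.uniform(5, 120, n),
        },
        index=pd.Index(idx, name="sample_id"),
    )
    for k, v in overrides.items():
        df[k] = v
    return ClinicalTable(df)


def make_ct(values, genes=None, samples=None) -> CtMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"P{i:02d}" for i in range(values.shape[1])]
    return CtMatrix(pd.DataFrame(values, index=genes, columns=samples))
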