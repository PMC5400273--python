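"""Unsupervised hierarchical clustering of patients on dCt profiles.

Patients are clustered with Ward's minimum-variance method (the barycenter
formulation, i.e. Ward on Euclidean distances) on raw dCt values; the
resulting partition is then tested against relapse occurrence with a
Pearson chi-square on the cluster x relapse contingency table.  A
median-centered, sign-flipped matrix is provided for heatmap display
(positive = expression above the gene's median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .datatypes import ClinicalTable
from .quantify import DeltaCtMatrix

__all__ = [
    "ClusterResult",
    "Chi2Result",
    "hierarchical_cluster",
    "median_center",
    "cluster_relapse_association",
]


@dataclass
class ClusterResult:
    """Ward linkage over patients with a cut at k clusters."""

    linkage: np.ndarray
    labels: pd.Series  # sample id -> cluster 1..k
    k: int
    gene_linkage: np.ndarray | None = None
    display: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes_used: list[str] = field(default_factory=list)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class Chi2Result:
    """Pearson chi-square of a cluster x relapse contingency table."""

    table: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    relapse_proportion: pd.Series
    expected: np.ndarray
    min_expected: float
    small_expected_warning: bool
    fisher_p_extra: float | None = None


def _impute_row_means(values: pd.DataFrame) -> pd.DataFrame:
    if values.isna().any().any():
        warnings.warn(
            "masked dCt cells mean-imputed per gene before clustering",
            stacklevel=3,
        )
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
        if values.isna().any().any():
            raise ValueError("a gene has no observed value in any sample")
    return values


def hierarchical_cluster(
    dct: DeltaCtMatrix,
    genes: list[str] | None = None,
    k: int = 2,
    z_score: bool = False,
    gene_tree: bool = True,
) -> ClusterResult:
    """Ward/Euclidean clustering of patients on their dCt profiles.

    Distances are Euclidean between patient profiles over ``genes`` (default
    all genes of the matrix); linkage is Ward, cut into ``k`` clusters.
    Genes are left on the raw dCt scale unless ``z_score`` standardizes each
    gene first.  Masked cells are mean-imputed per gene with a warning.
    """
    values = dct.values if genes is None else dct.values.loc[genes]
    values = _impute_row_means(values.astype(float))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > values.shape[1]:
        raise ValueError(f"k={k} exceeds the {values.shape[1]} samples")
    if z_score:
        sd = values.std(axis=1, ddof=1).replace(0.0, 1.0)
        values = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    x = values.to_numpy().T  # samples x genes
    linkage = hierarchy.linkage(x, method="ward")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=values.columns, name="cluster")
    gene_linkage = (
        hierarchy.linkage(values.to_numpy(), method="ward") if gene_tree else None
    )
    return ClusterResult(
        linkage=linkage,
        labels=labels,
        k=k,
        gene_linkage=gene_linkage,
        display=median_center(DeltaCtMatrix(values, dct.strategy, dct.reference_genes)),
        genes_used=list(values.index),
    )


def median_center(dct: DeltaCtMatrix) -> pd.DataFrame:
    """Display matrix: per-gene median-centered dCt with the sign flipped.

    Lower dCt means higher expression, so the flip makes above-median
    expression positive ("red") and below-median negative ("green").  Every
    gene row of the output has median 0.
    """
    values = dct.values.astype(float)
    return -(values.sub(values.median(axis=1, skipna=True), axis=0))


def cluster_relapse_association(
    labels: pd.Series,
    clinical: ClinicalTable,
    merge: dict[int, list[int]] | None = None,
) -> Chi2Result:
    """Pearson chi-square of cluster membership against relapse.

    ``merge`` optionally pools clusters before testing, e.g.
    ``{1: [1], 2: [2, 3]}`` compares cluster 1 against clusters 2+3
    collapsed.  Empty clusters are dropped with a warning.  No continuity
    correction is applied; a Fisher exact p is attached for 2x2 tables as a
    supplementary readout.
    """
    labels = labels.copy()
    if merge is not None:
        remap = {old: new for new, olds in merge.items() for old in olds}
        labels = labels.map(remap)
        if labels.isna().any():
            raise ValueError("merge spec does not cover all cluster labels")
    events = clinical.data.loc[labels.index, "relapse"]
    table = pd.crosstab(labels, events)
    table = table.reindex(columns=[0, 1], fill_value=0)
    nonempty = table.sum(axis=1) > 0
    if not nonempty.all():
        warnings.warn("dropping empty clusters from contingency table", stacklevel=2)
        table = table.loc[nonempty]
    if table.shape[0] < 2:
        raise ValueError("need >= 2 non-empty clusters for the chi-square test")
    obs = table.to_numpy(dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    min_exp = float(expected.min())
    small = min_exp < 5.0
    if small:
        warnings.warn(
            f"chi-square expected count as low as {min_exp:.2f}; "
            "consider the Fisher exact extra",
            stacklevel=2,
        )
    fisher = None
    if obs.shape == (2, 2):
        fisher = float(stats.fisher_exact(obs.astype(int)).pvalue)
    prop = table[1] / table.sum(axis=1)
    return Chi2Result(
        table=table,
        statistic=float(chi2),
        df=int(dof),
        p_value=float(p),
        relapse_proportion=prop.rename("relapse_proportion"),
        expected=expected,
        min_expected=min_exp,
        small_expected_warning=small,
        fisher_p_extra=fisher,
    )
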