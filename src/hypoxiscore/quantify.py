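"""Relative quantification of qPCR Ct values by the comparative ddCt method.

Pipeline: apply the detection cutoff (Ct >= 35 cycles is treated as
non-expressed), choose reference genes (the two endogenous controls, the
most stable genes of a model-based stability ranking, or the per-sample
global mean of all measured genes), subtract the per-sample reference mean
to get dCt, center each gene on a calibrator to get ddCt, and exponentiate:
RQ = 2**(-ddCt).

RQ is dimensionless relative expression; with the default cohort-mean
calibrator it is fold expression versus the cohort average, and the
geometric mean of each gene's RQ over samples is 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CtMatrix

__all__ = [
    "GLOBAL_MEAN",
    "DEFAULT_CT_CUTOFF",
    "DeltaCtMatrix",
    "ExpressionMatrix",
    "StabilityRanking",
    "ReferenceSet",
    "apply_detection_cutoff",
    "missingness_report",
    "stability_ranking",
    "select_references",
    "compute_delta_ct",
    "compute_rq",
]

#: Sentinel: normalize against the per-sample mean Ct of all measured genes.
GLOBAL_MEAN = "__global_mean__"

#: Detection cutoff in cycles; a Ct at or above this is called non-expressed.
DEFAULT_CT_CUTOFF = 35.0

#: The two endogenous-control assays preloaded on the array.
HOUSEKEEPING_GENES = ("RPL32", "18S")


@dataclass
class DeltaCtMatrix:
    """Reference-normalized cycle values (dCt), genes x samples."""

    values: pd.DataFrame
    strategy: str
    reference_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Relative quantification (RQ = 2**-ddCt), genes x samples, with its
    companion ddCt matrix and a record of the calibrator used."""

    values: pd.DataFrame
    calibrator: str
    ddct: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StabilityRanking:
    """Per-gene expression-stability values (lower = more stable).

    ``table`` columns: ``stability`` plus its ``intra_group`` (sampling
    noise) and ``inter_group`` (shrunken group bias) components.  Ordering is
    by stability with the gene symbol as deterministic tie-break.
    """

    table: pd.DataFrame
    grouped: bool

    @property
    def ordered_genes(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return self.ordered_genes[:k]


@dataclass(frozen=True)
class ReferenceSet:
    """The normalizer: either an explicit gene set or the global-mean sentinel."""

    strategy: str
    genes: tuple[str, ...] = ()

    @property
    def is_global_mean(self) -> bool:
        return self.strategy == "global_mean"


def apply_detection_cutoff(
    ct: CtMatrix, cutoff: float = DEFAULT_CT_CUTOFF, inclusive: bool = True
) -> CtMatrix:
    """Mask wells at or beyond the detection cutoff as non-expressed.

    The boundary is inclusive by default (Ct == cutoff is non-expressed);
    pass ``inclusive=False`` to keep the boundary value.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    values = ct.values.copy()
    beyond = values >= cutoff if inclusive else values > cutoff
    values[beyond] = np.nan
    return CtMatrix(values)


def missingness_report(ct: CtMatrix) -> pd.DataFrame:
    """Per-gene count/fraction of masked wells, flagging fully masked genes."""
    miss = ct.mask
    return pd.DataFrame(
        {
            "n_missing": miss.sum(axis=1).astype(int),
            "fraction_missing": miss.mean(axis=1),
            "all_missing": miss.all(axis=1),
        }
    )


def _center_columns(values: pd.DataFrame) -> pd.DataFrame:
    # Remove per-sample level (e.g. cDNA input) so only gene-wise variation remains.
    return values - values.mean(axis=0, skipna=True)


def stability_ranking(
    values: pd.DataFrame | CtMatrix | DeltaCtMatrix,
    groups: pd.Series | None = None,
) -> StabilityRanking:
    """Model-based reference-gene stability ranking.

    Works on log-scale expression (raw Ct or dCt; any per-sample additive
    level is removed by column centering first).  Without groups the
    stability value is simply each gene's standard deviation of centered
    values.  With a group label per sample, the centered values are
    decomposed per gene into an inter-group bias (the deviation of the group
    mean from the gene's overall mean, shrunken toward zero in proportion to
    its sampling uncertainty) and an intra-group sampling term; the stability
    value adds the absolute shrunken bias and the residual sampling standard
    error, averaged over groups.  Lower values rank first.
    """
    if isinstance(values, (CtMatrix, DeltaCtMatrix)):
        values = values.values
    if values.shape[1] < 2:
        raise ValueError("stability ranking needs at least 2 samples")
    z = _center_columns(values.astype(float))

    if groups is None:
        sd = z.std(axis=1, ddof=1, skipna=True)
        table = pd.DataFrame(
            {"stability": sd, "intra_group": sd, "inter_group": 0.0}
        )
    else:
        groups = pd.Series(groups).reindex(values.columns)
        labels = groups.dropna().unique()
        if len(labels) < 2:
            raise ValueError("grouped stability ranking needs >= 2 groups")
        per_group = {}
        for lab in labels:
            cols = groups.index[groups == lab]
            if len(cols) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")
            sub = z[cols]
            per_group[lab] = {
                "mean": sub.mean(axis=1, skipna=True),
                "var": sub.var(axis=1, ddof=1, skipna=True),
                "n": sub.notna().sum(axis=1).clip(lower=1),
            }
        grand = pd.concat([g["mean"] for g in per_group.values()], axis=1).mean(axis=1)
        stab_parts, intra_parts, inter_parts = [], [], []
        for g in per_group.values():
            d = g["mean"] - grand            # raw inter-group bias per gene
            u = g["var"] / g["n"]            # sampling variance of that bias
            gamma2 = max(float(d.var(ddof=1) - u.mean()), 0.0)
            shrink = gamma2 / (gamma2 + u) if gamma2 > 0 else 0.0 * u
            d_shrunk = d * shrink
            post_sd = np.sqrt(u * shrink) if gamma2 > 0 else np.sqrt(u)
            stab_parts.append(d_shrunk.abs() + post_sd)
            intra_parts.append(np.sqrt(u))
            inter_parts.append(d_shrunk.abs())
        table = pd.DataFrame(
            {
                "stability": pd.concat(stab_parts, axis=1).mean(axis=1),
                "intra_group": pd.concat(intra_parts, axis=1).mean(axis=1),
                "inter_group": pd.concat(inter_parts, axis=1).mean(axis=1),
            }
        )
    # sort by stability with the gene symbol as deterministic tie-break
    table = table.iloc[
        np.lexsort((table.index.to_numpy(), table["stability"].to_numpy()))
    ]
    return StabilityRanking(table=table, grouped=groups is not None)


def select_references(
    strategy: str,
    ranking: StabilityRanking | None = None,
    available_genes: list[str] | None = None,
    k: int = 2,
) -> ReferenceSet:
    """Choose the normalizer.

    ``housekeeping`` -> the two endogenous controls (RPL32, 18S);
    ``stability_top_k`` -> the k most stable genes of ``ranking``;
    ``global_mean`` -> per-sample mean Ct of all measured genes.
    """
    if strategy == "housekeeping":
        if available_genes is not None:
            absent = [g for g in HOUSEKEEPING_GENES if g not in available_genes]
            if absent:
                raise ValueError(f"housekeeping genes absent from data: {absent}")
        return ReferenceSet(strategy="housekeeping", genes=HOUSEKEEPING_GENES)
    if strategy == "stability_top_k":
        if ranking is None:
            raise ValueError("stability_top_k requires a stability ranking")
        return ReferenceSet(strategy="stability_top_k", genes=tuple(ranking.top(k)))
    if strategy == "global_mean":
        return ReferenceSet(strategy="global_mean", genes=(GLOBAL_MEAN,))
    raise ValueError(f"unknown normalization strategy {strategy!r}")


def compute_delta_ct(ct: CtMatrix, refs: ReferenceSet) -> DeltaCtMatrix:
    """dCt(g, s) = Ct(g, s) - R(s), R(s) the arithmetic mean reference Ct.

    The detection cutoff should already have been applied.  For an explicit
    reference set, reference rows are consumed (dropped from the output).
    For the global-mean strategy R(s) averages every measured gene of the
    sample.  A sample whose reference genes are all masked yields a fully
    masked column, with a warning.
    """
    values = ct.values
    if refs.is_global_mean:
        r = values.mean(axis=0, skipna=True)
        targets = values
        consumed: tuple[str, ...] = ()
    else:
        absent = [g for g in refs.genes if g not in values.index]
        if absent:
            raise ValueError(f"reference genes absent from Ct matrix: {absent}")
        r = values.loc[list(refs.genes)].mean(axis=0, skipna=True)
        targets = values.drop(index=list(refs.genes))
        consumed = refs.genes
    dead = r.index[r.isna()].tolist()
    if dead:
        warnings.warn(
            f"samples with no usable reference Ct, columns masked: {dead}",
            stacklevel=2,
        )
    dct = targets.sub(r, axis=1)
    return DeltaCtMatrix(values=dct, strategy=refs.strategy, reference_genes=consumed)


def compute_rq(dct: DeltaCtMatrix, calibrator: str = "cohort_mean") -> ExpressionMatrix:
    """RQ = 2**-(ddCt) with ddCt = dCt - calibrator dCt.

    ``calibrator`` is either ``"cohort_mean"`` (per gene, the mean dCt over
    all samples — RQ then measures fold expression versus the cohort
    average) or a sample id whose dCt column becomes the calibrator (its RQ
    is 1 for every gene by construction).  Masked cells propagate.
    """
    values = dct.values
    if calibrator == "cohort_mean":
        c = values.mean(axis=1, skipna=True)
    else:
        if calibrator not in values.columns:
            raise ValueError(f"calibrator sample {calibrator!r} not in dCt matrix")
        c = values[calibrator]
    ddct = values.sub(c, axis=0)
    rq = np.power(2.0, -ddct)
    return ExpressionMatrix(values=rq, calibrator=str(calibrator), ddct=ddct)
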