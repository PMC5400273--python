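"""Core data containers for a qPCR expression cohort.

A cohort couples three pieces of data: the gene panel measured on the
low-density array (target genes plus endogenous-control genes), the raw
threshold-cycle (Ct) matrix, and the per-patient clinical annotation with
relapse follow-up.  Everything downstream — normalization, group comparison,
clustering, the relapse risk score — consumes these containers.

Conventions
-----------
* Ct matrices are genes x samples ``DataFrame``s of float64.  ``NaN`` marks a
  well the instrument reported as undetermined.  A numeric Ct above the
  detection cutoff is *not* masked here; the cutoff is applied explicitly by
  the quantification stage so that raw data stay lossless.
* Clinical categories use fixed vocabularies (see module constants); times
  are months stored as floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelEntry",
    "GenePanel",
    "CtMatrix",
    "ClinicalTable",
    "CohortDataset",
    "CLINICAL_COLUMNS",
    "AGE_GROUPS",
    "BINARY_STATUS",
    "GROUPINGS",
]

#: Canonical clinical CSV column order.
CLINICAL_COLUMNS = (
    "sample_id",
    "age_group",
    "er",
    "pr",
    "nodes",
    "stage",
    "grade_msbr",
    "her2",
    "relapse",
    "rfs_months",
)

AGE_GROUPS = ("<50", ">=50")
BINARY_STATUS = ("neg", "pos")

#: Supported dichotomous groupings -> (case description, control description).
#: ``case`` is the clinically adverse level; fold inductions are case/control.
GROUPINGS = {
    "stage": ("stage 2-3", "stage 1"),
    "grade": ("mSBR grade 4-5", "mSBR grade 1-3"),
    "her2": ("HER2 positive", "HER2 negative"),
    "relapse": ("recurrent", "non-recurrent"),
    "nodes": ("node positive", "node negative"),
}


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


@dataclass(frozen=True)
class PanelEntry:
    """One assay of the expression panel."""

    symbol: str
    assay_id: str
    category: str
    is_reference: bool


@dataclass(frozen=True)
class GenePanel:
    """The measured gene panel: target genes plus endogenous controls."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        dupes = {s for s in symbols if symbols.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate gene symbols in panel: {sorted(dupes)}")
        if not any(not e.is_reference for e in self.entries):
            raise ValidationError("panel needs at least one non-reference gene")

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    @property
    def reference_genes(self) -> list[str]:
        return [e.symbol for e in self.entries if e.is_reference]

    @property
    def target_genes(self) -> list[str]:
        return [e.symbol for e in self.entries if not e.is_reference]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.symbol, e.assay_id, e.category, int(e.is_reference))
                for e in self.entries
            ],
            columns=["gene_symbol", "assay_id", "category", "is_reference"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenePanel":
        entries = tuple(
            PanelEntry(
                symbol=str(r.gene_symbol),
                assay_id=str(r.assay_id),
                category=str(r.category),
                is_reference=bool(int(r.is_reference)),
            )
            for r in frame.itertuples()
        )
        return cls(entries)


@dataclass
class CtMatrix:
    """Raw threshold-cycle values, genes x samples.

    ``values`` is float64 with ``NaN`` marking undetermined wells.  Observed
    cycle values must be positive (a Ct of 0 or below has no physical
    meaning on a real-time instrument).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = v.to_numpy(dtype=float, copy=False)
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValidationError("all numeric Ct values must be > 0")
        self.values = v.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the well is undetermined."""
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "CtMatrix":
        return CtMatrix(self.values.loc[:, list(samples)].copy())

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy())

    def equals(self, other: "CtMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates and relapse follow-up.

    ``data`` is indexed by sample id and carries the columns of
    :data:`CLINICAL_COLUMNS` (minus ``sample_id``).  ``relapse`` is the event
    indicator of relapse-free survival (local or distant recurrence);
    ``rfs_months`` is time from diagnosis to recurrence or censoring.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        required = [c for c in CLINICAL_COLUMNS if c != "sample_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing mandatory clinical columns: {missing}")

        def check_vocab(col: str, vocab: Iterable) -> None:
            bad = sorted(set(df[col].unique()) - set(vocab))
            if bad:
                raise ValidationError(f"unknown {col!r} tokens: {bad}")

        check_vocab("age_group", AGE_GROUPS)
        for col in ("er", "pr", "nodes", "her2"):
            check_vocab(col, BINARY_STATUS)
        check_vocab("stage", (1, 2, 3))
        check_vocab("grade_msbr", (1, 2, 3, 4, 5))
        check_vocab("relapse", (0, 1))
        if (df["rfs_months"].to_numpy(dtype=float) <= 0).any():
            bad = df.index[df["rfs_months"] <= 0].tolist()
            raise ValidationError(f"rfs_months must be > 0; offending samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        """Relapse-free survival times in months."""
        return self.data["rfs_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        """Relapse event indicators (1 = recurrence observed)."""
        return self.data["relapse"].to_numpy(dtype=int)

    def dichotomy(self, grouping: str) -> pd.Series:
        """Boolean case indicator for one of the study dichotomies.

        True marks the case (adverse) level: stage 2-3, mSBR grade 4-5,
        HER2 positive, relapsed, or node positive.
        """
        if grouping not in GROUPINGS:
            raise KeyError(
                f"unknown grouping {grouping!r}; choose from {sorted(GROUPINGS)}"
            )
        df = self.data
        if grouping == "stage":
            return df["stage"] >= 2
        if grouping == "grade":
            return df["grade_msbr"] >= 4
        if grouping == "her2":
            return df["her2"] == "pos"
        if grouping == "relapse":
            return df["relapse"] == 1
        return df["nodes"] == "pos"

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from clinical table: {missing}")
        return ClinicalTable(self.data.loc[list(samples)].copy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CohortDataset:
    """A validated, sample-aligned bundle of panel, Ct matrix and clinical table."""

    panel: GenePanel
    ct: CtMatrix
    clinical: ClinicalTable
    missingness: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_samples(self) -> int:
        return self.ct.n_samples

    @property
    def samples(self) -> list[str]:
        return self.ct.samples


def assemble_cohort(
    ct: CtMatrix, clinical: ClinicalTable, panel: GenePanel
) -> CohortDataset:
    """Cross-check ids and align a Ct matrix with its clinical annotation.

    Samples are ordered as in the Ct matrix; clinical rows not measured on
    the array are dropped with a warning.  A Ct sample without a clinical row
    is an error (survival analysis would silently lose patients otherwise).
    Per-gene missingness of the raw matrix is recorded on the dataset.
    """
    unknown_genes = [g for g in ct.genes if g not in panel]
    if unknown_genes:
        raise ValidationError(f"Ct genes absent from panel: {unknown_genes}")
    orphan = [s for s in ct.samples if s not in clinical.data.index]
    if orphan:
        raise ValidationError(f"Ct samples absent from clinical table: {orphan}")
    extra = [s for s in clinical.sample_ids if s not in set(ct.samples)]
    if extra:
        warnings.warn(
            f"dropping {len(extra)} clinical rows without Ct data: {extra}",
            stacklevel=2,
        )
    aligned = clinical.subset(ct.samples)
    miss = ct.mask
    report = pd.DataFrame(
        {
            "n_missing": miss.sum(axis=1).astype(int),
            "fraction_missing": miss.mean(axis=1),
            "all_missing": miss.all(axis=1),
        }
    )
    return CohortDataset(panel=panel, ct=ct, clinical=aligned, missingness=report)
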