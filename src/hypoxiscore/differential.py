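"""Group-wise fold-induction profiles and per-gene significance tests.

For each gene the ratio of mean RQ between a case group and a control group
is turned into a signed fold induction: +1 means 2-fold up-regulation in
cases, -1 means 2-fold down-regulation.  Significance uses Welch's t-test on
the dCt (log) scale when per-group normality is not rejected, otherwise the
Kruskal-Wallis rank test on RQ; both p-values are always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, GROUPINGS
from .quantify import DeltaCtMatrix, ExpressionMatrix

__all__ = ["GroupComparison", "signed_fold", "compare_groups"]

#: Shapiro-Wilk gate for choosing the t-test branch.
NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Per-gene case-versus-control comparison for one clinical dichotomy.

    ``table`` (ordered by fold induction, ascending) carries per gene the
    group mean RQs, ratio, signed fold, both test p-values, the chosen test
    and a Benjamini-Hochberg column (an extra aid; the primary readout is
    the raw p-value).  ``mean_overexpression_pct`` is 100 x mean(ratio - 1)
    over genes; ``mean_fold`` averages the signed folds instead.
    """

    grouping: str
    case_label: str
    control_label: str
    case_samples: list[str]
    control_samples: list[str]
    table: pd.DataFrame
    mean_overexpression_pct: float
    mean_fold: float


def signed_fold(r):
    """Signed fold induction of a positive expression ratio.

    f(r) = r - 1 for r >= 1 and -(1/r - 1) otherwise, so a ratio of 2 maps
    to +1 (2-fold up) and a ratio of 0.5 to -1 (2-fold down);
    f(r) = -f(1/r) for every r > 0.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("ratio must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arr >= 1, arr - 1.0, -(1.0 / arr - 1.0))
    return out if out.ndim else float(out)


def _normal_ok(x: np.ndarray) -> bool:
    if x.size < 3:
        return False
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= NORMALITY_ALPHA


def _kruskal_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all tied: no evidence against the null
        return 1.0
    return float(stats.kruskal(a, b).pvalue)


def compare_groups(
    rq: ExpressionMatrix,
    dct: DeltaCtMatrix,
    clinical: ClinicalTable,
    grouping: str,
) -> GroupComparison:
    """Fold inductions and per-gene tests between a clinical dichotomy.

    ``grouping`` is one of ``stage`` (2-3 vs 1), ``grade`` (mSBR 4-5 vs
    1-3), ``her2`` (+ vs -), ``relapse`` (recurrent vs non-recurrent) or
    ``nodes``.  Masked cells are excluded pairwise.  With a group of fewer
    than 2 patients, tests are skipped (NaN p) but folds are still reported.
    """
    case = clinical.dichotomy(grouping)
    case_ids = [s for s in rq.samples if case.get(s, False)]
    ctrl_ids = [s for s in rq.samples if s in case.index and not case[s]]
    if not case_ids or not ctrl_ids:
        raise ValueError(f"grouping {grouping!r} leaves an empty group")
    small = min(len(case_ids), len(ctrl_ids)) < 2
    if small:
        warnings.warn(
            f"grouping {grouping!r}: a group has < 2 patients; tests skipped",
            stacklevel=2,
        )

    rows = []
    for gene in rq.genes:
        rq_case = rq.values.loc[gene, case_ids].dropna().to_numpy(dtype=float)
        rq_ctrl = rq.values.loc[gene, ctrl_ids].dropna().to_numpy(dtype=float)
        d_case = dct.values.loc[gene, case_ids].dropna().to_numpy(dtype=float)
        d_ctrl = dct.values.loc[gene, ctrl_ids].dropna().to_numpy(dtype=float)
        m_case = rq_case.mean() if rq_case.size else np.nan
        m_ctrl = rq_ctrl.mean() if rq_ctrl.size else np.nan
        ratio = m_case / m_ctrl if m_ctrl and not np.isnan(m_ctrl) else np.nan
        fold = signed_fold(ratio) if ratio > 0 else np.nan
        p_t = p_kw = np.nan
        test = "none"
        if not small and min(d_case.size, d_ctrl.size) >= 2:
            if np.ptp(np.concatenate([d_case, d_ctrl])) == 0:
                p_t, p_kw, test = 1.0, 1.0, "kruskal"
            else:
                p_t = float(
                    stats.ttest_ind(d_case, d_ctrl, equal_var=False).pvalue
                )
                p_kw = _kruskal_p(rq_case, rq_ctrl)
                test = "t" if (_normal_ok(d_case) and _normal_ok(d_ctrl)) else "kruskal"
        p = p_t if test == "t" else p_kw
        rows.append(
            {
                "gene": gene,
                "n_case": int(rq_case.size),
                "n_control": int(rq_ctrl.size),
                "mean_rq_case": m_case,
                "mean_rq_control": m_ctrl,
                "ratio": ratio,
                "fold": fold,
                "p_t_welch_dct": p_t,
                "p_kruskal_rq": p_kw,
                "test": test,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    finite = table["p"].notna()
    bh = pd.Series(np.nan, index=table.index, name="p_bh_extra")
    if finite.any():
        bh.loc[finite] = stats.false_discovery_control(
            table.loc[finite, "p"].to_numpy(), method="bh"
        )
    table["p_bh_extra"] = bh
    table = table.sort_values("fold", kind="mergesort")
    ratios = table["ratio"].dropna()
    folds = table["fold"].dropna()
    case_label, control_label = GROUPINGS[grouping]
    return GroupComparison(
        grouping=grouping,
        case_label=case_label,
        control_label=control_label,
        case_samples=case_ids,
        control_samples=ctrl_ids,
        table=table,
        mean_overexpression_pct=float(100.0 * (ratios - 1.0).mean()),
        mean_fold=float(folds.mean()),
    )
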