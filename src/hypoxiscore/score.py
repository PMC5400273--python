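"""Relapse risk score: signature selection, survival-optimized cut-points,
indicator-sum scoring and risk-group evaluation.

The procedure:

1. keep the genes significantly overexpressed in recurrent patients
   (p < alpha and positive fold induction);
2. for each kept gene, search every midpoint between consecutive distinct
   RQ values for the threshold that maximizes the two-group log-rank
   statistic of relapse-free survival (subject to a minimum group-size
   fraction on both sides);
3. score each patient by counting the genes whose RQ strictly exceeds its
   threshold;
4. choose the score cut s* (low risk = score <= s*) that again maximizes
   the log-rank statistic, and evaluate the two risk groups (Kaplan-Meier
   curves, 5-/10-year cumulative incidence, O/E hazard ratio).

The in-sample p-values of steps 2 and 4 are optimistic: the same data chose
the thresholds.  They are reported as such; a permutation-corrected p for
the final grouping is available as a supplementary readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable
from .differential import GroupComparison
from .io import published_score_thresholds
from .quantify import ExpressionMatrix
from .survival import (
    LogRankResult,
    SurvivalCurve,
    km_estimate,
    logrank_profile,
    logrank_test,
    survival_at,
)

__all__ = [
    "SignatureEmptyError",
    "CutpointResult",
    "ThresholdTable",
    "ScoreThresholdResult",
    "RiskScoreResult",
    "select_signature",
    "optimal_cutpoint",
    "build_threshold_table",
    "compute_scores",
    "select_score_threshold",
    "evaluate_risk_groups",
    "cronbach_alpha",
    "permutation_p_extra",
]

#: Tolerance within which two log-rank statistics count as tied during the
#: cut-point searches (documented tie-breaking then applies).
TIE_TOL = 1e-9


class SignatureEmptyError(ValueError):
    """No gene passed the selection filter; consider relaxing alpha."""


@dataclass(frozen=True)
class CutpointResult:
    """Optimum expression threshold for one gene."""

    threshold: float
    statistic: float
    n_candidates: int
    min_frac: float


@dataclass
class ThresholdTable:
    """Per-gene optimum RQ thresholds of the signature.

    ``table`` columns: ``threshold``, ``statistic`` (log-rank at the
    optimum; NaN in published mode), ``n_candidates``, ``min_frac``.
    ``mode`` is ``"search"`` or ``"published"``.
    """

    table: pd.DataFrame
    mode: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def thresholds(self) -> pd.Series:
        return self.table["threshold"]


@dataclass
class ScoreThresholdResult:
    """Chosen score cut s* and the full per-candidate log-rank profile."""

    s_star: int
    profile: pd.DataFrame  # index s, columns statistic, n_low, n_high


@dataclass
class RiskScoreResult:
    """Risk-group evaluation at a fixed score cut."""

    s_star: int
    groups: pd.Series  # sample id -> "low" | "high"
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    curve_low: SurvivalCurve
    curve_high: SurvivalCurve
    logrank: LogRankResult
    incidence_low: dict[int, float]
    incidence_high: dict[int, float]
    hazard_ratio: float
    hazard_ratio_degenerate: bool
    cronbach_alpha: float | None = None
    scores: pd.Series = field(default_factory=pd.Series)


def select_signature(comparison: GroupComparison, alpha: float = 0.05) -> list[str]:
    """Genes significantly overexpressed in the recurrent group.

    Keeps genes with p < alpha and a positive fold induction (higher mean RQ
    in relapsed patients).  Raises :class:`SignatureEmptyError` when nothing
    passes, advising a relaxed alpha.
    """
    if comparison.grouping != "relapse":
        raise ValueError("signature selection needs the relapse-group comparison")
    t = comparison.table
    keep = t.index[(t["p"] < alpha) & (t["fold"] > 0)].tolist()
    if not keep:
        raise SignatureEmptyError(
            f"no gene reached p < {alpha} with positive fold; relax alpha"
        )
    return keep


def _candidate_midpoints(values: np.ndarray, min_frac: float):
    """Admissible thresholds: midpoints of consecutive sorted distinct values
    leaving at least ceil(min_frac * n) patients on each side."""
    n = values.size
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("all expression values equal: no cut exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = int(np.ceil(min_frac * n))
    n_high = np.array([(values > m).sum() for m in mids])
    ok = (n_high >= min_n) & ((n - n_high) >= min_n)
    return mids[ok], n_high[ok], distinct.size - 1


def optimal_cutpoint(
    values, times, events, min_frac: float = 0.1
) -> CutpointResult:
    """Exhaustive survival cut-point search for one gene.

    Candidates are the midpoints between consecutive sorted distinct RQ
    values; patients with value > tau form the high group; the tau
    maximizing the log-rank statistic wins.  Ties (within ``TIE_TOL``) break
    toward the more balanced split, then the smaller tau.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.isnan(values).any():
        raise ValueError("masked expression values: drop or flag patients first")
    mids, n_high, n_total = _candidate_midpoints(values, min_frac)
    if mids.size == 0:
        raise ValueError(
            f"no admissible cut with min_frac={min_frac} on {values.size} patients"
        )
    membership = values[None, :] > mids[:, None]
    stat, _, _, _ = logrank_profile(times, events, membership)
    if np.all(np.isnan(stat)):
        raise ValueError("log-rank undefined for every candidate cut (no events?)")
    best = np.nanmax(stat)
    tied = np.flatnonzero(stat >= best - TIE_TOL)
    imbalance = np.abs(values.size - 2 * n_high[tied])
    order = np.lexsort((mids[tied], imbalance))
    pick = tied[order[0]]
    return CutpointResult(
        threshold=float(mids[pick]),
        statistic=float(stat[pick]),
        n_candidates=int(n_total),
        min_frac=float(min_frac),
    )


def build_threshold_table(
    rq: ExpressionMatrix,
    signature: list[str],
    clinical: ClinicalTable,
    mode: str = "search",
    min_frac: float = 0.1,
) -> ThresholdTable:
    """Per-gene optimum thresholds, searched or loaded from the published table.

    ``mode="search"`` runs :func:`optimal_cutpoint` per signature gene on the
    cohort, excluding masked wells pairwise per gene; ``mode="published"``
    loads the packaged six-gene threshold table instead (same schema, NaN
    search statistics).
    """
    if mode == "published":
        pub = published_score_thresholds()
        missing = [g for g in signature if g not in pub.index]
        if missing:
            raise ValueError(f"no published threshold for genes: {missing}")
        table = pd.DataFrame(
            {
                "threshold": pub.loc[signature],
                "statistic": np.nan,
                "n_candidates": 0,
                "min_frac": np.nan,
            }
        )
        return ThresholdTable(table=table, mode="published")
    if mode != "search":
        raise ValueError(f"unknown mode {mode!r}")
    absent = [g for g in signature if g not in rq.genes]
    if absent:
        raise ValueError(f"signature genes absent from RQ matrix: {absent}")
    times = clinical.times
    events = clinical.events
    samples = clinical.sample_ids
    rows = {}
    for gene in signature:
        vals = rq.values.loc[gene, samples].to_numpy(dtype=float)
        keep = ~np.isnan(vals)  # masked wells excluded pairwise per gene
        res = optimal_cutpoint(vals[keep], times[keep], events[keep], min_frac=min_frac)
        rows[gene] = {
            "threshold": res.threshold,
            "statistic": res.statistic,
            "n_candidates": res.n_candidates,
            "min_frac": res.min_frac,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[signature]
    return ThresholdTable(table=table, mode="search")


def compute_scores(rq: ExpressionMatrix, thresholds: ThresholdTable) -> pd.DataFrame:
    """Indicator-sum risk score per patient.

    A gene contributes 1 when its RQ is strictly above the gene's threshold
    (equality scores 0).  Returns a patients x (genes + score + complete)
    frame; patients with a masked signature gene keep a score over their
    observed genes but are flagged ``complete=False``.
    """
    genes = thresholds.genes
    sub = rq.values.loc[genes].T  # patients x genes
    indicators = sub.gt(thresholds.thresholds, axis=1).astype(int)
    complete = sub.notna().all(axis=1)
    indicators[sub.isna()] = 0
    out = indicators.copy()
    out["score"] = indicators.sum(axis=1)
    out["complete"] = complete
    return out


def select_score_threshold(scores, times, events) -> ScoreThresholdResult:
    """Choose the score cut s* maximizing relapse-free survival separation.

    For each candidate s, patients split into score <= s versus >= s+1 and
    the log-rank statistic is computed; the smallest maximizing s is
    returned (most conservative high-risk group) together with the whole
    profile.
    """
    scores = np.asarray(scores, dtype=int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("scores take a single value: no cut exists")
    candidates = np.arange(distinct.min(), distinct.max())
    membership = scores[None, :] > candidates[:, None]  # high group: score >= s+1
    stat, _, _, _ = logrank_profile(times, events, membership)
    if np.all(np.isnan(stat)):
        raise ValueError("log-rank undefined for every score cut")
    profile = pd.DataFrame(
        {
            "statistic": stat,
            "n_low": [(scores <= s).sum() for s in candidates],
            "n_high": [(scores > s).sum() for s in candidates],
        },
        index=pd.Index(candidates, name="s"),
    )
    best = np.nanmax(stat)
    tied = np.flatnonzero(stat >= best - TIE_TOL)
    s_star = int(candidates[tied[0]])  # smallest maximizing s
    return ScoreThresholdResult(s_star=s_star, profile=profile)


def evaluate_risk_groups(
    scores: pd.Series,
    s_star: int,
    clinical: ClinicalTable,
    items: pd.DataFrame | None = None,
) -> RiskScoreResult:
    """Evaluate the low (score <= s*) versus high (score >= s*+1) risk groups.

    Produces per-group Kaplan-Meier curves, the log-rank test, cumulative
    incidence at 60 and 120 months and the O/E hazard ratio.  ``items``
    (patients x signature genes, e.g. log2 RQ) optionally adds Cronbach's
    alpha for the scale.
    """
    scores = pd.Series(scores)
    clin = clinical.subset(list(scores.index))
    high = scores > s_star
    if high.all() or (~high).all():
        raise ValueError("both risk groups must be non-empty")
    groups = high.map({True: "high", False: "low"}).rename("risk_group")
    groups.index.name = "sample_id"
    times, events = clin.times, clin.events
    lo, hi = ~high.to_numpy(), high.to_numpy()
    curve_low = km_estimate(times[lo], events[lo])
    curve_high = km_estimate(times[hi], events[hi])
    lr = logrank_test(times, events, groups.to_numpy())
    inc_low = {
        t: survival_at(curve_low, t).cumulative_incidence for t in (60, 120)
    }
    inc_high = {
        t: survival_at(curve_high, t).cumulative_incidence for t in (60, 120)
    }
    # logrank_test orders labels alphabetically: index 0 = "high", 1 = "low";
    # report the hazard of high relative to low.
    o, e = lr.observed, lr.expected
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (
            float((o[0] / e[0]) / (o[1] / e[1]))
            if o[1] > 0 and e[1] > 0 and e[0] > 0
            else float("inf")
        )
    alpha = None
    if items is not None:
        try:
            alpha = cronbach_alpha(items)
        except ValueError:  # fewer than 2 items / degenerate variance
            alpha = None
    return RiskScoreResult(
        s_star=int(s_star),
        groups=groups,
        n_low=int(lo.sum()),
        n_high=int(hi.sum()),
        events_low=int(events[lo].sum()),
        events_high=int(events[hi].sum()),
        curve_low=curve_low,
        curve_high=curve_high,
        logrank=lr,
        incidence_low=inc_low,
        incidence_high=inc_high,
        hazard_ratio=hr,
        hazard_ratio_degenerate=lr.hazard_ratio_degenerate,
        cronbach_alpha=alpha,
        scores=scores,
    )


def cronbach_alpha(items: pd.DataFrame, standardized: bool = True) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``items`` is patients x items (the signature genes, on log2 RQ by
    default upstream).  With ``standardized=True`` each item is z-scored
    first, which makes alpha invariant to per-item affine rescaling.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), variances over
    patients (ddof=1), var_total the variance of per-patient item sums.
    """
    x = pd.DataFrame(items).dropna(axis=0)
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 patients")
    if standardized:
        sd = x.std(ddof=1)
        if (sd == 0).any():
            raise ValueError("an item has zero variance; cannot standardize")
        x = (x - x.mean()) / sd
    item_vars = x.var(ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def permutation_p_extra(
    rq: ExpressionMatrix,
    signature: list[str],
    clinical: ClinicalTable,
    min_frac: float = 0.1,
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """Selection-corrected permutation p-value for the risk grouping.

    The in-sample log-rank p of the final risk groups is optimistic because
    the per-gene thresholds and the score cut were optimized on the same
    outcomes.  This supplementary readout permutes the (time, event) pairs
    against patients, re-runs the *entire* optimization (per-gene cut-point
    search, scoring, score-cut search) on each permutation, and compares the
    optimized statistics.  Returns (1 + #{perm >= observed}) / (1 + n_perm).
    """

    def optimized_stat(times: np.ndarray, events: np.ndarray) -> float:
        thr = {}
        samples = clinical.sample_ids
        for gene in signature:
            vals = rq.values.loc[gene, samples].to_numpy(dtype=float)
            keep = ~np.isnan(vals)
            mids, _, _ = _candidate_midpoints(vals[keep], min_frac)
            if mids.size == 0:
                return np.nan
            member = vals[keep][None, :] > mids[:, None]
            stat, _, _, _ = logrank_profile(times[keep], events[keep], member)
            pick = int(np.nanargmax(stat))
            thr[gene] = mids[pick]
        sub = rq.values.loc[signature, samples].T
        sc = sub.gt(pd.Series(thr), axis=1).astype(int).sum(axis=1).to_numpy()
        cands = np.arange(sc.min(), sc.max())
        if cands.size == 0:
            return np.nan
        member = sc[None, :] > cands[:, None]
        stat, _, _, _ = logrank_profile(times, events, member)
        return float(np.nanmax(stat))

    rng = np.random.default_rng(seed)
    times, events = clinical.times, clinical.events
    obs = optimized_stat(times, events)
    if np.isnan(obs):
        raise ValueError("observed optimized statistic undefined")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(times.size)
        s = optimized_stat(times[perm], events[perm])
        if not np.isnan(s) and s >= obs - TIE_TOL:
            hits += 1
    return float((hits + 1) / (n_perm + 1))
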