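"""Synthetic qPCR cohorts with planted prognostic structure.

The generator emulates the statistical shape of a small retrospective
low-density-array study: 47 assays (45 hypoxia-related targets plus the
RPL32 and 18S endogenous controls) measured on 32 early-stage breast tumor
patients whose clinical covariates follow the reference cohort's marginal
frequencies.

Expression is simulated on the Ct (log2) scale — Ct ~ Normal(baseline -
shifts, sd), lower Ct meaning higher expression — so relative
quantification downstream is log-normal, matching qPCR physics.  A latent
per-patient hypoxia activity loads on every target gene (strongest on the
signature), reproducing the coordinated co-expression of hypoxia-responsive
transcripts that makes a multi-gene scale internally consistent.  Reference
genes get a small technical sd, no biological shifts and no activity
loading.  Relapse-free
survival comes from an exponential proportional-hazards model on the
signature genes, either on continuous centered log2 expression
(``proportional`` mode) or on planted binary above-threshold indicators
(``threshold`` mode, which is what the risk-score recovery tests exercise).
Administrative and independent random censoring are applied.  Wells whose
Ct lands beyond the detection cutoff are reported numerically; the cutoff
is applied downstream, as with real exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    AGE_GROUPS,
    ClinicalTable,
    CohortDataset,
    CtMatrix,
    GenePanel,
    assemble_cohort,
)
from .io import load_gene_panel

__all__ = [
    "GroupEffect",
    "HazardModel",
    "SimConfig",
    "GroundTruth",
    "reference_cohort_frequencies",
    "default_baseline_ct",
    "simulate_cohort",
]

#: The six relapse-signature genes planted by default.
DEFAULT_SIGNATURE = ("EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI")


def reference_cohort_frequencies() -> dict[str, dict]:
    """Marginal covariate counts of the 32-patient reference cohort.

    Dichotomies collapse as: stage 1 (7) vs 2-3 (25, a single stage-3
    patient), mSBR grade 1-3 (25) vs 4-5 (7), HER2 negative (27) vs
    positive (5).  Within-band grade counts are a modeling choice; only the
    low/high split is constrained.
    """
    return {
        "age_group": {"<50": 8, ">=50": 24},
        "er": {"neg": 1, "pos": 31},
        "pr": {"neg": 8, "pos": 24},
        "nodes": {"neg": 20, "pos": 12},
        "stage": {1: 7, 2: 24, 3: 1},
        "grade_msbr": {1: 5, 2: 10, 3: 10, 4: 5, 5: 2},
        "her2": {"neg": 27, "pos": 5},
    }


@dataclass(frozen=True)
class GroupEffect:
    """An additive expression shift linked to a clinical dichotomy.

    Case patients of ``covariate`` (see ``ClinicalTable.dichotomy``) have
    the Ct of every gene in ``genes`` lowered by ``shift_cycles`` (one cycle
    = one log2 unit of up-regulation)."""

    covariate: str
    genes: tuple[str, ...]
    shift_cycles: float


@dataclass(frozen=True)
class HazardModel:
    """Exponential proportional-hazards model for relapse times.

    ``proportional`` mode: log-hazard = log(baseline_rate) + sum over
    signature genes of coefficient x centered log2 RQ.  ``threshold`` mode:
    log-hazard adds ``threshold_coef`` for every signature gene whose RQ
    exceeds its planted cutoff (indicators centered cohort-wise).
    """

    mode: str = "proportional"
    baseline_rate: float = 0.003  # events per month at the cohort average
    coefficients: dict = field(default_factory=dict)  # gene -> per-log2-unit
    threshold_rq: dict = field(default_factory=dict)  # gene -> planted RQ cutoff
    threshold_coef: float = 0.8  # log-hazard per positive indicator


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_patients: int = 32
    panel: GenePanel | None = None
    baseline_ct: pd.DataFrame | None = None  # index gene, columns mean, sd
    reference_sd: float = 0.2
    #: loadings (cycles per sd of the latent per-patient hypoxia activity)
    #: inducing the coordinated co-expression of hypoxia-responsive genes
    hypoxia_loading_signature: float = 1.0
    hypoxia_loading_other: float = 0.5
    group_effects: tuple[GroupEffect, ...] = ()
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE
    hazard: HazardModel = field(default_factory=HazardModel)
    horizon_months: float = 180.0
    censoring_rate: float = 0.003  # independent censoring, per month
    dropout_ct_threshold: float = 35.0
    frequencies: dict | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    """What was planted, aligned with the generated samples."""

    linear_predictor: pd.Series
    signature: tuple[str, ...]
    thresholds: dict | None
    group_effects: tuple[GroupEffect, ...]
    event_times: pd.Series
    censor_times: pd.Series
    true_log2rq: pd.DataFrame
    hypoxia_activity: pd.Series | None = None


def default_baseline_ct(panel: GenePanel, reference_sd: float = 0.2) -> pd.DataFrame:
    """Per-gene baseline Ct mean/sd (cycles).

    Abundant transcripts (glycolytic enzymes, structural genes) sit in the
    low 20s; scarce ones (EPO, LEP, CA9, CXCR4) near the detection limit so
    that realistic Ct > 35 dropouts occur.  Targets get a 1.5-cycle
    biological sd; the endogenous controls get the technical sd only.
    """
    low_abundance = {"EPO": 32.0, "LEP": 33.0, "CA9": 31.5, "CXCR4": 30.5}
    abundant = {
        "ENO1": 22.0, "LDHA": 22.5, "PGK1": 22.5, "TPI": 21.5, "GPI": 23.0,
        "KRT19": 21.0, "VIM": 21.5, "CTSD": 22.0, "GLUT1": 24.0,
    }
    rows = {}
    for entry in panel.entries:
        g = entry.symbol
        if entry.is_reference:
            mean = 13.0 if g == "18S" else 21.0
            sd = reference_sd
        else:
            mean = low_abundance.get(g, abundant.get(g, 26.0))
            sd = 1.5
        rows[g] = {"mean": mean, "sd": sd}
    return pd.DataFrame.from_dict(rows, orient="index").loc[panel.symbols]


def _exact_count_labels(freq: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Labels honoring the marginal frequencies as exactly as n allows
    (largest-remainder apportionment), in random order."""
    labels = list(freq)
    weights = np.array([freq[k] for k in labels], dtype=float)
    quota = weights / weights.sum() * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    for i in np.argsort(-(quota - counts))[:short]:
        counts[i] += 1
    vec = np.repeat(np.array(labels, dtype=object), counts)
    return rng.permutation(vec)


def _validate(config: SimConfig, panel: GenePanel) -> None:
    if config.n_patients < 2:
        raise ValueError("need at least 2 patients")
    if config.horizon_months <= 0:
        raise ValueError("administrative horizon must be > 0")
    if config.hazard.baseline_rate <= 0:
        raise ValueError("baseline hazard rate must be > 0")
    if config.reference_sd <= 0:
        raise ValueError("reference_sd must be > 0")
    if config.censoring_rate < 0:
        raise ValueError("censoring_rate must be >= 0")
    bad = [g for g in config.signature_genes if g not in panel.target_genes]
    if bad:
        raise ValueError(f"signature genes not in panel targets: {bad}")


def simulate_cohort(config: SimConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw one synthetic cohort plus its ground truth.

    Identical config and seed give a bit-identical cohort.  Ct values are
    reported to 2 decimals, as instrument exports are.
    """
    panel = config.panel or load_gene_panel()
    _validate(config, panel)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    samples = [f"S{i + 1:03d}" for i in range(n)]
    baseline = (
        config.baseline_ct
        if config.baseline_ct is not None
        else default_baseline_ct(panel, config.reference_sd)
    )
    if (baseline["sd"] <= 0).any():
        raise ValueError("baseline sds must be > 0")

    # --- clinical covariates (independent of expression unless linked) ---
    freqs = config.frequencies or reference_cohort_frequencies()
    clin = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for col in ("age_group", "er", "pr", "nodes", "stage", "grade_msbr", "her2"):
        clin[col] = _exact_count_labels(freqs[col], n, rng)
    clin["age_group"] = clin["age_group"].astype(str)
    for col in ("stage", "grade_msbr"):
        clin[col] = clin[col].astype(int)
    # placeholders until the event model runs
    clin["relapse"] = 0
    clin["rfs_months"] = 1.0
    provisional = ClinicalTable(clin.copy())

    # --- Ct matrix ---
    genes = panel.symbols
    means = pd.DataFrame(
        np.tile(baseline["mean"].to_numpy()[:, None], (1, n)),
        index=genes,
        columns=samples,
    )
    for eff in config.group_effects:
        case = provisional.dichotomy(eff.covariate)
        cols = [s for s in samples if case[s]]
        rows = [g for g in eff.genes if g in means.index]
        means.loc[rows, cols] -= eff.shift_cycles
    # latent per-patient hypoxia activity: shared up-regulation (lower Ct)
    # across all hypoxia-responsive targets, strongest on the signature
    activity = rng.standard_normal(n)
    loadings = np.array(
        [
            0.0
            if g in panel.reference_genes
            else (
                config.hypoxia_loading_signature
                if g in config.signature_genes
                else config.hypoxia_loading_other
            )
            for g in genes
        ]
    )
    means -= loadings[:, None] * activity[None, :]
    noise = rng.standard_normal((len(genes), n)) * baseline["sd"].to_numpy()[:, None]
    ct_values = np.maximum(means.to_numpy() + noise, 0.1).round(2)
    ct = CtMatrix(pd.DataFrame(ct_values, index=genes, columns=samples))

    # --- true relative quantification (no detection cutoff applied) ---
    ref_mean = ct.values.loc[panel.reference_genes].mean(axis=0)
    dct = ct.values.drop(index=panel.reference_genes).sub(ref_mean, axis=1)
    ddct = dct.sub(dct.mean(axis=1), axis=0)
    log2rq = -ddct  # centered log2 expression
    rq = np.power(2.0, log2rq)

    # --- hazards ---
    hz = config.hazard
    sig = list(config.signature_genes)
    thresholds = None
    if hz.mode == "proportional":
        coefs = pd.Series({g: hz.coefficients.get(g, 0.4) for g in sig})
        lp = log2rq.loc[sig].mul(coefs, axis=0).sum(axis=0)
    elif hz.mode == "threshold":
        thresholds = {g: hz.threshold_rq.get(g, 2.0) for g in sig}
        ind = rq.loc[sig].gt(pd.Series(thresholds), axis=0).astype(float)
        lp = hz.threshold_coef * (ind - ind.mean(axis=1).to_numpy()[:, None]).sum(
            axis=0
        )
    else:
        raise ValueError(f"unknown hazard mode {hz.mode!r}")
    rate = hz.baseline_rate * np.exp(lp.to_numpy())
    event_t = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        censor_t = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    censor_t = np.minimum(censor_t, config.horizon_months)
    observed = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    if np.all(observed <= 0):
        raise ValueError("degenerate configuration: all follow-up at time 0")
    clin["relapse"] = event
    clin["rfs_months"] = np.maximum(observed.round(2), 0.01)
    clinical = ClinicalTable(clin)

    cohort = assemble_cohort(ct, clinical, panel)
    truth = GroundTruth(
        linear_predictor=pd.Series(lp, index=samples, name="lp"),
        signature=tuple(sig),
        thresholds=thresholds,
        group_effects=config.group_effects,
        event_times=pd.Series(event_t, index=samples, name="event_time"),
        censor_times=pd.Series(censor_t, index=samples, name="censor_time"),
        true_log2rq=log2rq,
        hypoxia_activity=pd.Series(activity, index=samples, name="hypoxia_activity"),
    )
    return cohort, truth


def null_config(n_patients: int = 32, seed: int = 0) -> SimConfig:
    """A configuration with no planted effect: zero signature coefficients."""
    hz = HazardModel(mode="proportional", coefficients={g: 0.0 for g in DEFAULT_SIGNATURE})
    return SimConfig(n_patients=n_patients, hazard=hz, seed=seed)


def threshold_config(
    n_patients: int = 200,
    seed: int = 0,
    threshold_rq: dict | None = None,
    threshold_coef: float = 0.8,
) -> SimConfig:
    """Threshold-mode configuration planting binary indicator hazards."""
    hz = HazardModel(
        mode="threshold",
        threshold_rq=threshold_rq or {},
        threshold_coef=threshold_coef,
    )
    return SimConfig(n_patients=n_patients, hazard=hz, seed=seed)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
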