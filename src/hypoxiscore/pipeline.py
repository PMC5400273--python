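"""End-to-end orchestration: quantify -> differential -> cluster -> score -> survival.

A :class:`PipelineConfig` names either input files (Ct + clinical CSV) or a
simulation block; :func:`run_pipeline` executes every stage, writes the
stage tables and figures to the output directory and a machine-readable
``summary.json``.  The same config and seed produce a byte-identical
summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import plots
from .cluster import cluster_relapse_association, hierarchical_cluster
from .datatypes import CohortDataset, assemble_cohort
from .differential import compare_groups
from .io import load_gene_panel, read_clinical_table, read_ct_table, write_ct_table
from .quantify import (
    apply_detection_cutoff,
    compute_delta_ct,
    compute_rq,
    missingness_report,
    select_references,
    stability_ranking,
)
from .score import (
    SignatureEmptyError,
    build_threshold_table,
    compute_scores,
    evaluate_risk_groups,
    select_score_threshold,
    select_signature,
)
from .simulate import HazardModel, SimConfig, simulate_cohort

logger = logging.getLogger("hypoxiscore")

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``ct_path``/``clinical_path`` or ``simulate`` must be
    given.  ``signature_alphas`` is the ladder of significance levels tried
    in order for signature selection (the first non-empty set wins).
    """

    ct_path: str | None = None
    clinical_path: str | None = None
    simulate: SimConfig | None = None
    normalization: str = "housekeeping"  # housekeeping | normfinder | global_mean
    ct_cutoff: float = 35.0
    calibrator: str = "cohort_mean"
    groupings: tuple[str, ...] = ("stage", "grade", "her2", "relapse")
    cluster_k_all: int = 2
    cluster_k_signature: int = 3
    signature_alphas: tuple[float, ...] = (0.05,)
    threshold_mode: str = "search"  # search | published
    min_frac: float = 0.1
    score_threshold: str | int = "auto"
    out_dir: str = "hypoxiscore_out"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        has_files = self.ct_path is not None and self.clinical_path is not None
        if has_files == (self.simulate is not None):
            raise ConfigError(
                "exactly one of (ct_path + clinical_path) or a simulate block required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            hz = sim.pop("hazard", None)
            if hz is not None:
                sim["hazard"] = HazardModel(**hz)
            sim = SimConfig(**sim)
        for key in ("groupings", "signature_alphas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)


def _load_cohort(config: PipelineConfig) -> CohortDataset:
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        cohort, _ = simulate_cohort(sim)
        return cohort
    ct = read_ct_table(config.ct_path)
    clinical = read_clinical_table(config.clinical_path)
    return assemble_cohort(ct, clinical, load_gene_panel())


def _select_with_ladder(comparison, alphas):
    last_exc: Exception | None = None
    for a in alphas:
        try:
            return select_signature(comparison, alpha=a), a
        except SignatureEmptyError as exc:
            last_exc = exc
    raise last_exc  # type: ignore[misc]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "normalization": config.normalization}

    cohort = _load_cohort(config)
    summary["n_patients"] = cohort.n_samples
    logger.info("cohort: %d genes x %d samples", cohort.ct.n_genes, cohort.n_samples)

    # --- quantification ---
    ct = apply_detection_cutoff(cohort.ct, cutoff=config.ct_cutoff)
    missingness_report(ct).to_csv(out / "missingness.csv")
    if config.normalization == "housekeeping":
        refs = select_references("housekeeping", available_genes=ct.genes)
    elif config.normalization == "normfinder":
        ranking = stability_ranking(ct, groups=None)
        refs = select_references("stability_top_k", ranking=ranking, k=2)
        ranking.table.to_csv(out / "stability_ranking.csv")
    elif config.normalization == "global_mean":
        refs = select_references("global_mean")
    else:
        raise ConfigError(f"unknown normalization {config.normalization!r}")
    dct = compute_delta_ct(ct, refs)
    rq = compute_rq(dct, calibrator=config.calibrator)
    dct.values.to_csv(out / "delta_ct.csv")
    rq.values.to_csv(out / "rq.csv")
    write_ct_table(ct, out / "ct_after_cutoff.csv")
    summary["reference_genes"] = list(refs.genes)

    # --- differential profiles ---
    comparisons = {}
    summary["differential"] = {}
    for grouping in config.groupings:
        comp = compare_groups(rq, dct, cohort.clinical, grouping)
        comparisons[grouping] = comp
        comp.table.to_csv(out / f"diffexp_{grouping}.tsv", sep="\t")
        summary["differential"][grouping] = {
            "n_case": len(comp.case_samples),
            "n_control": len(comp.control_samples),
            "mean_overexpression_pct": round(comp.mean_overexpression_pct, 4),
            "mean_fold": round(comp.mean_fold, 4),
            "n_significant": int((comp.table["p"] < 0.05).sum()),
        }
        if config.make_plots:
            plots.fold_profile_plot(comp, out / f"fold_profile_{grouping}.png")

    # --- clustering (all genes, then the signature) ---
    cl_all = hierarchical_cluster(dct, k=config.cluster_k_all)
    cl_all.labels.to_csv(out / "clusters_all_genes.csv")
    assoc_all = cluster_relapse_association(cl_all.labels, cohort.clinical)
    summary["clustering_all_genes"] = {
        "k": cl_all.k,
        "chi2": round(assoc_all.statistic, 4),
        "p": round(assoc_all.p_value, 6),
        "relapse_proportion": {
            str(k): round(v, 4) for k, v in assoc_all.relapse_proportion.items()
        },
    }
    if config.make_plots:
        plots.heatmap_plot(cl_all, out / "heatmap_all_genes.png")

    # --- signature + risk score ---
    relapse_comp = comparisons.get("relapse") or compare_groups(
        rq, dct, cohort.clinical, "relapse"
    )
    signature, alpha_used = _select_with_ladder(relapse_comp, config.signature_alphas)
    summary["signature"] = {"genes": signature, "alpha_used": alpha_used}

    if len(signature) >= 2:
        cl_sig = hierarchical_cluster(
            dct, genes=signature, k=min(config.cluster_k_signature, cohort.n_samples)
        )
        cl_sig.labels.to_csv(out / "clusters_signature.csv")
        assoc_sig = cluster_relapse_association(cl_sig.labels, cohort.clinical)
        summary["clustering_signature"] = {
            "k": cl_sig.k,
            "chi2": round(assoc_sig.statistic, 4),
            "p": round(assoc_sig.p_value, 6),
        }
        if config.make_plots:
            plots.heatmap_plot(cl_sig, out / "heatmap_signature.png")

    thresholds = build_threshold_table(
        rq, signature, cohort.clinical, mode=config.threshold_mode, min_frac=config.min_frac
    )
    thresholds.table.to_csv(out / "thresholds.csv")
    scores = compute_scores(rq, thresholds)
    scores.to_csv(out / "scores.csv")
    times, events = cohort.clinical.times, cohort.clinical.events
    if config.score_threshold == "auto":
        sel = select_score_threshold(scores["score"].to_numpy(), times, events)
        s_star = sel.s_star
        sel.profile.to_csv(out / "score_threshold_profile.csv")
    else:
        s_star = int(config.score_threshold)

    items = np.log2(rq.values.loc[signature].T)
    result = evaluate_risk_groups(scores["score"], s_star, cohort.clinical, items=items)
    alpha_coef = result.cronbach_alpha
    result.groups.to_csv(out / "risk_groups.csv")
    if config.make_plots:
        plots.km_plot(result, out / "km_risk_groups.png")

    summary["risk_score"] = {
        "thresholds": {g: round(v, 6) for g, v in thresholds.thresholds.items()},
        "threshold_mode": thresholds.mode,
        "score_threshold": result.s_star,
        "n_low": result.n_low,
        "n_high": result.n_high,
        "events_low": result.events_low,
        "events_high": result.events_high,
        "logrank_statistic": round(result.logrank.statistic, 6),
        "logrank_p_in_sample": round(result.logrank.p_value, 6),
        "hazard_ratio_oe": (
            "inf" if np.isinf(result.hazard_ratio) else round(result.hazard_ratio, 4)
        ),
        "incidence_high_pct": {
            str(t): round(100 * v, 2) for t, v in result.incidence_high.items()
        },
        "incidence_low_pct": {
            str(t): round(100 * v, 2) for t, v in result.incidence_low.items()
        },
        "cronbach_alpha": None if alpha_coef is None else round(alpha_coef, 4),
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(summary["risk_score"], fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
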