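"""End-to-end orchestration: ingest -> normalize -> DE -> cluster -> CV -> subgroups.

A single :class:`PipelineConfig` drives the whole analysis.  Input is
either a pair of files (Ct matrix + annotation) or a simulation
configuration; every stochastic stage is seeded from one global seed, and
all artifacts — normalized matrix, DE table, signatures, cluster
assignments, CV reports, sweep trace — are written as CSV plus a
machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import crossval as cv
from . import de as de_mod
from . import io as io_mod
from . import normalize as norm_mod
from .pca import pca as compute_pca, subgroup_sweep
from .simulate import SimulationConfig, generate_paired_dataset

log = logging.getLogger("mirsig")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    ct_path: str | None = None
    annot_path: str | None = None
    simulate: SimulationConfig | None = None
    exclude: list[str] = field(default_factory=list)
    normalize: bool = True
    alpha: float = 1e-4
    alpha2: float = 1e-5
    k_full_cohort: int = 2
    cv: cv.CVConfig = field(default_factory=cv.CVConfig)
    run_permutation: bool = True
    subgroup_variable: str = "gleason_score"
    subgroup_thresholds: list[float] | None = None
    out_dir: str = "mirsig_out"
    seed: int = 0

    def validate(self) -> None:
        has_files = self.ct_path is not None and self.annot_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide either (ct_path, annot_path) or a simulate block")
        for al in (self.alpha, self.alpha2):
            if not 0 < al < 1:
                raise ValueError(f"alpha {al} outside (0, 1)")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sim = doc.pop("simulate", None)
    cvc = doc.pop("cv", None)
    cfg = PipelineConfig(**doc)
    if sim is not None:
        if "baseline_ct_range" in sim:
            sim["baseline_ct_range"] = tuple(sim["baseline_ct_range"])
        cfg.simulate = SimulationConfig(**sim)
    if cvc is not None:
        cfg.cv = cv.CVConfig(**cvc)
    return cfg


def _dump_config(cfg: PipelineConfig, path: Path) -> None:
    doc = json.loads(json.dumps(dataclasses.asdict(cfg), default=str))  # tuples -> lists
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and return the JSON-ready summary dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_config(cfg, out / "config_resolved.yaml")

    # ingest
    if cfg.simulate is not None:
        ds = generate_paired_dataset(
            dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed or cfg.seed)
        )
        ct, annot = ds.ct, ds.annotation
        log.info("simulated dataset: %d features x %d samples", *ct.shape)
    else:
        ct = io_mod.read_ct_table(cfg.ct_path)
        annot = io_mod.read_annotation(cfg.annot_path)
        log.info("loaded %d features x %d samples", *ct.shape)
    if cfg.exclude:
        ct, annot = io_mod.exclude_samples(ct, annot, cfg.exclude)
        log.info("excluded %s; %d complete pairs remain",
                 cfg.exclude, len(io_mod.complete_pairs(annot)))

    # normalize
    if cfg.normalize:
        ct, report = norm_mod.quantile_normalize(ct)
        report.to_frame().to_csv(out / "normalization_report.csv")
    io_mod.write_ct_table(ct, out / "ct_processed.csv")
    io_mod.write_annotation(annot, out / "annotation_processed.csv")

    # differential expression
    de = de_mod.de_table(ct, annot, wilcoxon=True)
    de.to_csv(out / "de_results.csv")
    sig1 = de_mod.select_signature(de, cfg.alpha)
    sig2 = de_mod.select_signature(de, cfg.alpha2)
    log.info("signatures: %d features at p<%g, %d at p<%g",
             len(sig1), cfg.alpha, len(sig2), cfg.alpha2)
    for name, sig in (("signature_alpha1.txt", sig1), ("signature_alpha2.txt", sig2)):
        (out / name).write_text("\n".join(sig.feature_ids) + "\n")

    # full-cohort clustering of both signatures
    cohort: dict[str, dict] = {}
    for label, sig in (("alpha1", sig1), ("alpha2", sig2)):
        if len(sig) == 0:
            cohort[label] = {"n_features": 0, "misplaced": None}
            continue
        d = cl.distance_matrix(ct, sig.feature_ids)
        tree = cl.average_linkage(d)
        assign = cl.cut_tree(tree, cfg.k_full_cohort)
        misplaced, rate, scored = cl.score_assignment(assign, annot)
        scored.assignment.to_csv(out / f"clusters_{label}.csv", header=["cluster"])
        (out / f"dendrogram_{label}.nwk").write_text(tree.to_newick() + "\n")
        cohort[label] = {
            "n_features": len(sig),
            "misplaced": misplaced,
            "error_rate_pct": 100 * rate,
            "misplaced_samples": sorted(scored.misplaced),
        }
        log.info("full-cohort clustering (%s, k=%d): %d misplaced",
                 label, cfg.k_full_cohort, misplaced)

    # cross-validation + permutation null
    cv_cfg = dataclasses.replace(cfg.cv, seed=cfg.cv.seed or cfg.seed)
    report = cv.run_cv(ct, annot, cv_cfg)
    report.to_frame().to_csv(out / "cv_repeats.csv")
    freq = cv.selection_frequency(report) if report.successful else pd.DataFrame()
    if len(freq):
        freq.to_csv(out / "cv_selection_frequency.csv")
    summary_cv = {
        "n_repeats": cv_cfg.n_repeats,
        "n_failed": len(report.repeats) - len(report.successful),
        "held_out_size": report.held_out_size,
        "histogram": {str(k): v for k, v in report.histogram().items()},
        "average_error_rate_pct": report.average_error_rate(),
    }
    log.info("cross-validation: average error rate %.1f%%", report.average_error_rate())

    summary_null = None
    if cfg.run_permutation:
        null_cfg = dataclasses.replace(cv_cfg, permute_labels=True)
        null_report = cv.run_permutation_null(ct, annot, null_cfg)
        null_report.to_frame().to_csv(out / "cv_permutation_repeats.csv")
        summary_null = {
            "n_failed": len(null_report.repeats) - len(null_report.successful),
            "average_error_rate_pct": null_report.average_error_rate(),
        }

    # PCA on the stringent signature
    pca_summary = None
    sig_for_pca = sig2 if len(sig2) >= 2 else sig1
    complete_feats = [f for f in sig_for_pca.feature_ids if not ct.loc[f].isna().any()]
    if len(complete_feats) >= 2:
        res = compute_pca(ct, complete_feats)
        res.scores.to_csv(out / "pca_scores.csv")
        pca_summary = {
            "n_features": len(complete_feats),
            "variance_explained": [float(v) for v in res.variance_explained[:2]],
        }

    # subgroup sweep among malignant samples
    sweep_summary = None
    malig = annot[annot["tissue_class"] == "malignant"]
    if malig[cfg.subgroup_variable].dropna().nunique() >= 2:
        sweep = subgroup_sweep(
            ct[malig.index.tolist()],
            malig,
            grouping_variable=cfg.subgroup_variable,
            thresholds=cfg.subgroup_thresholds,
            seed=cfg.seed,
        )
        sweep.trace.to_csv(out / "subgroup_sweep_trace.csv")
        sweep_summary = {
            "threshold": sweep.threshold,
            "n_features": len(sweep.feature_ids),
            "misplaced": len(sweep.misplaced),
        }
        log.info("subgroup sweep: p<%g keeps %d features, %d misplaced",
                 sweep.threshold, len(sweep.feature_ids), len(sweep.misplaced))

    summary = {
        "seed": cfg.seed,
        "n_features": int(ct.shape[0]),
        "n_samples": int(ct.shape[1]),
        "n_complete_pairs": len(io_mod.complete_pairs(annot)),
        "signature_sizes": {"alpha1": len(sig1), "alpha2": len(sig2)},
        "alphas": {"alpha1": cfg.alpha, "alpha2": cfg.alpha2},
        "full_cohort_clustering": cohort,
        "cross_validation": summary_cv,
        "permutation_null": summary_null,
        "pca": pca_summary,
        "subgroup_sweep": sweep_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
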