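"""End-to-end orchestration: read -> merge -> filter -> normalize -> DE ->
risk score -> enrichment, from a single structured config."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import CountMatrix, ValidationError
from .diffexpr import NegativeBinomialDE
from .enrichment import collect_target_genes, enrich_gene_sets
from .normalization import estimate_size_factors, fpm, log_fpm
from .risk_score import PolygenicRiskScore, polygenic_score

logger = logging.getLogger("circmir")


@dataclass
class PipelineConfig:
    """Run configuration; unknown keys in a YAML file are rejected."""

    counts: str | None = None
    metadata: str | None = None
    targets: str | None = None
    gene_sets: str | None = None
    precursor_column: str | None = None
    outdir: str = "circmir_run"
    min_total: int = 200
    p_threshold: float = 0.01
    lfc_threshold: float = 2.0
    pseudocount: float = 1.0
    log_base: float = 2.0
    background_n: int = 20_000
    correction: str = "bonferroni"
    restrict_to_universe: bool = True
    size_factors_on: str = "filtered"   # or "all"
    sf_fallback: str | None = None      # "poscounts"
    standardize_covariates: bool = False
    adjust_for_age: bool = True
    ci_method: str = "delong"
    seed: int = 0
    simulate: bool = False              # generate inputs instead of reading them
    sim_n_features: int = 756           # simulate-mode generator settings
    sim_frac_de: float = 0.02

    def __post_init__(self) -> None:
        if self.min_total < 0 or self.p_threshold < 0 or self.lfc_threshold < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.size_factors_on not in ("filtered", "all"):
            raise ValidationError("size_factors_on must be 'filtered' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _setup_run_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes result TSVs, run.log and summary.json into
    ``config.outdir`` and returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    try:
        return _run(config, outdir)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        from .simulate import SimulationParams, simulate_dataset

        params = SimulationParams(
            n_features=config.sim_n_features, frac_de=config.sim_frac_de
        )
        cm, metadata, truth = simulate_dataset(params, seed=config.seed)
        # target table/gene sets are built later, once the DE panel is known
        return cm, metadata.drop(columns=["true_size_factor"]), None, None
    if config.counts is None or config.metadata is None:
        raise ValidationError("counts and metadata paths are required unless simulate: true")
    cm = cio.read_count_matrix(config.counts, precursor_column=config.precursor_column)
    if cm.mature_map is not None:
        cm = cio.merge_mature_counts(cm)
    metadata = cio.read_sample_metadata(config.metadata)
    targets = cio.read_target_table(config.targets) if config.targets else None
    collection = (
        cio.read_gmt(config.gene_sets, background_size=config.background_n)
        if config.gene_sets
        else None
    )
    return cm, metadata, targets, collection


def _run(config: PipelineConfig, outdir: Path) -> dict:
    summary: dict = {"config": dataclasses.asdict(config)}

    logger.info("stage read: loading inputs")
    cm, metadata, targets, collection = _load_inputs(config)
    metadata = metadata.loc[cm.samples]
    summary["n_features_input"] = cm.shape[0]
    summary["n_samples"] = cm.shape[1]

    logger.info("stage filter: abundance threshold total >= %d", config.min_total)
    if config.size_factors_on == "all":
        sf = estimate_size_factors(cm, fallback=config.sf_fallback)
        cm = cio.filter_low_abundance(cm, config.min_total)
    else:
        cm = cio.filter_low_abundance(cm, config.min_total)
        sf = estimate_size_factors(cm, fallback=config.sf_fallback)
    summary["n_features_tested"] = cm.shape[0]
    sf.to_csv(outdir / "size_factors.tsv", sep="\t", header=True, index_label="sample_id")

    logger.info("stage normalize: FPM and log%g(FPM + %g)", config.log_base, config.pseudocount)
    fpm_mat = fpm(cm, sf)
    logfpm = log_fpm(fpm_mat, pseudocount=config.pseudocount, base=config.log_base)
    fpm_mat.round(4).to_csv(outdir / "fpm.tsv", sep="\t", index_label="mirna")

    logger.info("stage de: NB Wald test adjusted for age=%s", config.adjust_for_age)
    de = NegativeBinomialDE(
        p_threshold=config.p_threshold,
        lfc_threshold=config.lfc_threshold,
        adjust_for_age=config.adjust_for_age,
        standardize_covariates=config.standardize_covariates,
    )
    de.fit(
        cm.values.T,
        metadata["group"].to_numpy(),
        age=metadata["age"].to_numpy() if config.adjust_for_age else None,
        size_factors=sf.to_numpy(),
        feature_names=cm.features,
    )
    results = de.results_
    results.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    panel = results.loc[results["de"], ["feature", "lfc"]].set_index("feature")["lfc"]
    summary["n_de"] = int(len(panel))
    summary["de_panel"] = {k: round(float(v), 4) for k, v in panel.items()}

    if len(panel) == 0:
        logger.info("stage score: skipped (empty DE panel)")
        summary["risk_score"] = None
    else:
        logger.info("stage score: %d-miRNA LFC-weighted polygenic score", len(panel))
        scores = polygenic_score(logfpm, panel)
        labels = (metadata["group"] == "DR").to_numpy()
        prs = PolygenicRiskScore(weights=panel, ci_method=config.ci_method,
                                 random_state=config.seed).fit(logfpm.T, labels)
        pd.DataFrame(
            {"score": scores, "group": metadata["group"], "predicted_case": prs.predict(logfpm.T)}
        ).to_csv(outdir / "risk_scores.tsv", sep="\t", index_label="sample_id")
        prs.roc_.points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        summary["risk_score"] = {
            "auc": round(prs.auc_, 4),
            "auc_ci": [round(v, 4) for v in prs.auc_ci_],
            "cutoff": round(prs.cutoff_, 4),
            "sensitivity": round(prs.sensitivity_, 4),
            "specificity": round(prs.specificity_, 4),
            "orientation": prs.orientation_,
            "in_sample_evaluation": True,  # weights and AUC share samples: optimistic
        }

    if config.simulate and len(panel) >= 2:
        from .simulate import make_target_fixture

        targets, collection = make_target_fixture(
            panel=list(panel.index)[:5], seed=config.seed
        )

    if targets is not None and collection is not None and len(panel) > 0:
        logger.info("stage enrich: hypergeometric over-representation, N=%d", config.background_n)
        query, per_mirna = collect_target_genes(list(panel.index), targets)
        enr = enrich_gene_sets(
            query, collection,
            background_size=config.background_n,
            restrict_to_universe=config.restrict_to_universe,
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        headline = "p_bonferroni" if config.correction == "bonferroni" else "q_bh"
        top = enr.head(5)
        summary["enrichment"] = {
            "n_query_genes": int(len(query)),
            "per_mirna_targets": {k: int(v) for k, v in per_mirna.items()},
            "top_sets": [
                {"set": r["set"], "k": int(r["k"]), "K": int(r["K"]),
                 "p": float(r["p"]), headline: float(r[headline])}
                for _, r in top.iterrows()
            ],
        }
    else:
        summary["enrichment"] = None

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("pipeline complete; outputs in %s", outdir)
    return summary
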