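"""Pipeline configuration, validation, and the end-to-end `discover` run.

A run is fully described by a :class:`PipelineConfig` (loadable from a YAML
key/value file); every stochastic stage derives its seed from the single
top-level seed, so re-running with the same config reproduces identical
outputs.  Each run writes its artifacts plus a machine-readable manifest
(config, config hash, seeds, package versions, per-stage wall-clock).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomarker_scoring as scoring
from . import prognostic
from .data_model import (read_count_matrix, read_labels, read_survival,
                         ValidationError)
from .vaejmlp import ArchitectureSpec, TrainingSchedule
from .attribution import AttributionConfig

log = logging.getLogger("vaemarker")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    counts_path: str = ""
    labels_path: str = ""
    survival_path: str | None = None
    outdir: str = "vaemarker_out"
    counts_format: str | None = None
    discovery: scoring.DiscoveryConfig = scoring.DiscoveryConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        disc = dict(raw.pop("discovery", {}))
        known_top = {f.name for f in dataclasses.fields(cls)} - {"discovery"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        known_disc = {f.name for f in dataclasses.fields(scoring.DiscoveryConfig)}
        unknown = set(disc) - known_disc
        if unknown:
            raise ValidationError(f"unknown discovery config keys: {sorted(unknown)}")
        if "schedule" in disc:
            disc["schedule"] = TrainingSchedule(**disc["schedule"])
        if "attribution" in disc:
            disc["attribution"] = AttributionConfig(**disc["attribution"])
        if "arch" in disc and disc["arch"] is not None:
            disc["arch"] = ArchitectureSpec(**disc["arch"])
        for key in ("freq_thresholds", "q_tails"):
            if key in disc:
                disc[key] = tuple(disc[key])
        return cls(**raw, discovery=scoring.DiscoveryConfig(**disc))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Cross-field invariant checks; returns a list of error messages."""
    errors = []
    try:
        config.discovery.validate()
    except ValidationError as exc:
        errors.append(str(exc))
    sched = config.discovery.schedule
    if sched.vae_only_epochs + sched.mlp_only_epochs + sched.joint_epochs \
            != sched.total_epochs:
        pass  # already reported by validate()
    if config.counts_path and not Path(config.counts_path).exists():
        errors.append(f"counts file not found: {config.counts_path}")
    if config.labels_path and not Path(config.labels_path).exists():
        errors.append(f"labels file not found: {config.labels_path}")
    return errors


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> scoring.BiomarkerResult:
    """Execute discovery end to end and persist all artifacts.

    Writes: frequency table, feature-set gene lists, per-run candidates, the
    final biomarker list, provenance JSON, a manifest, and (when survival
    data is supplied) the risk-model outputs.
    """
    errors = validate_config(config)
    if errors:
        raise ValidationError("; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    counts = read_count_matrix(config.counts_path, config.counts_format)
    labels = read_labels(config.labels_path)
    timings["load"] = time.perf_counter() - t0

    log.info("discovery: %d genes x %d samples", counts.n_genes, counts.n_samples)
    t0 = time.perf_counter()
    result = scoring.run_discovery(counts, labels, config.discovery)
    timings["discovery"] = time.perf_counter() - t0

    (outdir / "final_biomarkers.txt").write_text(
        "".join(f"{g}\n" for g in result.gene_ids))
    for i, cand in enumerate(result.candidate_sets):
        name = (f"candidates_{cand.provenance.get('feature_set', i)}"
                f"_set{cand.provenance.get('sample_set', i)}.txt"
                ).replace(">=", "ge").replace(" ", "_")
        (outdir / name).write_text(
            "".join(f"{g}\n" for g in sorted(cand.gene_ids)))
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, default=str))

    if config.survival_path and result.gene_ids:
        t0 = time.perf_counter()
        surv = read_survival(config.survival_path)
        expr = np.log2(counts.to_frame() + 1)  # log-normalized expression
        cox = prognostic.fit_cox(expr, surv, list(result.gene_ids),
                                 mode="multivariate")
        fitted = cox[cox["converged"]]
        model = prognostic.RiskModel(tuple(fitted.index),
                                     fitted["coef"].to_numpy(),
                                     expression_source="log2_counts")
        scores = prognostic.risk_score(model, expr)
        groups = prognostic.median_split(scores)
        stat, pval = prognostic.logrank_test(groups, surv)
        cox.to_csv(outdir / "cox_coefficients.tsv", sep="\t")
        pd.DataFrame({"sample_id": list(groups.sample_ids),
                      "risk_score": groups.scores,
                      "group": list(groups.group)}
                     ).to_csv(outdir / "risk_groups.tsv", sep="\t", index=False)
        (outdir / "logrank.json").write_text(
            json.dumps({"statistic": stat, "pvalue": pval}))
        timings["prognostic"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.discovery.seed,
        "n_final_biomarkers": len(result.gene_ids),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    log.info("final biomarkers: %d", len(result.gene_ids))
    return result
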