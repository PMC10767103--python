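"""Biomarker potential scoring and candidate intersection.

A gene is a good biomarker when it contributes *consistently*: significantly
positive attributions in tumor samples and significantly negative ones in
normal samples, in a high fraction of each class.  Significance cutoffs are
the q and (1-q) empirical quantiles of the pooled attribution distribution
(all samples x all genes); with C_P the number of tumor samples above the
positive cutoff and C_N the number of normal samples below the negative one,

    P_tumor  = C_P / N_tumor,   P_normal = C_N / N_normal
    Score(g) = 2 * P_tumor * P_normal / (P_tumor + P_normal)

i.e. the harmonic mean of the two proportions (0 when both are 0).  Genes in
the top quartile of scores survive; candidates are intersected across the
tail-width groups, across resampled sample sets, and across feature
configurations to give the final, maximally consistent list.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import diffexp_stability as de
from . import vaejmlp
from .attribution import AttributionConfig, AttributionMatrix, attribute
from .data_model import CountMatrix, LabelVector, ValidationError, minmax_scale


@dataclasses.dataclass(frozen=True)
class ContributionThresholds:
    """Significance cutoffs from the pooled attribution distribution."""

    q: float
    pos_cutoff: float
    neg_cutoff: float

    def __post_init__(self):
        if self.neg_cutoff > self.pos_cutoff:
            raise ValidationError("neg_cutoff must not exceed pos_cutoff")


@dataclasses.dataclass(frozen=True)
class BiomarkerScoreTable:
    """Per-gene counts, proportions and harmonic-mean score."""

    table: pd.DataFrame  # index gene, cols C_P, C_N, P_tumor, P_normal, score
    n_tumor: int
    n_normal: int
    thresholds: ContributionThresholds


@dataclasses.dataclass(frozen=True)
class CandidateSet:
    gene_ids: frozenset[str]
    provenance: dict


@dataclasses.dataclass(frozen=True)
class BiomarkerResult:
    """Final gene list shared by all candidate sets, plus the full trace."""

    gene_ids: tuple[str, ...]
    candidate_sets: tuple[CandidateSet, ...]
    provenance: dict


def compute_thresholds(attr: AttributionMatrix, q: float) -> ContributionThresholds:
    """q and (1-q) linear-interpolation quantiles of all pooled attributions."""
    if not (0 < q < 0.5):
        raise ValidationError(f"tail fraction q must lie in (0, 0.5), got {q}")
    pooled = attr.values.ravel()
    neg, pos = np.quantile(pooled, [q, 1 - q])
    return ContributionThresholds(q, float(pos), float(neg))


def contribution_shares(attr: AttributionMatrix) -> AttributionMatrix:
    """Per-sample signed contribution shares: each attribution divided by the
    sample's total absolute attribution, so a value of 0.05 means the gene
    carries 5% of everything that moved this sample's prediction."""
    denom = np.abs(attr.values).sum(axis=1, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    return AttributionMatrix(attr.values / safe, attr.sample_ids, attr.gene_ids,
                             attr.base_value,
                             explained_output=attr.explained_output + "_share")


def share_thresholds(q: float) -> ContributionThresholds:
    """Fixed cutoffs +-q on per-sample contribution shares (e.g. q = 0.05
    means a gene is significant in a sample when it carries at least 5% of
    the sample's total absolute contribution)."""
    if not (0 < q < 0.5):
        raise ValidationError(f"share cutoff must lie in (0, 0.5), got {q}")
    return ContributionThresholds(q, q, -q)


def score_genes(attr: AttributionMatrix, labels: LabelVector,
                thr: ContributionThresholds) -> BiomarkerScoreTable:
    """Count concordant significant contributions per gene and score them.

    Only the concordant directions count: attributions above the positive
    cutoff in tumor samples (C_P) and below the negative cutoff in normal
    samples (C_N).  Score is 0, not NaN, when both proportions vanish.
    """
    y = labels.for_samples(list(attr.sample_ids))
    n_tumor = int((y == 1).sum())
    n_normal = int((y == 0).sum())
    if n_tumor == 0 or n_normal == 0:
        raise ValidationError("both classes required for scoring")
    c_p = (attr.values[y == 1] > thr.pos_cutoff).sum(axis=0)
    c_n = (attr.values[y == 0] < thr.neg_cutoff).sum(axis=0)
    p_t = c_p / n_tumor
    p_n = c_n / n_normal
    denom = p_t + p_n
    score = np.divide(2.0 * p_t * p_n, denom, out=np.zeros_like(denom),
                      where=denom > 0)
    table = pd.DataFrame({"C_P": c_p, "C_N": c_n, "P_tumor": p_t,
                          "P_normal": p_n, "score": score},
                         index=list(attr.gene_ids))
    return BiomarkerScoreTable(table, n_tumor, n_normal, thr)


def quartile_filter(scores: BiomarkerScoreTable,
                    fraction: float = 0.25) -> tuple[str, ...]:
    """Genes in the top ``fraction`` of scores (descending), boundary ties kept.

    The lower bound is the (1 - fraction) linear-interpolation quantile of all
    scores; genes with score >= bound survive.
    """
    s = scores.table["score"]
    if len(s) < 4:
        raise ValidationError("need at least 4 scored genes for a quartile cut")
    bound = float(np.quantile(s.to_numpy(), 1.0 - fraction))
    return tuple(s.index[s >= bound])


def intersect_candidates(sets: Sequence[CandidateSet]) -> CandidateSet:
    """Set intersection with provenance union."""
    if not sets:
        raise ValidationError("cannot intersect an empty list of candidate sets")
    genes = frozenset.intersection(*(s.gene_ids for s in sets))
    prov = {"intersected": [s.provenance for s in sets]}
    return CandidateSet(genes, prov)


# ---------------------------------------------------------------------------
# end-to-end discovery


@dataclasses.dataclass(frozen=True)
class DiscoveryConfig:
    """Configuration of the full discovery run.

    Defaults mirror the full-scale design (1000 iterations at ratio 1:6,
    frequency cutoffs 950/750, tail widths 5%/1%/0.5%, quartile cut); the
    desk-scale knobs are the iteration and sample-set counts.
    """

    n_iterations: int = 1000
    ratio: int = 6
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    freq_thresholds: tuple[int, ...] = (950, 750)
    dispersion: float | str = "estimate"
    q_tails: tuple[float, ...] = (0.05, 0.01, 0.005)
    threshold_mode: str = "share"  # "share" | "pooled_quantile"
    log_scale: bool = True  # log2(1+n) before min-max scaling
    n_sample_sets: int = 5
    quartile_fraction: float = 0.25
    schedule: vaejmlp.TrainingSchedule = vaejmlp.TrainingSchedule(batch_size=64)
    attribution: AttributionConfig = AttributionConfig(n_background=64)
    arch: vaejmlp.ArchitectureSpec | None = None  # None: auto-scaled widths
    seed: int = 0

    def validate(self):
        if any(t > self.n_iterations for t in self.freq_thresholds):
            raise ValidationError("frequency thresholds exceed n_iterations")
        if any(not (0 < q < 0.5) for q in self.q_tails):
            raise ValidationError("tail fractions must lie in (0, 0.5)")
        if self.threshold_mode not in ("share", "pooled_quantile"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")
        self.schedule.validate()


def run_discovery(counts: CountMatrix, labels: LabelVector,
                  config: DiscoveryConfig) -> BiomarkerResult:
    """Stability DE -> per-feature-set model training -> attribution ->
    scoring -> quartile cut -> intersection across tails, sample sets, and
    feature configurations.

    Deterministic under ``config.seed``: every stage seed is spawned from it.
    """
    config.validate()
    labels.require_both_classes()
    root = np.random.SeedSequence(config.seed)
    seed_de, seed_sets, seed_train = (int(s.generate_state(1)[0] % (2 ** 31))
                                      for s in root.spawn(3))

    plan = de.make_resampling_plan(labels, config.n_iterations, config.ratio,
                                   seed_de)
    freq = de.run_stability(counts, labels, plan, config.lfc_threshold,
                            config.p_threshold, config.dispersion)
    feature_sets = de.build_feature_sets(freq, list(config.freq_thresholds))

    # sample sets for model training: same draw design as the DE resampling
    sample_plan = de.make_resampling_plan(labels, config.n_sample_sets,
                                          config.ratio, seed_sets)

    candidate_sets: list[CandidateSet] = []
    run_log: list[dict] = []
    for f_idx, fs in enumerate(feature_sets):
        if not fs.gene_ids:
            run_log.append({"feature_set": fs.name, "skipped": "empty"})
            continue
        sub_counts = counts.subset_genes(list(fs.gene_ids))
        for s_idx in range(config.n_sample_sets):
            ids = sample_plan.sample_ids(s_idx)
            run_counts = sub_counts.subset_samples(ids)
            run_labels = LabelVector(tuple(ids), labels.for_samples(ids))
            run_seed = int(np.random.SeedSequence(
                [seed_train, s_idx, f_idx]
            ).generate_state(1)[0] % (2 ** 31))

            # weight init is pinned to the top-level seed so that runs vary
            # only in their data (the axis the resampling design intends)
            sched = dataclasses.replace(config.schedule, seed=run_seed,
                                        init_seed=config.seed)
            train_ids, test_ids = vaejmlp.stratified_split(
                run_labels, sched.test_fraction, run_seed)
            scaled = minmax_scale(run_counts, train_ids, log2=config.log_scale)
            arch = (config.arch if config.arch is not None
                    else vaejmlp.ArchitectureSpec.scaled(len(fs.gene_ids)))
            model = vaejmlp.train(scaled, run_labels, arch, sched,
                                  split=(train_ids, test_ids))

            attr_cfg = dataclasses.replace(config.attribution, seed=run_seed)
            attr = attribute(model, scaled, background=train_ids,
                             config=attr_cfg)

            if config.threshold_mode == "share":
                attr_for_scoring = contribution_shares(attr)
            else:
                attr_for_scoring = attr
            per_tail = []
            for q in config.q_tails:
                thr = (share_thresholds(q) if config.threshold_mode == "share"
                       else compute_thresholds(attr_for_scoring, q))
                table = score_genes(attr_for_scoring, run_labels, thr)
                if len(table.table) < 4:  # degenerate tiny feature set
                    kept = tuple(table.table.index)
                else:
                    kept = quartile_filter(table, config.quartile_fraction)
                per_tail.append(CandidateSet(
                    frozenset(kept),
                    {"feature_set": fs.name, "sample_set": s_idx, "q": q}))
            cand = intersect_candidates(per_tail)
            cand = CandidateSet(cand.gene_ids,
                                {"feature_set": fs.name, "sample_set": s_idx,
                                 "tails": list(config.q_tails)})
            candidate_sets.append(cand)
            run_log.append({"feature_set": fs.name, "sample_set": s_idx,
                            "n_features": len(fs.gene_ids),
                            "n_candidates": len(cand.gene_ids),
                            "metrics": model.metrics})

    if not candidate_sets:
        raise ValidationError("no non-empty feature sets; nothing to intersect")
    final = intersect_candidates(candidate_sets)
    provenance = {
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "freq_thresholds": list(config.freq_thresholds),
        "q_tails": list(config.q_tails),
        "feature_set_sizes": {fs.name: len(fs.gene_ids) for fs in feature_sets},
        "runs": run_log,
    }
    return BiomarkerResult(tuple(sorted(final.gene_ids)),
                           tuple(candidate_sets), provenance)
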