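"""Synthetic RNA-seq cohorts with planted differential genes and biomarkers.

Counts are negative-binomial, ``var = mu + phi * mu^2``, with log-normal
per-gene baseline means and log-normal library-size factors.  A subset of
genes is differential between tumor and normal; within those, a sub-subset of
"consistent" biomarkers carries its fold-change in every tumor sample
(penetrance 1), while the remaining differential genes are heterogeneous —
only a configurable fraction of tumor samples are carriers.  That contrast is
what downstream consistency-rewarding scores must be able to resolve, so the
full ground truth (differential genes, biomarkers, per-sample carrier
indicators, library sizes) is recorded.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import CountMatrix, LabelVector, SurvivalTable, ValidationError


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small discovery cohort: 2000 genes, 10 normal and 60
    tumor samples, 200 differential genes with log2 fold-changes in [1.5, 3]
    of which 20 are fully penetrant biomarkers; the other 180 are carried by
    ~30% of tumors.  Baseline means are log-normal (ln-scale mean 4, sd 1,
    i.e. a median of ~55 reads), dispersion phi = 0.2, library-size CV 0.2.
    """

    n_genes: int = 2000
    n_normal: int = 10
    n_tumor: int = 60
    seed: int = 0
    baseline_logmean_dist: tuple[float, float] = (4.0, 1.0)  # ln-scale (mu, sigma)
    dispersion: float = 0.2  # phi in var = mu + phi mu^2
    n_de: int = 200
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_biomarkers: int = 20
    heterogeneous_penetrance: float = 0.3
    libsize_cv: float = 0.2

    def validate(self):
        if not (0 <= self.n_biomarkers <= self.n_de <= self.n_genes):
            raise ValidationError(
                "need n_biomarkers <= n_de <= n_genes, got "
                f"{self.n_biomarkers} / {self.n_de} / {self.n_genes}")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not (0 < self.heterogeneous_penetrance <= 1):
            raise ValidationError("penetrance must lie in (0, 1]")
        if self.n_normal < 1 or self.n_tumor < 1:
            raise ValidationError("need at least one sample per class")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    de_gene_ids: tuple[str, ...]
    biomarker_gene_ids: tuple[str, ...]
    log2fc: dict[str, float]  # per DE gene; signed
    carriers: dict[str, tuple[str, ...]]  # DE gene -> tumor samples carrying the shift
    library_size_factors: dict[str, float]

    def __post_init__(self):
        if not set(self.biomarker_gene_ids) <= set(self.de_gene_ids):
            raise ValidationError("biomarkers must be a subset of DE genes")

    def null_gene_ids(self, all_gene_ids) -> set[str]:
        """Genes with no planted class difference (complement of the DE set)."""
        return set(all_gene_ids) - set(self.de_gene_ids)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    # NB with var = mu + phi mu^2 <=> shape r = 1/phi, p = r / (r + mu)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimulationConfig
                    ) -> tuple[CountMatrix, LabelVector, SyntheticTruth]:
    """Draw a tumor/normal count matrix under the configured conditions.

    Tumor carrier samples of a differential gene have mean ``mu * 2**log2fc``
    (signs alternate so both up- and down-regulated genes occur); all other
    entries keep the baseline mean.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_normal + config.n_tumor
    gene_ids = tuple(f"G{i:05d}" for i in range(config.n_genes))
    sample_ids = tuple([f"N{i:03d}" for i in range(config.n_normal)]
                       + [f"T{i:03d}" for i in range(config.n_tumor)])
    labels = LabelVector(sample_ids,
                         np.r_[np.zeros(config.n_normal), np.ones(config.n_tumor)])

    mu_ln, sd_ln = config.baseline_logmean_dist
    base_mean = rng.lognormal(mu_ln, sd_ln, size=config.n_genes)

    # library-size factors: log-normal with unit mean and stated CV
    if config.libsize_cv > 0:
        s2 = np.log1p(config.libsize_cv ** 2)
        libsize = rng.lognormal(-s2 / 2, np.sqrt(s2), size=n)
    else:
        libsize = np.ones(n)

    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    bm_idx = de_idx[:config.n_biomarkers]
    lo, hi = config.de_log2fc_range
    mag = rng.uniform(lo, hi, size=config.n_de)
    sign = rng.choice([-1.0, 1.0], size=config.n_de)
    log2fc = mag * sign

    tumor_cols = np.arange(config.n_normal, n)
    mean = np.broadcast_to(base_mean[:, None], (config.n_genes, n)).copy()
    carriers: dict[str, tuple[str, ...]] = {}
    bm_set = set(bm_idx.tolist())
    for k, g in enumerate(de_idx):
        pen = 1.0 if g in bm_set else config.heterogeneous_penetrance
        n_carrier = max(1, int(round(pen * config.n_tumor)))
        carrier_cols = rng.choice(tumor_cols, size=n_carrier, replace=False)
        mean[g, carrier_cols] = base_mean[g] * 2.0 ** log2fc[k]
        carriers[gene_ids[g]] = tuple(sorted(sample_ids[c] for c in carrier_cols))

    counts = _nb_draw(rng, mean * libsize[None, :], config.dispersion)
    truth = SyntheticTruth(
        de_gene_ids=tuple(gene_ids[g] for g in de_idx),
        biomarker_gene_ids=tuple(gene_ids[g] for g in bm_idx),
        log2fc={gene_ids[g]: float(f) for g, f in zip(de_idx, log2fc)},
        carriers=carriers,
        library_size_factors=dict(zip(sample_ids, libsize.astype(float))),
    )
    return CountMatrix(counts, gene_ids, sample_ids), labels, truth


@dataclasses.dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    effect: float = 0.0  # log-hazard per SD of risk score
    censor_rate: float = 0.3
    seed: int = 0


def simulate_survival(risk_scores: np.ndarray, sample_ids: list[str],
                      config: SurvivalConfig) -> SurvivalTable:
    """Exponential event times with hazard proportional to exp(effect * z-score).

    Censoring is independent: each sample is censored with probability
    ``censor_rate``, in which case the recorded time is uniform on (0, t_event).
    """
    scores = np.asarray(risk_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValidationError("risk scores must be finite")
    if scores.shape != (len(sample_ids),):
        raise ValidationError("one score per sample required")
    rng = np.random.default_rng(config.seed)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    hazard = config.baseline_hazard * np.exp(config.effect * z)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(scores)) < config.censor_rate
    time = np.where(censored, rng.uniform(0, t_event), t_event)
    event = (~censored).astype(int)
    return SurvivalTable(tuple(sample_ids), time, event)
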