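"""Stability-resampled negative-binomial differential expression.

The selection design: draw many tumor subsamples at a fixed tumor:normal
ratio (every normal sample enters every draw), run an NB exact test per draw,
count how often each gene clears ``|log2FC| > 1`` and ``p < 0.05``, and keep
genes whose significance frequency exceeds stated cutoffs.

The test itself is the conditional exact test for overdispersed counts: given
two groups of NB-distributed counts with common dispersion phi and a shared
mean under the null, the group-A total S_A given the grand total T = t has a
computable conditional distribution (group sums of i.i.d. NB(mu, phi) are
NB(n*mu, phi/n)).  The two-sided p-value doubles the smaller tail, observed
point included, capped at 1.  Library sizes are equalized by scaling each
sample to the geometric-mean library size ("pseudo-counts", rounded back to
integers); the common dispersion is a method-of-moments estimate across genes
(floor 1e-4) unless a fixed phi is supplied.  Numerical identity with
empirical-Bayes GLM packages is not claimed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .data_model import CountMatrix, LabelVector, ValidationError

_DISPERSION_FLOOR = 1e-4
_TAIL_SD_WINDOW = 60.0  # conditional-support truncation, mass beyond is ~0


@dataclasses.dataclass(frozen=True)
class ResamplingPlan:
    """Reproducible tumor subsampling design; normals are never subsampled."""

    normal_ids: tuple[str, ...]
    tumor_pool_ids: tuple[str, ...]
    ratio: int
    seed: int
    iterations: tuple[tuple[str, ...], ...]  # drawn tumor ids per iteration

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def sample_ids(self, iteration: int) -> list[str]:
        return list(self.normal_ids) + list(self.iterations[iteration])


@dataclasses.dataclass(frozen=True)
class FrequencyTable:
    """Per-gene count of iterations in which the gene was significant."""

    gene_ids: tuple[str, ...]
    frequency: np.ndarray
    n_iterations: int

    def __post_init__(self):
        freq = np.asarray(self.frequency, dtype=np.int64)
        if (freq < 0).any() or (freq > self.n_iterations).any():
            raise ValidationError("frequencies must lie in [0, n_iterations]")
        object.__setattr__(self, "frequency", freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.gene_ids),
                             "frequency": self.frequency})


@dataclasses.dataclass(frozen=True)
class FeatureSet:
    name: str
    gene_ids: tuple[str, ...]
    threshold: int  # minimum frequency; 1 for the "All" set


def make_resampling_plan(labels: LabelVector, n_iterations: int, ratio: int,
                         seed: int) -> ResamplingPlan:
    """Plan ``n_iterations`` draws of ``ratio * n_normal`` tumors (no replacement
    within a draw), with every normal sample included in every draw."""
    labels.require_both_classes()
    normals = labels.normal_ids
    tumors = labels.tumor_ids
    n_draw = ratio * len(normals)
    if len(tumors) < n_draw:
        raise ValidationError(
            f"tumor pool has {len(tumors)} samples but ratio {ratio} with "
            f"{len(normals)} normals requires {n_draw}")
    rng = np.random.default_rng(seed)
    tumors = np.array(tumors)
    iters = tuple(tuple(rng.choice(tumors, size=n_draw, replace=False))
                  for _ in range(n_iterations))
    return ResamplingPlan(tuple(normals), tuple(labels.tumor_ids), ratio, seed, iters)


def _estimate_common_dispersion(pseudo: np.ndarray, n_a: int) -> float:
    """Method-of-moments common phi from within-group moments of pseudo-counts."""
    a, b = pseudo[:, :n_a], pseudo[:, n_a:]
    phis = []
    for grp in (a, b):
        if grp.shape[1] < 2:
            continue
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        ok = m > 0
        phis.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not phis:
        return _DISPERSION_FLOOR
    pooled = np.concatenate(phis)
    return float(max(np.median(pooled), _DISPERSION_FLOOR))


def _conditional_two_sided_p(s_obs: int, t: int, n_a: int, n_b: int,
                             phi: float) -> float:
    """P-value of S_A = s_obs given S_A + S_B = t under the null common mean."""
    mu = t / (n_a + n_b)  # per-sample null mean
    # group sums: S_A ~ NB(size n_a/phi, mean n_a*mu), same for B
    r_a, r_b = n_a / phi, n_b / phi
    mean_a, mean_b = n_a * mu, n_b * mu
    # truncate support to a generous window around the conditional mean
    cond_mean = t * n_a / (n_a + n_b)
    var_a = mean_a * (1 + phi * mu)
    half = _TAIL_SD_WINDOW * np.sqrt(max(var_a, 1.0))
    lo = int(max(0, min(np.floor(cond_mean - half), s_obs)))
    hi = int(min(t, max(np.ceil(cond_mean + half), s_obs)))
    s = np.arange(lo, hi + 1)
    logp = (nbinom.logpmf(s, r_a, r_a / (r_a + mean_a))
            + nbinom.logpmf(t - s, r_b, r_b / (r_b + mean_b)))
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    k = s_obs - lo
    lower = pmf[: k + 1].sum()
    upper = pmf[k:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_exact_test(counts: CountMatrix, group_a: Sequence[str],
                  group_b: Sequence[str],
                  dispersion: float | str = "estimate") -> pd.DataFrame:
    """Per-gene NB exact test of group A vs group B.

    Returns a frame indexed by gene with columns ``log2fc`` (A over B, on
    normalized means with pseudo-count 0.5), ``pvalue``, and ``zero_total``
    flagging genes with no reads in either group (reported as p = 1, lfc = 0).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    sub = counts.subset_samples(group_a + group_b)
    n_a, n_b = len(group_a), len(group_b)
    x = sub.values.astype(float)

    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("sample with zero library size")
    common = np.exp(np.mean(np.log(lib)))
    pseudo = np.rint(x * (common / lib)[None, :]).astype(np.int64)

    phi = (_estimate_common_dispersion(pseudo, n_a)
           if dispersion == "estimate" else float(dispersion))
    if phi <= 0:
        raise ValidationError("dispersion must be positive")

    s_a = pseudo[:, :n_a].sum(axis=1)
    s_b = pseudo[:, n_a:].sum(axis=1)
    t = s_a + s_b
    mean_a = s_a / n_a
    mean_b = s_b / n_b
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    pvals = np.ones(sub.n_genes)
    for g in range(sub.n_genes):
        if t[g] == 0:
            continue
        pvals[g] = _conditional_two_sided_p(int(s_a[g]), int(t[g]), n_a, n_b, phi)
    zero = t == 0
    log2fc[zero] = 0.0
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals, "zero_total": zero},
                        index=list(sub.gene_ids))


def run_stability(counts: CountMatrix, labels: LabelVector, plan: ResamplingPlan,
                  lfc_threshold: float = 1.0, p_threshold: float = 0.05,
                  dispersion: float | str = "estimate") -> FrequencyTable:
    """Run the exact test per planned draw and count per-gene significance.

    Group A is the drawn tumor set, group B the full normal set, so positive
    log2FC means up-regulation in tumors.
    """
    freq = np.zeros(counts.n_genes, dtype=np.int64)
    for it in range(plan.n_iterations):
        res = nb_exact_test(counts, list(plan.iterations[it]),
                            list(plan.normal_ids), dispersion=dispersion)
        sig = (res["log2fc"].abs() > lfc_threshold) & (res["pvalue"] < p_threshold)
        freq += sig.to_numpy()
    return FrequencyTable(counts.gene_ids, freq, plan.n_iterations)


def build_feature_sets(freq: FrequencyTable,
                       thresholds: Sequence[int]) -> list[FeatureSet]:
    """The "All" (ever-significant) set plus one ``Freq>=t`` set per threshold."""
    order = np.asarray(freq.frequency)
    all_genes = tuple(g for g, f in zip(freq.gene_ids, order) if f >= 1)
    sets = [FeatureSet("All", all_genes, 1)]
    for thr in thresholds:
        genes = tuple(g for g, f in zip(freq.gene_ids, order) if f >= thr)
        if not genes:
            warnings.warn(f"feature set Freq>={thr} is empty")
        sets.append(FeatureSet(f"Freq>={thr}", genes, int(thr)))
    return sets
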