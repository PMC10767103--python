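"""Gene-signature risk scores, median-split risk groups, and survival tests.

The risk score is the linear predictor of a Cox model restricted to the
signature genes:

    RiskScore(sample) = sum_i Coef_i * Expr_i(sample)

Samples are split at the median score into High (> median) and Low
(<= median) risk groups, compared with the two-group log-rank test.  Cox
coefficient estimation itself is delegated to lifelines' proportional-hazards
solver; this module owns the score, the grouping rule, and the comparison.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_model import SurvivalTable, ValidationError


@dataclasses.dataclass(frozen=True)
class RiskModel:
    """Signature genes with their regression coefficients."""

    gene_ids: tuple[str, ...]
    coefficients: np.ndarray
    expression_source: str = "normalized_counts"

    def __post_init__(self):
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (len(self.gene_ids),):
            raise ValidationError("one coefficient per signature gene required")
        if not np.isfinite(coefs).all():
            raise ValidationError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


@dataclasses.dataclass(frozen=True)
class RiskGroups:
    sample_ids: tuple[str, ...]
    scores: np.ndarray
    median: float
    group: tuple[str, ...]  # "High" | "Low" per sample

    @property
    def high_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == "High"]

    @property
    def low_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == "Low"]


def risk_score(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Per-sample weighted sum of signature-gene expression.

    ``expr`` is genes x samples on the scale named by
    ``model.expression_source``; all signature genes must be present.
    """
    missing = set(model.gene_ids) - set(expr.index)
    if missing:
        raise ValidationError(f"signature genes absent from expression: "
                              f"{sorted(missing)}")
    sub = expr.loc[list(model.gene_ids)].to_numpy(dtype=float)
    return pd.Series(model.coefficients @ sub, index=expr.columns,
                     name="risk_score")


def median_split(scores: pd.Series) -> RiskGroups:
    """High if score > median, Low otherwise (ties at the median go Low)."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 samples to split")
    med = float(np.median(scores.to_numpy()))
    group = tuple("High" if s > med else "Low" for s in scores)
    if "High" not in group:
        warnings.warn("all scores at or below the median; High group is empty")
    return RiskGroups(tuple(str(i) for i in scores.index),
                      scores.to_numpy(dtype=float), med, group)


def logrank_test(groups: RiskGroups, surv: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value, High vs Low."""
    lut = {s: (t, e) for s, t, e in zip(surv.sample_ids, surv.time, surv.event)}
    high = [lut[s] for s in groups.high_ids]
    low = [lut[s] for s in groups.low_ids]
    if not high or not low:
        raise ValidationError("both risk groups must be non-empty")
    res = _ll_logrank(
        durations_A=[t for t, _ in high], durations_B=[t for t, _ in low],
        event_observed_A=[e for _, e in high], event_observed_B=[e for _, e in low])
    return float(res.test_statistic), float(res.p_value)


def fit_cox(expr: pd.DataFrame, surv: SurvivalTable, genes: Sequence[str],
            mode: str = "multivariate") -> pd.DataFrame:
    """Cox proportional-hazards fit via lifelines.

    ``univariate`` fits each gene separately; ``multivariate`` fits them
    jointly.  Returns a frame indexed by gene with columns ``coef``,
    ``hazard_ratio``, ``pvalue``, ``converged``.
    """
    genes = list(genes)
    missing = set(genes) - set(expr.index)
    if missing:
        raise ValidationError(f"genes absent from expression: {sorted(missing)}")
    base = pd.DataFrame({"time": surv.time, "event": surv.event},
                        index=list(surv.sample_ids))

    def _fit(cols: list[str]) -> pd.DataFrame | None:
        df = base.join(expr.loc[cols].T.loc[list(surv.sample_ids)])
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            return None
        return cph.summary

    rows = []
    if mode == "univariate":
        for g in genes:
            summary = _fit([g])
            rows.append(_summary_row(g, summary))
    elif mode == "multivariate":
        summary = _fit(genes)
        for g in genes:
            rows.append(_summary_row(g, summary))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).set_index("gene")


def _summary_row(gene: str, summary: pd.DataFrame | None) -> dict:
    if summary is None or gene not in summary.index:
        return {"gene": gene, "coef": np.nan, "hazard_ratio": np.nan,
                "pvalue": np.nan, "converged": False}
    row = summary.loc[gene]
    return {"gene": gene, "coef": float(row["coef"]),
            "hazard_ratio": float(row["exp(coef)"]),
            "pvalue": float(row["p"]), "converged": True}


def read_risk_model(path) -> RiskModel:
    df = pd.read_csv(path, sep="\t")
    return RiskModel(tuple(str(g) for g in df.iloc[:, 0]),
                     df.iloc[:, 1].to_numpy(float))


def write_risk_model(model: RiskModel, path):
    pd.DataFrame({"gene_id": list(model.gene_ids),
                  "coefficient": model.coefficients}
                 ).to_csv(path, sep="\t", index=False)
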