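"""Core data containers and I/O for count matrices, labels, and survival data.

The on-disk convention is genes-as-rows (the usual transcriptomics layout):
TSV/CSV files carry a header row of sample identifiers and a first column of
gene identifiers.  MatrixMarket triplets are supported with companion
one-id-per-line gene and sample files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    values: np.ndarray  # (n_genes, n_samples) integer
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError(f"count matrix must be 2-D, got {values.ndim}-D")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {values.shape} inconsistent with {len(self.gene_ids)} genes "
                f"x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        neg = np.argwhere(values < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                frac = np.argwhere(values != np.round(values))
                g, s = frac[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            values = values.astype(np.int64)
        object.__setattr__(self, "values", np.ascontiguousarray(values))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CountMatrix(self.values[idx], tuple(gene_ids), self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.values[:, idx], self.gene_ids, tuple(sample_ids))


@dataclasses.dataclass(frozen=True)
class LabelVector:
    """Binary per-sample labels: 0 = normal, 1 = tumor."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray  # (n_samples,) in {0,1}

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.shape != (len(self.sample_ids),):
            raise ValidationError("one label required per sample")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be 0 (normal) or 1 (tumor)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s, y in zip(self.sample_ids, self.labels) if y == 1]

    @property
    def normal_ids(self) -> list[str]:
        return [s for s, y in zip(self.sample_ids, self.labels) if y == 0]

    def for_samples(self, sample_ids: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.sample_ids, self.labels))
        return np.array([lut[s] for s in sample_ids], dtype=np.int64)

    def require_both_classes(self):
        if len(self.tumor_ids) == 0 or len(self.normal_ids) == 0:
            raise ValidationError("both classes (tumor and normal) must be present")


@dataclasses.dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = death observed)."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=np.int64)
        if time.shape != (len(self.sample_ids),) or event.shape != time.shape:
            raise ValidationError("time and event must align with sample_ids")
        if (time < 0).any():
            raise ValidationError("survival times must be non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValidationError("event must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))


@dataclasses.dataclass(frozen=True)
class ScaledMatrix:
    """Per-gene min-max scaled expression in [0, 1], genes x samples.

    Scaling parameters are derived from the training partition only; values
    from other samples are clipped into [0, 1].  A Bernoulli decoder's binary
    cross-entropy requires inputs on this scale.
    """

    values: np.ndarray  # (n_genes, n_samples) float in [0, 1]
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    train_min: np.ndarray  # per gene
    train_max: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any() or (v > 1).any():
            raise ValidationError("scaled values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def sample_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Samples x genes array (the orientation the neural stage consumes)."""
        if sample_ids is None:
            return self.values.T.copy()
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.values[:, idx].T.copy()


def minmax_scale(counts: CountMatrix, train_samples: Sequence[str],
                 log2: bool = False) -> ScaledMatrix:
    """Per-gene min-max scaling to [0, 1] with parameters from the training split.

    With ``log2=True`` counts are first transformed to log2(1 + n), the usual
    variance-compressing step before feeding expression to a neural network.
    Constant genes (train max == train min) map to 0 everywhere; samples outside
    the training split are clipped into [0, 1].
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValidationError("training partition must be non-empty")
    missing = set(train_samples) - set(counts.sample_ids)
    if missing:
        raise ValidationError(f"training samples not in matrix: {sorted(missing)}")
    idx = [counts.sample_ids.index(s) for s in train_samples]
    x = counts.values.astype(float)
    if log2:
        x = np.log2(1.0 + x)
    lo = x[:, idx].min(axis=1)
    hi = x[:, idx].max(axis=1)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((x - lo[:, None]) / safe[:, None], 0.0, 1.0)
    scaled[span == 0, :] = 0.0
    return ScaledMatrix(scaled, counts.gene_ids, counts.sample_ids, lo, hi)


# ---------------------------------------------------------------------------
# I/O


def _check_numeric(df: pd.DataFrame, path: str):
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValidationError(
                f"{path}: malformed numeric cell at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in count matrix")


def read_count_matrix(path: str | Path, fmt: str | None = None,
                      transpose: bool = False) -> CountMatrix:
    """Read a count matrix from TSV, CSV, or MatrixMarket triplet.

    Parameters
    ----------
    path
        Matrix file.  For ``mtx`` the companion files ``<stem>.genes.txt`` and
        ``<stem>.samples.txt`` must sit next to it.
    fmt
        ``tsv``, ``csv`` or ``mtx``; inferred from the suffix when omitted.
    transpose
        Set when the file stores samples as rows.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValidationError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        genes = Path(str(path)[: -len(path.suffix)] + ".genes.txt")
        samples = Path(str(path)[: -len(path.suffix)] + ".samples.txt")
        if not genes.exists() or not samples.exists():
            raise ValidationError(f"companion id files missing for {path}")
        gene_ids = genes.read_text().split()
        sample_ids = samples.read_text().split()
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        _check_numeric(df, str(path))
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
    if transpose:
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids
    return CountMatrix(values, tuple(gene_ids), tuple(sample_ids))


def write_count_matrix(counts: CountMatrix, path: str | Path, fmt: str | None = None):
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv")
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.values))
        stem = str(path)[: -len(path.suffix)] if path.suffix else str(path)
        Path(stem + ".genes.txt").write_text("\n".join(counts.gene_ids) + "\n")
        Path(stem + ".samples.txt").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        counts.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns sample_id, label")
    return LabelVector(tuple(str(s) for s in df.iloc[:, 0]),
                       df.iloc[:, 1].to_numpy())


def write_labels(labels: LabelVector, path: str | Path):
    pd.DataFrame({"sample_id": list(labels.sample_ids),
                  "label": labels.labels}).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected columns sample_id, time, event")
    return SurvivalTable(tuple(str(s) for s in df.iloc[:, 0]),
                         df.iloc[:, 1].to_numpy(float),
                         df.iloc[:, 2].to_numpy())


def write_survival(surv: SurvivalTable, path: str | Path):
    pd.DataFrame({"sample_id": list(surv.sample_ids), "time": surv.time,
                  "event": surv.event}).to_csv(path, sep="\t", index=False)
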