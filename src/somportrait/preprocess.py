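"""Expression-table I/O, normalization, filtering and batch adjustment.

The preprocessing chain mirrors the two presets used downstream:

* ``cllmap``   : ComBat (per-cohort batch) on TPM -> log2(TPM+1) -> sample-wise
  quantile normalization -> gene-wise centering. This is the input scale the
  self-organizing map expects (gene profiles centered on the cohort mean).
* ``harmonize``: low-expression filter on each dataset -> gene intersection ->
  merge -> ComBat (dataset as batch) -> quantile normalization. This is the
  scale shared by a dense reference cohort and a sparse companion cohort before
  projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

Scale = Literal["counts", "tpm", "log2tpm", "normalized"]

_TPM_SUM = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    scale
        One of ``counts``, ``tpm``, ``log2tpm``, ``normalized``.
    gene_lengths
        Optional per-gene length in kilobases; required only for
        :func:`counts_to_tpm`.
    strict_tpm
        When True and ``scale == "tpm"``, verify each column sums to 1e6
        (within 1e-3 relative tolerance). Gene filtering and batch adjustment
        legitimately break that sum, so they construct with ``strict_tpm=False``.
    """

    values: pd.DataFrame
    scale: Scale
    gene_lengths: Optional[pd.Series] = None
    strict_tpm: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [(g, s) for g in v.index for s in v.columns
                   if not np.isreal(v.at[g, s])]
            raise ValueError(f"non-numeric cells at {bad[:5]}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.scale == "counts" and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.scale == "tpm" and self.strict_tpm and arr.shape[0] > 0:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, _TPM_SUM, rtol=1e-3):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - _TPM_SUM)))]
                raise ValueError(
                    f"TPM columns must sum to 1e6; sample {bad!r} sums to "
                    f"{sums[self.sample_ids.index(bad)]:.4g}")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(v.index)

    # -- convenience ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: batch, clinical categoricals and survival columns."""

    table: pd.DataFrame  # indexed by sample_id

    BATCH = "batch"
    TIME = "time"
    EVENT = "event"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")
        t = self.table
        if self.TIME in t and self.EVENT in t:
            ev = t[self.EVENT].astype(float)
            missing_time = t[self.TIME].isna() & (ev == 1)
            if missing_time.any():
                raise ValueError(
                    f"events without survival time: {t.index[missing_time].tolist()}")
            if (t[self.TIME].dropna() < 0).any():
                raise ValueError("survival times must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def batch(self) -> pd.Series:
        return self.table[self.BATCH]

    def matches(self, m: ExpressionMatrix) -> bool:
        return set(self.sample_ids) >= set(m.sample_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, scale: Scale = "tpm",
                          samples_in_rows: bool = False,
                          sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes-x-samples table (first column = ``gene_id``).

    ``samples_in_rows=True`` transposes the table so the result is always
    genes x samples.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r}, rows {bad.tolist()[:5]}")
    if samples_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale, strict_tpm=False)


def write_expression_table(m: ExpressionMatrix, path: str | Path,
                           sep: str = "\t") -> None:
    m.values.to_csv(path, sep=sep, index_label="gene_id")


def read_annotation_table(path: str | Path, sep: str | None = None) -> SampleAnnotation:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col="sample_id")
    df.index = df.index.astype(str)
    return SampleAnnotation(df)


def write_annotation_table(ann: SampleAnnotation, path: str | Path,
                           sep: str = "\t") -> None:
    ann.table.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# Normalization steps
# ---------------------------------------------------------------------------

def counts_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million using gene lengths (kb)."""
    if m.scale != "counts":
        raise ValueError(f"expected counts, got scale={m.scale!r}")
    if m.gene_lengths is None:
        raise ValueError("gene_lengths (kb) required for counts -> TPM")
    lengths = m.gene_lengths.to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive and finite")
    counts = m.to_numpy()
    col_tot = counts.sum(axis=0)
    if np.any(col_tot == 0):
        bad = [s for s, t in zip(m.sample_ids, col_tot) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * _TPM_SUM
    return ExpressionMatrix(pd.DataFrame(tpm, index=m.values.index,
                                         columns=m.values.columns),
                            scale="tpm", gene_lengths=m.gene_lengths)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); input must be TPM-scale and non-negative."""
    if m.scale != "tpm":
        raise ValueError(f"expected tpm, got scale={m.scale!r}")
    arr = m.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log2(arr + 1.0)
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns),
                            scale="log2tpm", strict_tpm=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common mean-of-sorted-values vector.

    Ties within a column receive the mean of the target values spanned by
    their ranks, so tied inputs stay tied.
    """
    arr = m.to_numpy()
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return replace(m)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(n_samples):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n_genes)
        mapped[order] = reference
        # average the targets over each tied value group
        s = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns),
                            scale=m.scale, strict_tpm=False)


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample mean; output scale is 'normalized'."""
    if m.scale not in ("log2tpm", "normalized"):
        raise ValueError(f"center_genes expects log2tpm/normalized, got {m.scale!r}")
    arr = m.to_numpy()
    out = arr - arr.mean(axis=1, keepdims=True)
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns),
                            scale="normalized")


# ---------------------------------------------------------------------------
# ComBat batch adjustment (parametric empirical Bayes, no covariates)
# ---------------------------------------------------------------------------

def _combat_it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                   g_bar: float, t2: float, a: float, b: float,
                   conv: float = 1e-4, max_iter: int = 500
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled EB posterior-mode equations for one batch."""
    n = np.full(z.shape[0], z.shape[1], dtype=float)
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        sse = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sse + b) / (n / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-30)),
                     np.max(np.abs(d_new - d_old) / (d_old + 1e-30)))
        if change < conv:
            break
    return g_new, d_new


def combat_adjust(m: ExpressionMatrix, batches: pd.Series | list[str]
                  ) -> ExpressionMatrix:
    """Empirical-Bayes location/scale batch-effect adjustment.

    Each gene is standardized against its batch-free grand mean and pooled
    variance; per-batch additive and multiplicative effects are estimated and
    shrunk toward batch-level priors (normal prior for location, inverse-gamma
    for scale, moment-matched) before back-transformation. Genes with zero
    pooled variance pass through unadjusted with a warning.
    """
    arr = m.to_numpy()
    batch = pd.Series(batches, index=m.values.columns if isinstance(batches, list)
                      else None)
    if isinstance(batches, pd.Series):
        batch = batches.reindex(m.values.columns)
        if batch.isna().any():
            raise ValueError("batch labels missing for some samples")
    batch = batch.astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValueError("combat_adjust needs >=2 batches")
    groups = {b: np.flatnonzero(batch.to_numpy() == b) for b in levels}
    for b, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has <2 samples")

    n_samples = arr.shape[1]
    n_b = np.array([len(groups[b]) for b in levels], dtype=float)
    # batch means per gene, grand mean as the sample-size weighted average
    batch_mean = np.stack([arr[:, groups[b]].mean(axis=1) for b in levels], axis=1)
    grand_mean = batch_mean @ (n_b / n_samples)
    resid = arr.copy()
    for k, b in enumerate(levels):
        resid[:, groups[b]] -= batch_mean[:, [k]]
    var_pooled = (resid ** 2).sum(axis=1) / n_samples

    keep = var_pooled > 0
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} zero-variance gene(s) passed "
                      "through unadjusted")
    out = arr.astype(float).copy()
    if keep.any():
        sub = arr[keep]
        gm = grand_mean[keep]
        sd = np.sqrt(var_pooled[keep])
        z = (sub - gm[:, None]) / sd[:, None]
        adjusted = np.empty_like(z)
        for k, b in enumerate(levels):
            zb = z[:, groups[b]]
            g_hat = zb.mean(axis=1)
            d_hat = zb.var(axis=1, ddof=1)
            g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
            dm, dv = float(d_hat.mean()), float(d_hat.var(ddof=1))
            # inverse-gamma hyperparameters by moment matching
            a = (2.0 * dv + dm ** 2) / dv
            bprior = (dm * dv + dm ** 3) / dv
            g_star, d_star = _combat_it_sol(zb, g_hat, d_hat, g_bar, t2, a, bprior)
            adjusted[:, groups[b]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
        out[keep] = adjusted * sd[:, None] + gm[:, None]
    return ExpressionMatrix(pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns),
                            scale=m.scale, gene_lengths=m.gene_lengths,
                            strict_tpm=False)


# ---------------------------------------------------------------------------
# Filtering / harmonization
# ---------------------------------------------------------------------------

def filter_low_expression(m: ExpressionMatrix, tpm_floor: float = 2.0,
                          frac: float = 0.5) -> ExpressionMatrix:
    """Drop genes whose below-floor sample fraction reaches ``frac``.

    A gene is removed when at least ``frac`` of samples have TPM < ``tpm_floor``
    (boundary inclusive: exactly 50% below the floor removes the gene).
    """
    if m.scale != "tpm":
        raise ValueError(f"expected tpm, got scale={m.scale!r}")
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must be in (0, 1]")
    below = (m.to_numpy() < tpm_floor).mean(axis=1)
    kept = below < frac
    return ExpressionMatrix(m.values.loc[kept], scale="tpm",
                            gene_lengths=None if m.gene_lengths is None
                            else m.gene_lengths[kept],
                            strict_tpm=False)


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their sorted common gene set, same order."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("gene sets are disjoint: empty intersection")
    out_a = ExpressionMatrix(a.values.loc[common], scale=a.scale, strict_tpm=False)
    out_b = ExpressionMatrix(b.values.loc[common], scale=b.scale, strict_tpm=False)
    return out_a, out_b


def merge_cohorts(a: ExpressionMatrix, b: ExpressionMatrix
                  ) -> tuple[ExpressionMatrix, pd.Series]:
    """Column-concatenate two cohorts on an identical gene index.

    Returns the merged matrix and a per-sample dataset label usable as the
    ComBat batch variable in the harmonization preset.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("cohorts must share an identical gene index; "
                         "run intersect_genes first")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both cohorts: {sorted(overlap)[:5]}")
    merged = pd.concat([a.values, b.values], axis=1)
    labels = pd.Series(["a"] * a.n_samples + ["b"] * b.n_samples,
                       index=merged.columns, name="dataset")
    return ExpressionMatrix(merged, scale=a.scale, strict_tpm=False), labels
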