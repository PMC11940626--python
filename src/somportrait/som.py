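"""Batch self-organizing map for gene-expression portrayal.

Genes (rows of a centered expression matrix) are the data points; each point
lives in R^{n_samples}. Training clusters the genes onto a 2-D grid of
metagenes whose codebook vectors are mean expression profiles. A sample's
"portrait" is the column of the metagene matrix reshaped onto the grid: a
2-D map of that sample's co-expression-module activation.

The trainer is the deterministic batch variant: the codebook is initialized
on the plane spanned by the first two principal directions of the gene
profiles, and each epoch assigns every gene to its best-matching unit (BMU,
minimal Euclidean distance, ties broken toward the lowest row-major index)
and replaces each codebook vector by the Gaussian-neighborhood-weighted mean
of the assigned profiles. The neighborhood radius decays linearly from
max(rows, cols)/2 to 1 over the epochs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix


@dataclass(frozen=True)
class SOMGrid:
    """Rectangular metagene grid, (row, col) 0-based, row-major linearization."""

    rows: int = 50
    cols: int = 50

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows * self.cols < 4:
            raise ValueError("grid needs rows*cols >= 4")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def coords(self) -> np.ndarray:
        """(n_units, 2) array of (r, c) in linear order."""
        r, c = np.divmod(np.arange(self.n_units), self.cols)
        return np.stack([r, c], axis=1)

    def linear(self, r: int, c: int) -> int:
        return r * self.cols + c


@dataclass
class SOMModel:
    grid: SOMGrid
    codebook: np.ndarray                 # (n_units, n_samples)
    gene_to_metagene: pd.Series          # gene_id -> linear unit index
    sample_ids: list[str]
    gene_values: pd.DataFrame            # training matrix (genes x samples)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codebook.shape != (self.grid.n_units, len(self.sample_ids)):
            raise ValueError("codebook shape must be (n_units, n_samples)")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.gene_to_metagene.to_numpy(),
                           minlength=self.grid.n_units)

    # -- serialization -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {"rows": self.grid.rows, "cols": self.grid.cols,
                "sample_ids": self.sample_ids,
                "gene_ids": self.gene_to_metagene.index.tolist(),
                "training_meta": self.training_meta}
        np.savez_compressed(
            path, codebook=self.codebook,
            gene_to_metagene=self.gene_to_metagene.to_numpy(),
            gene_values=self.gene_values.to_numpy(),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            grid = SOMGrid(meta["rows"], meta["cols"])
            g2m = pd.Series(z["gene_to_metagene"], index=meta["gene_ids"])
            gene_values = pd.DataFrame(z["gene_values"], index=meta["gene_ids"],
                                       columns=meta["sample_ids"])
            return cls(grid, z["codebook"], g2m, meta["sample_ids"],
                       gene_values, meta["training_meta"])


@dataclass
class SamplePortrait:
    """One sample's metagene activation reshaped onto the grid."""

    sample_id: str
    values: np.ndarray                     # (rows, cols)
    mask: Optional[np.ndarray] = None      # True where the metagene is undefined

    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def valid(self) -> np.ndarray:
        """Boolean (rows, cols): cells that carry a defined value."""
        if self.mask is None:
            return np.ones_like(self.values, dtype=bool)
        return ~self.mask


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _pca_plane_init(x: np.ndarray, grid: SOMGrid, rng: np.random.Generator
                    ) -> np.ndarray:
    """Codebook on the plane of the first two principal directions.

    The grid's row axis spans +-2 SD along PC1 and the column axis along PC2;
    signs are fixed deterministically (largest-|loading| entry positive).
    """
    mean = x.mean(axis=0)
    xc = x - mean
    # two leading right singular vectors of the centered gene matrix
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    dirs = vt[:2].copy()
    for k in range(dirs.shape[0]):
        j = int(np.argmax(np.abs(dirs[k])))
        if dirs[k, j] < 0:
            dirs[k] *= -1
    sd = s[:2] / np.sqrt(max(x.shape[0] - 1, 1))
    if len(sd) < 2 or sd[1] == 0:  # degenerate second direction
        extra = rng.standard_normal(x.shape[1])
        extra -= extra @ dirs[0] * dirs[0]
        nrm = np.linalg.norm(extra)
        dirs = np.vstack([dirs[0], extra / (nrm if nrm else 1.0)])
        sd = np.array([sd[0], sd[0] * 0.1 if sd[0] else 1.0])
    coords = SOMGrid(grid.rows, grid.cols).coords().astype(float)
    a = (coords[:, 0] / max(grid.rows - 1, 1) - 0.5) * 4 * sd[0]
    b = (coords[:, 1] / max(grid.cols - 1, 1) - 0.5) * 4 * sd[1]
    return mean + a[:, None] * dirs[0] + b[:, None] * dirs[1]


def _assign_bmu(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Row-wise argmin of Euclidean distance; np.argmin keeps the lowest index."""
    d2 = (np.einsum("ij,ij->i", x, x)[:, None]
          - 2.0 * x @ codebook.T
          + np.einsum("ij,ij->i", codebook, codebook)[None, :])
    return np.argmin(d2, axis=1)


def train_som(m: ExpressionMatrix, grid: SOMGrid | None = None,
              seed: int = 0, epochs: int = 20,
              radius_start: float | None = None, radius_end: float = 1.0
              ) -> SOMModel:
    """Train the batch SOM on gene profiles of a gene-centered matrix."""
    if m.scale != "normalized":
        warnings.warn(f"training on scale={m.scale!r}; gene-centered "
                      "('normalized') input is expected")
    grid = grid or SOMGrid()
    x = m.to_numpy()
    n_genes = x.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes to train")
    if n_genes < grid.n_units:
        warnings.warn(f"fewer genes ({n_genes}) than metagenes ({grid.n_units})")
    rng = np.random.default_rng(seed)
    codebook = _pca_plane_init(x, grid, rng)

    coords = grid.coords().astype(float)
    # squared grid distances between all unit pairs
    gd2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    if radius_start is None:
        radius_start = max(grid.rows, grid.cols) / 2.0
    radii = np.linspace(radius_start, radius_end, num=epochs)

    qe_history = []
    bmu = _assign_bmu(x, codebook)
    for radius in radii:
        h = np.exp(-gd2 / (2.0 * radius * radius))
        # per-unit sums of assigned profiles, then neighborhood smoothing
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, x)
        counts = np.bincount(bmu, minlength=grid.n_units).astype(float)
        num = h @ sums
        den = h @ counts
        nz = den > 0
        codebook[nz] = num[nz] / den[nz, None]
        bmu = _assign_bmu(x, codebook)
        qe = float(np.mean(np.linalg.norm(x - codebook[bmu], axis=1)))
        qe_history.append(qe)

    g2m = pd.Series(bmu, index=m.values.index, name="metagene")
    meta = {"seed": int(seed), "epochs": int(epochs),
            "radius_start": float(radius_start), "radius_end": float(radius_end),
            "neighborhood": "gaussian", "quantization_error": qe_history}
    return SOMModel(grid, codebook, g2m, m.sample_ids, m.values.copy(), meta)


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def best_matching_unit(model: SOMModel, profile: np.ndarray) -> int:
    """Metagene index nearest (Euclidean) to ``profile``; ties -> lowest index."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (model.n_samples,):
        raise ValueError(f"profile length {profile.shape} != n_samples "
                         f"({model.n_samples})")
    d2 = ((model.codebook - profile[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def metagene_matrix(model: SOMModel, empirical: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Metagene x sample matrix.

    With ``empirical=False`` this is the codebook. With ``empirical=True`` each
    metagene carries the mean profile of its assigned genes; empty metagenes
    fall back to the codebook value and are flagged in the returned boolean
    vector (True = empty).
    """
    if not empirical:
        return model.codebook.copy(), np.zeros(model.grid.n_units, dtype=bool)
    x = model.gene_values.to_numpy()
    bmu = model.gene_to_metagene.to_numpy()
    sums = np.zeros_like(model.codebook)
    np.add.at(sums, bmu, x)
    counts = np.bincount(bmu, minlength=model.grid.n_units).astype(float)
    empty = counts == 0
    out = model.codebook.copy()
    nz = ~empty
    out[nz] = sums[nz] / counts[nz, None]
    return out, empty


def portrait(model: SOMModel, sample_id: str) -> SamplePortrait:
    """Reshape one sample's metagene column onto the grid (row-major)."""
    if sample_id not in model.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    j = model.sample_ids.index(sample_id)
    vals = model.codebook[:, j].reshape(model.grid.rows, model.grid.cols)
    return SamplePortrait(sample_id, vals.copy())


def all_portraits(model: SOMModel) -> list[SamplePortrait]:
    return [portrait(model, s) for s in model.sample_ids]


def empirical_portrait(model: SOMModel, gene_values: pd.Series,
                       sample_id: str = "query") -> SamplePortrait:
    """Portrait of a profile not used in training.

    Each metagene takes the mean of ``gene_values`` over its member genes
    (restricted to genes the series provides); metagenes with no covered gene
    are masked. This is the direct (non-regression) mapping of a new sample
    through the trained gene->metagene assignment.
    """
    common = model.gene_to_metagene.index.intersection(gene_values.index)
    if len(common) == 0:
        raise ValueError("no overlap between profile genes and model genes")
    bmu = model.gene_to_metagene.loc[common].to_numpy()
    vals = gene_values.loc[common].to_numpy(dtype=float)
    sums = np.zeros(model.grid.n_units)
    np.add.at(sums, bmu, vals)
    counts = np.bincount(bmu, minlength=model.grid.n_units).astype(float)
    out = np.zeros(model.grid.n_units)
    covered = counts > 0
    out[covered] = sums[covered] / counts[covered]
    shape = (model.grid.rows, model.grid.cols)
    return SamplePortrait(sample_id, out.reshape(shape),
                          mask=~covered.reshape(shape))


def render_channels(p: SamplePortrait) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric diverging red/blue channels in [0, 1], per-portrait scaled.

    Values are divided by the maximum absolute value over unmasked cells;
    positive parts feed the red channel, negative parts the blue channel.
    Masked cells are 0 in both channels.
    """
    valid = p.valid()
    vals = np.where(valid, p.values, 0.0)
    vmax = np.max(np.abs(vals)) if valid.any() else 0.0
    if vmax == 0:
        zero = np.zeros_like(vals)
        return zero, zero.copy()
    scaled = vals / vmax
    red = np.clip(scaled, 0.0, None)
    blue = np.clip(-scaled, 0.0, None)
    return red, blue


def portrait_png(p: SamplePortrait, path: str | Path) -> None:
    """Write the maroon-to-blue heatmap of a portrait as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    red, blue = render_channels(p)
    rgb = np.ones(p.values.shape + (3,))
    rgb[..., 0] -= blue          # red channel attenuated where blue
    rgb[..., 1] -= 0.7 * (red + blue)
    rgb[..., 2] -= red
    rgb = np.clip(rgb, 0, 1)
    rgb[~p.valid()] = 1.0        # masked cells rendered white
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([]), ax.set_yticks([])
    ax.set_title(p.sample_id, fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
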