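"""Spot-module segmentation, PAT stratification and gene-set ORA.

On a trained SOM the perturbed metagenes aggregate into contiguous grid
regions ("spots") that behave as co-expressed gene modules. Samples are then
stratified into pattern types (PATs): a PAT is the combination of spots
active (above the cohort mean) in a sample's portrait.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .som import SamplePortrait, SOMModel


@dataclass
class Spot:
    label: str
    metagene_cells: set[tuple[int, int]]
    genes: set[str]

    @property
    def n_cells(self) -> int:
        return len(self.metagene_cells)


@dataclass
class SpotSegmentation:
    spots: list[Spot]
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        all_cells: set[tuple[int, int]] = set()
        for s in self.spots:
            if not s.metagene_cells:
                raise ValueError(f"spot {s.label} is empty")
            if all_cells & s.metagene_cells:
                raise ValueError("spots overlap in cells")
            all_cells |= s.metagene_cells
        labels = [s.label for s in self.spots]
        if labels != list(string.ascii_uppercase[:len(labels)]):
            raise ValueError("spot labels must be consecutive letters A, B, ...")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spots]

    def label_map(self) -> np.ndarray:
        """Grid of spot indices (-1 = background)."""
        out = np.full(self.grid_shape, -1, dtype=int)
        for i, s in enumerate(self.spots):
            for (r, c) in s.metagene_cells:
                out[r, c] = i
        return out


@dataclass
class SpotExpressionTable:
    """Samples x spots mean metagene values and the derived activation calls."""

    values: pd.DataFrame                      # samples x spot labels
    activation: pd.DataFrame | None = None    # boolean, same shape


@dataclass
class PATAssignment:
    assignments: pd.DataFrame   # index sample_id; columns active_spots, pat_label
    group_portraits: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.assignments["pat_label"]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


# ---------------------------------------------------------------------------
# Summary maps and segmentation
# ---------------------------------------------------------------------------

def summary_map(portraits: list[SamplePortrait], kind: str = "variance"
                ) -> np.ndarray:
    """Aggregate portraits cell-wise: 'overexpression' = max, 'variance' = var."""
    if not portraits:
        raise ValueError("need at least one portrait")
    stack = np.stack([p.values for p in portraits])
    if kind in ("overexpression", "max"):
        return stack.max(axis=0)
    if kind in ("variance", "var"):
        return stack.var(axis=0)
    raise ValueError(f"unknown summary kind {kind!r}")


def _split_and_refine(summary: np.ndarray, fg: np.ndarray, labeled: np.ndarray,
                      codebook: np.ndarray, refine_iter: int = 10
                      ) -> np.ndarray:
    """Split multi-peak foreground components and refine basin boundaries.

    Markers are the 8-connected components of weak local maxima of the
    summary map inside the foreground (a flat plateau yields one marker, so
    constant blocks are never split). Watershed on the inverted summary
    separates touching spots; each foreground cell is then iteratively
    reassigned to the adjacent basin whose mean codebook profile it
    correlates with best, which fixes off-by-one watershed boundaries
    between genuinely distinct co-expression modules.
    """
    from skimage.segmentation import watershed

    eight = np.ones((3, 3), dtype=int)
    local_max = fg & (summary >= ndimage.maximum_filter(summary, size=3))
    markers, n_mark = ndimage.label(local_max, structure=eight)
    if n_mark <= labeled.max():
        return labeled
    ws = watershed(-summary, markers, mask=fg, connectivity=2)
    rows, cols = summary.shape
    for _ in range(refine_iter):
        present = [k for k in range(1, ws.max() + 1) if (ws == k).any()]
        means = {k: codebook[(ws == k).ravel()].mean(axis=0) for k in present}
        changed = False
        for (r, c) in np.argwhere(ws > 0):
            neigh = {int(ws[rr, cc])
                     for rr in range(max(r - 1, 0), min(r + 2, rows))
                     for cc in range(max(c - 1, 0), min(c + 2, cols))
                     if ws[rr, cc] > 0}
            prof = codebook[r * cols + c]
            best = max(sorted(neigh),
                       key=lambda k: np.corrcoef(prof, means[k])[0, 1])
            if best != ws[r, c]:
                ws[r, c] = best
                changed = True
        if not changed:
            break
    return ws


def segment_spots(summary: np.ndarray, model: SOMModel,
                  threshold_quantile: float = 0.92, min_cells: int = 4,
                  split: bool = True) -> SpotSegmentation:
    """Threshold the summary map and segment the foreground into spots.

    Cells above the per-map quantile are foreground; 8-connected components
    become candidate spots, touching multi-peak components are split by a
    profile-refined watershed (see ``_split_and_refine``), and components
    with at least ``min_cells`` cells are kept, labeled A, B, ... in
    decreasing size. A spot's gene set is the union of genes assigned to its
    cells.
    """
    if not np.all(np.isfinite(summary)):
        raise ValueError("summary map must be finite")
    if threshold_quantile <= 0:
        fg = np.ones_like(summary, dtype=bool)
    else:
        thr = np.quantile(summary, threshold_quantile)
        fg = summary > thr
    labeled, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if split and n_comp > 0:
        labeled = _split_and_refine(summary, fg, labeled, model.codebook)
    comps = []
    for k in range(1, labeled.max() + 1):
        cells = np.argwhere(labeled == k)
        if len(cells) >= min_cells:
            comps.append(cells)
    if not comps and threshold_quantile <= 0:
        comps = [np.argwhere(np.ones_like(summary, dtype=bool))]
    if not comps:
        warnings.warn("no foreground components >= min_cells; empty segmentation")
        return SpotSegmentation([], summary.shape)
    # stable order: decreasing size, ties by top-left cell
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    g2m = model.gene_to_metagene
    cols = model.grid.cols
    spots = []
    for i, cells in enumerate(comps):
        cellset = {(int(r), int(c)) for r, c in cells}
        linear = {r * cols + c for (r, c) in cellset}
        genes = set(g2m.index[g2m.isin(linear)])
        spots.append(Spot(string.ascii_uppercase[i], cellset, genes))
    return SpotSegmentation(spots, summary.shape)


# ---------------------------------------------------------------------------
# Spot expression, activation, PATs
# ---------------------------------------------------------------------------

def spot_expression(seg: SpotSegmentation, portraits: list[SamplePortrait]
                    ) -> SpotExpressionTable:
    """Mean portrait value over each spot's cells, per sample."""
    rows = {}
    for p in portraits:
        if p.values.shape != seg.grid_shape:
            raise ValueError("portrait grid does not match segmentation grid")
        rows[p.sample_id] = [
            float(np.mean([p.values[r, c] for (r, c) in s.metagene_cells]))
            for s in seg.spots]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=seg.labels)
    return SpotExpressionTable(df)


def call_spot_activation(table: SpotExpressionTable, tau: float = 0.0
                         ) -> pd.DataFrame:
    """Binary activation: spot expression strictly above ``tau``.

    On the gene-centered scale tau=0 means "above the cohort mean".
    """
    act = table.values > tau
    table.activation = act
    return act


def derive_pats(activation: pd.DataFrame,
                portraits: list[SamplePortrait] | None = None,
                min_group_size: int = 5) -> PATAssignment:
    """Group samples by identical active-spot combinations.

    Combinations with fewer than ``min_group_size`` members are dissolved:
    each of their samples joins the anchor PAT whose mean portrait best
    correlates (Pearson) with the sample portrait. Samples with no active
    spot always form PAT ``none*``.
    """
    combos = activation.apply(lambda row: "".join(sorted(activation.columns[row])),
                              axis=1)
    labels = combos.map(lambda c: (c + "*") if c else "none*")
    counts = labels.value_counts()
    anchors = set(counts.index[counts >= min_group_size])
    rare = [s for s in labels.index if labels[s] not in anchors]
    pmap = {p.sample_id: p.values for p in portraits} if portraits else {}
    if rare:
        if not anchors:
            raise ValueError("all combinations are rare; no anchor PAT exists")
        if not pmap:
            raise ValueError("portraits required to reassign rare combinations")
        anchor_means = {
            lab: np.mean([pmap[s] for s in labels.index
                          if labels[s] == lab], axis=0)
            for lab in anchors}
        for s in rare:
            flat = pmap[s].ravel()
            # best Pearson correlation; exact ties go alphabetically first
            best = min(sorted(anchor_means),
                       key=lambda lab: -np.corrcoef(
                           flat, anchor_means[lab].ravel())[0, 1])
            labels[s] = best
    active = labels.map(lambda lab: "" if lab == "none*" else lab[:-1])
    out = pd.DataFrame({"active_spots": active, "pat_label": labels})
    assignment = PATAssignment(out)
    if portraits:
        assignment.group_portraits = pat_mean_portraits(assignment, portraits)
    return assignment


def pat_mean_portraits(assignment: PATAssignment,
                       portraits: list[SamplePortrait]) -> dict[str, np.ndarray]:
    """Cell-wise mean portrait per PAT."""
    pmap = {p.sample_id: p.values for p in portraits}
    out = {}
    for lab, members in assignment.labels.groupby(assignment.labels).groups.items():
        out[str(lab)] = np.mean([pmap[s] for s in members], axis=0)
    return out


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, set[str]]]   # name -> (description, gene ids)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, desc, genes = parts[0], parts[1], set(parts[2:]) - {""}
                if name in sets:
                    raise ValueError(f"duplicate gene-set name {name!r}")
                sets[name] = (desc, genes)
        return cls(sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (desc, genes) in self.sets.items():
                fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def ora_hypergeometric(spot_genes: set[str], gene_set: set[str],
                       universe: set[str]) -> dict:
    """One-sided hypergeometric over-representation test.

    P(X >= overlap) where X ~ Hypergeom(population=|universe|,
    successes=|set n universe|, draws=|spot n universe|).
    """
    if not universe:
        raise ValueError("empty universe")
    spot = spot_genes & universe
    gset = gene_set & universe
    overlap = len(spot & gset)
    M, n, N = len(universe), len(gset), len(spot)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    expected = n * N / M
    ratio = overlap / expected if expected > 0 else np.nan
    return {"overlap": overlap, "p_value": min(p, 1.0),
            "enrichment_ratio": ratio}


def ora_collection(spot_genes: set[str], collection: GeneSetCollection,
                   universe: set[str]) -> pd.DataFrame:
    """ORA of one spot against every set, with Benjamini-Hochberg q-values."""
    rows = []
    for name, (desc, genes) in collection.sets.items():
        res = ora_hypergeometric(spot_genes, genes, universe)
        rows.append({"set": name, "description": desc, "set_size": len(genes),
                     **res})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def spot_report(seg: SpotSegmentation, collection: GeneSetCollection | None,
                universe: set[str], top: int = 3) -> pd.DataFrame:
    """Per-spot summary table: size, gene count and top enriched sets."""
    rows = []
    for s in seg.spots:
        row = {"spot": s.label, "n_cells": s.n_cells, "n_genes": len(s.genes)}
        if collection is not None:
            ora = ora_collection(s.genes, collection, universe).head(top)
            row["top_sets"] = ";".join(ora["set"])
            row["top_p"] = ";".join(f"{p:.3g}" for p in ora["p_value"])
            row["top_q"] = ";".join(f"{q:.3g}" for q in ora["q_value"])
        rows.append(row)
    return pd.DataFrame(rows)
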