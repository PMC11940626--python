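"""supSOM: project sparse expression profiles into a trained SOM space.

For every metagene a support-vector regressor learns to predict that
metagene's value for a sample from the sample's expression of the genes
whose best-matching unit lies within a grid-neighborhood radius of the
metagene (Chebyshev distance <= radius by default, radius 4). Metagenes with
no common gene in their neighborhood stay uncovered and are masked (rendered
white) in predicted portraits. A predicted portrait is then assigned to the
pattern type (PAT) whose mean portrait has the most similar red/blue channel
rendering, by Pearson correlation of the concatenated channel vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_curve, auc
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .preprocess import ExpressionMatrix
from .som import SamplePortrait, SOMModel, render_channels


@dataclass
class ProjectionModel:
    som: SOMModel
    radius: int
    gene_ids: list[str]                       # common gene space, fixed order
    regressors: dict[int, SVR]                # metagene -> fitted SVR
    feature_masks: dict[int, np.ndarray]      # metagene -> bool over gene_ids
    scaler: StandardScaler
    coverage_mask: np.ndarray                 # (rows, cols) True = covered
    neighborhood: str = "chebyshev"

    @property
    def n_covered(self) -> int:
        return int(self.coverage_mask.sum())


@dataclass
class ValidationReport:
    classes: list[str]
    confusion: pd.DataFrame
    per_class: pd.DataFrame        # sensitivity, specificity, balanced accuracy
    roc: dict[str, pd.DataFrame]   # class -> fpr/tpr table
    aucs: dict[str, float]
    macro_sensitivity: float
    macro_specificity: float
    macro_balanced_accuracy: float
    accuracy: float
    portrait_correlations: pd.Series | None = None  # predicted vs direct SOM
    scores: pd.DataFrame | None = None              # per-class assignment scores
    y_true: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _neighborhood_members(grid_rows: int, grid_cols: int, radius: int,
                          metric: str) -> np.ndarray:
    """(n_units, n_units) bool: unit j within ``radius`` of unit i."""
    r, c = np.divmod(np.arange(grid_rows * grid_cols), grid_cols)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if metric == "chebyshev":
        return np.maximum(dr, dc) <= radius
    if metric == "euclidean":
        return dr ** 2 + dc ** 2 <= radius ** 2
    raise ValueError(f"unknown neighborhood metric {metric!r}")


def train_supsom(som: SOMModel, train_expr: ExpressionMatrix, radius: int = 4,
                 neighborhood: str = "chebyshev",
                 svr_params: dict | None = None) -> ProjectionModel:
    """Fit one epsilon-SVR per covered metagene.

    ``train_expr`` must be restricted to the common (harmonized) gene space;
    its samples must be samples of the trained SOM, whose codebook provides
    the regression targets. Features are standardized per gene with training
    statistics.
    """
    missing = [s for s in train_expr.sample_ids if s not in som.sample_ids]
    if missing:
        raise ValueError(f"samples not in the SOM: {missing[:5]}")
    common = [g for g in train_expr.gene_ids if g in som.gene_to_metagene.index]
    if not common:
        raise ValueError("no overlap between training genes and SOM genes")
    sample_idx = [som.sample_ids.index(s) for s in train_expr.sample_ids]
    X_raw = train_expr.values.loc[common].to_numpy().T   # samples x genes
    scaler = StandardScaler()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # constant genes scale to 0
        X = scaler.fit_transform(X_raw)
    X = np.nan_to_num(X)

    grid = som.grid
    bmu = som.gene_to_metagene.loc[common].to_numpy()
    within = _neighborhood_members(grid.rows, grid.cols, radius, neighborhood)
    targets = som.codebook[:, sample_idx]                # units x train samples
    params = {"kernel": "rbf", "C": 10.0, "epsilon": 0.01, **(svr_params or {})}

    regressors: dict[int, SVR] = {}
    masks: dict[int, np.ndarray] = {}
    covered = np.zeros(grid.n_units, dtype=bool)
    for m in range(grid.n_units):
        feat = within[m][bmu]          # genes whose BMU is near metagene m
        if not feat.any():
            continue
        try:
            reg = SVR(**params)
            reg.fit(X[:, feat], targets[m])
        except Exception as exc:       # pragma: no cover - defensive
            warnings.warn(f"metagene {m}: SVR fit failed ({exc}); left uncovered")
            continue
        regressors[m] = reg
        masks[m] = feat
        covered[m] = True
    if not covered.any():
        raise ValueError("no metagene is covered by the common gene set")
    return ProjectionModel(som, radius, list(common), regressors, masks, scaler,
                           covered.reshape(grid.rows, grid.cols), neighborhood)


# ---------------------------------------------------------------------------
# Prediction and PAT assignment
# ---------------------------------------------------------------------------

def _predict_matrix(pm: ProjectionModel, raw: np.ndarray) -> np.ndarray:
    """(n_queries, n_units) predictions; one regressor call per metagene."""
    x = np.nan_to_num(pm.scaler.transform(raw))
    out = np.zeros((raw.shape[0], pm.som.grid.n_units))
    for m, reg in pm.regressors.items():
        out[:, m] = reg.predict(x[:, pm.feature_masks[m]])
    return out


def predict_portrait(pm: ProjectionModel, sample_expr: pd.Series,
                     sample_id: str | None = None) -> SamplePortrait:
    """Predict one sample's portrait from its common-gene expression."""
    missing = [g for g in pm.gene_ids if g not in sample_expr.index]
    if missing:
        raise ValueError(f"missing genes in query profile: {missing[:10]}"
                         f"{'...' if len(missing) > 10 else ''}")
    raw = sample_expr.loc[pm.gene_ids].to_numpy(dtype=float)[None, :]
    vals = _predict_matrix(pm, raw)[0]
    grid = pm.som.grid
    return SamplePortrait(sample_id or str(sample_expr.name),
                          vals.reshape(grid.rows, grid.cols),
                          mask=~pm.coverage_mask)


def predict_portraits(pm: ProjectionModel, expr: ExpressionMatrix
                      ) -> list[SamplePortrait]:
    missing = [g for g in pm.gene_ids if g not in expr.gene_ids]
    if missing:
        raise ValueError(f"missing genes in query matrix: {missing[:10]}"
                         f"{'...' if len(missing) > 10 else ''}")
    raw = expr.values.loc[pm.gene_ids].to_numpy(dtype=float).T
    preds = _predict_matrix(pm, raw)
    grid = pm.som.grid
    return [SamplePortrait(s, preds[j].reshape(grid.rows, grid.cols),
                           mask=~pm.coverage_mask)
            for j, s in enumerate(expr.sample_ids)]


def _channel_vector(values: np.ndarray, valid: np.ndarray,
                    mode: str = "diff") -> np.ndarray:
    p = SamplePortrait("_", values, mask=~valid)
    red, blue = render_channels(p)
    if mode == "diff":
        return red[valid] - blue[valid]
    if mode == "concat":
        return np.concatenate([red[valid], blue[valid]])
    raise ValueError(f"unknown channel mode {mode!r}")


def pat_correlations(query: SamplePortrait, pat_portraits: dict[str, np.ndarray],
                     mode: str = "diff") -> pd.Series:
    """Pearson correlation of red/blue channel renderings, query vs PAT means.

    Channels are rendered per portrait (so the comparison is scale-free) and
    restricted to the query's unmasked cells. The default combines the two
    channels as their signed difference (red minus blue), which makes the
    similarity antisymmetric: negating a portrait flips the sign of its
    correlations. ``mode="concat"`` correlates the stacked channel vectors
    instead. PATs whose restricted channel vector has zero variance are
    skipped with a warning.
    """
    valid = query.valid()
    qv = _channel_vector(query.values, valid, mode)
    out = {}
    for lab, vals in pat_portraits.items():
        pv = _channel_vector(np.asarray(vals), valid, mode)
        if np.std(pv) == 0 or np.std(qv) == 0:
            warnings.warn(f"PAT {lab!r}: zero-variance channel vector; skipped")
            continue
        out[lab] = float(np.corrcoef(qv, pv)[0, 1])
    return pd.Series(out, name=query.sample_id).sort_index()


def assign_pat(query: SamplePortrait, pat_portraits: dict[str, np.ndarray]
               ) -> tuple[str, pd.Series]:
    """Assign the query to the PAT with the highest channel correlation.

    Exact ties resolve to the alphabetically first PAT label (the full
    correlation table is returned alongside for inspection).
    """
    corr = pat_correlations(query, pat_portraits)
    if corr.empty:
        raise ValueError("no PAT with a defined correlation")
    best = corr.index[np.argmax(corr.to_numpy())]  # sorted index => ties -> first
    return str(best), corr


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_projection(som: SOMModel, expr: ExpressionMatrix,
                        pat_labels: pd.Series, radius: int = 4,
                        split: float = 0.9, seed: int = 0,
                        svr_params: dict | None = None) -> ValidationReport:
    """Hold-out validation of the projection + PAT assignment chain.

    The cohort is split into train/validation stratified by PAT label; the
    supSOM model and the PAT mean portraits are built from the training
    split only, and the held-out samples are assigned by channel correlation.
    Per-class sensitivity/specificity/balanced accuracy are one-vs-rest;
    ROC curves sweep the correlation score for one-vs-all classification.
    """
    from .som import portrait as som_portrait  # local to avoid cycle at import

    labels = pat_labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("PAT labels missing for some samples")
    counts = labels.value_counts()
    stratify = labels if counts.min() >= 2 else None
    train_ids, val_ids = train_test_split(
        list(expr.sample_ids), train_size=split, random_state=seed,
        stratify=stratify)
    train_classes = set(labels[train_ids])
    excluded = sorted(set(labels[val_ids]) - train_classes)
    if excluded:
        warnings.warn(f"PAT(s) absent from the training split: {excluded}; "
                      "their validation samples are excluded from metrics")
        val_ids = [s for s in val_ids if labels[s] in train_classes]

    train_expr = ExpressionMatrix(expr.values[train_ids], scale=expr.scale,
                                  strict_tpm=False)
    pm = train_supsom(som, train_expr, radius=radius, svr_params=svr_params)
    pat_means: dict[str, np.ndarray] = {}
    for lab in sorted(train_classes):
        members = [s for s in train_ids if labels[s] == lab]
        pat_means[lab] = np.mean([som_portrait(som, s).values for s in members],
                                 axis=0)

    classes = sorted(train_classes)
    val_expr = ExpressionMatrix(expr.values[val_ids], scale=expr.scale,
                                strict_tpm=False)
    predicted = predict_portraits(pm, val_expr)
    y_true, y_pred, scores, fidelity = [], [], [], {}
    for p in predicted:
        s = p.sample_id
        lab, corr = assign_pat(p, pat_means)
        y_true.append(str(labels[s]))
        y_pred.append(lab)
        scores.append(corr.reindex(classes).to_numpy())
        direct = som_portrait(som, s).values
        valid = p.valid()
        fidelity[s] = float(np.corrcoef(p.values[valid], direct[valid])[0, 1])
    scores_arr = np.asarray(scores)

    cm = confusion_matrix(y_true, y_pred, labels=classes)
    per_rows, rocs, aucs = [], {}, {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        per_rows.append({"pat": cls, "n": int(tp + fn),
                         "sensitivity": sens, "specificity": spec,
                         "balanced_accuracy": np.nanmean([sens, spec])})
        binary = np.array([t == cls for t in y_true], dtype=int)
        if 0 < binary.sum() < len(binary):
            fpr, tpr, _ = roc_curve(binary, scores_arr[:, i])
            rocs[cls] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
            aucs[cls] = float(auc(fpr, tpr))
    per = pd.DataFrame(per_rows).set_index("pat")
    present = per["n"] > 0
    return ValidationReport(
        classes=classes,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class=per, roc=rocs, aucs=aucs,
        macro_sensitivity=float(per.loc[present, "sensitivity"].mean()),
        macro_specificity=float(per.loc[present, "specificity"].mean()),
        macro_balanced_accuracy=float(per.loc[present,
                                              "balanced_accuracy"].mean()),
        accuracy=float(np.mean(np.array(y_true) == np.array(y_pred))),
        portrait_correlations=pd.Series(fidelity, name="portrait_correlation"),
        scores=pd.DataFrame(scores_arr, index=val_ids, columns=classes),
        y_true=y_true, excluded=excluded)
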