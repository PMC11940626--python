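"""End-to-end orchestration: portray (SOM + spots + PATs) and project stages.

A single YAML config drives both stages; unknown keys are rejected. Every
stage writes its artifacts plus a JSON manifest with versions, seeds and
stage timings, so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (ExpressionMatrix, SampleAnnotation, center_genes,
                         combat_adjust, filter_low_expression, intersect_genes,
                         log_transform, merge_cohorts, quantile_normalize,
                         read_annotation_table, read_expression_table,
                         write_expression_table)
from .projection import (predict_portraits, assign_pat, train_supsom,
                         validate_projection)
from .som import SOMGrid, SOMModel, all_portraits, portrait_png, train_som
from .spots import (GeneSetCollection, call_spot_activation, derive_pats,
                    pat_mean_portraits, segment_spots, spot_expression,
                    spot_report, summary_map)

log = logging.getLogger("somportrait")


def setup_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


@dataclass
class PipelineConfig:
    """Schema-checked pipeline settings (unknown YAML keys are rejected)."""

    expression: str | None = None          # TSV path (TPM scale)
    annotation: str | None = None
    query_expression: str | None = None    # sparse companion cohort TSV
    out_dir: str = "somportrait_out"
    grid_rows: int = 50
    grid_cols: int = 50
    epochs: int = 20
    radius_end: float = 1.0
    preprocessing: str = "cllmap"          # or "harmonize" (projection stage)
    tpm_floor: float = 2.0
    low_expression_frac: float = 0.5
    spot_threshold_quantile: float = 0.92
    spot_min_cells: int = 4
    summary_kind: str = "variance"
    pat_min_group_size: int = 5
    activation_tau: float = 0.0
    radius: int = 4
    validation_split: float = 0.9
    seed: int = 0
    gmt: str | None = None
    write_png: bool = False

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """Configuration for cohorts of a few thousand genes.

        The grid is sized to keep the gene-per-metagene density near the
        ~13 genes/unit of a 50x50 map trained on a 32k-gene transcriptome
        (a 25x25 grid for ~5,000 genes), with a slightly longer, sharper
        neighborhood schedule that improves spot boundary purity at this
        scale.
        """
        base = dict(grid_rows=25, grid_cols=25, epochs=30, radius_end=0.7)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.preprocessing not in ("cllmap", "harmonize"):
            raise ValueError(f"unknown preprocessing preset {self.preprocessing!r}")
        if not (0 < self.validation_split < 1):
            raise ValueError("validation_split must be in (0, 1)")
        if self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid too small")


def _manifest(out: Path, stage: str, cfg: PipelineConfig, extra: dict,
              timings: dict[str, float]) -> None:
    manifest = {"stage": stage, "version": __version__,
                "config": dataclasses.asdict(cfg),
                "timings_s": {k: round(v, 3) for k, v in timings.items()},
                **extra}
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Stage: portray
# ---------------------------------------------------------------------------

def preprocess_cllmap(expr: ExpressionMatrix, batches: pd.Series
                      ) -> ExpressionMatrix:
    """ComBat on TPM -> log2(TPM+1) -> quantile normalize -> gene centering.

    ComBat output can dip slightly below zero on the TPM scale; values are
    clipped at 0 before the log step.
    """
    adj = combat_adjust(expr, batches)
    adj.values.clip(lower=0.0, inplace=True)
    return center_genes(quantile_normalize(log_transform(adj)))


def run_portray(config: PipelineConfig,
                expr: ExpressionMatrix | None = None,
                annotation: SampleAnnotation | None = None) -> dict:
    """Preprocess, train the SOM, segment spots and derive PATs.

    Inputs may be passed in memory or read from the configured paths.
    Returns the in-memory artifacts and writes TSV/JSON artifacts to
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("portray: %s", name)
        timings[name] = _time.perf_counter()
        return name

    def done(name):
        timings[name] = _time.perf_counter() - timings[name]

    try:
        name = stage("load")
        if expr is None:
            if config.expression is None:
                raise ValueError("no expression input configured")
            expr = read_expression_table(config.expression, scale="tpm")
        if annotation is None:
            if config.annotation is None:
                raise ValueError("no annotation input configured")
            annotation = read_annotation_table(config.annotation)
        done(name)

        name = stage("preprocess")
        normalized = preprocess_cllmap(expr, annotation.batch)
        done(name)

        name = stage("train_som")
        grid = SOMGrid(config.grid_rows, config.grid_cols)
        model = train_som(normalized, grid, seed=config.seed,
                          epochs=config.epochs, radius_end=config.radius_end)
        model.save(out / "som_model.npz")
        done(name)

        name = stage("spots")
        portraits = all_portraits(model)
        summary = summary_map(portraits, kind=config.summary_kind)
        seg = segment_spots(summary, model,
                            threshold_quantile=config.spot_threshold_quantile,
                            min_cells=config.spot_min_cells)
        table = spot_expression(seg, portraits)
        activation = call_spot_activation(table, tau=config.activation_tau)
        universe = set(model.gene_to_metagene.index)
        collection = (GeneSetCollection.from_gmt(config.gmt)
                      if config.gmt else None)
        spot_report(seg, collection, universe).to_csv(
            out / "spots.tsv", sep="\t", index=False)
        table.values.to_csv(out / "spot_expression.tsv", sep="\t",
                            index_label="sample_id")
        done(name)

        name = stage("pats")
        pats = derive_pats(activation, portraits,
                           min_group_size=config.pat_min_group_size)
        pats.assignments.to_csv(out / "pats.tsv", sep="\t",
                                index_label="sample_id")
        done(name)

        if config.write_png:
            name = stage("render")
            png_dir = out / "portraits"
            png_dir.mkdir(exist_ok=True)
            for p in portraits[:20]:
                portrait_png(p, png_dir / f"{p.sample_id}.png")
            done(name)
    except Exception as exc:
        raise RuntimeError(f"portray stage {name!r} failed: {exc}") from exc

    _manifest(out, "portray", config,
              {"n_metagenes": model.grid.n_units,
               "n_genes": model.gene_values.shape[0],
               "n_samples": model.n_samples,
               "n_spots": len(seg.spots),
               "pat_sizes": pats.sizes().to_dict()}, timings)
    return {"model": model, "portraits": portraits, "segmentation": seg,
            "spot_table": table, "pats": pats, "normalized": normalized}


# ---------------------------------------------------------------------------
# Stage: project
# ---------------------------------------------------------------------------

def harmonize(reference: ExpressionMatrix, query: ExpressionMatrix,
              tpm_floor: float = 2.0, frac: float = 0.5
              ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Make a dense reference and a sparse query cohort comparable.

    Low-expression filter both cohorts, intersect genes, merge, log2(TPM+1),
    ComBat with the dataset label as batch, quantile normalize; split back
    into the two cohorts. The log step stabilizes the scale before the
    empirical-Bayes adjustment and is the scale regression models downstream
    expect.
    """
    ref_f = filter_low_expression(reference, tpm_floor, frac)
    qry_f = filter_low_expression(query, tpm_floor, frac)
    ref_i, qry_i = intersect_genes(ref_f, qry_f)
    merged, dataset = merge_cohorts(ref_i, qry_i)
    adjusted = quantile_normalize(combat_adjust(log_transform(merged),
                                                dataset))
    ref_out = ExpressionMatrix(adjusted.values[ref_i.sample_ids],
                               scale="normalized", strict_tpm=False)
    qry_out = ExpressionMatrix(adjusted.values[qry_i.sample_ids],
                               scale="normalized", strict_tpm=False)
    return ref_out, qry_out


def run_project(config: PipelineConfig,
                model: SOMModel | None = None,
                reference: ExpressionMatrix | None = None,
                query: ExpressionMatrix | None = None,
                pat_labels: pd.Series | None = None) -> dict:
    """Harmonize reference + query, train supSOM, predict and assign PATs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    name = "load"
    try:
        t0 = _time.perf_counter()
        if model is None:
            model_path = out / "som_model.npz"
            if not model_path.exists():
                raise FileNotFoundError(f"missing trained SOM: {model_path}")
            model = SOMModel.load(model_path)
        if reference is None:
            reference = read_expression_table(config.expression, scale="tpm")
        if query is None:
            if config.query_expression is None:
                raise ValueError("no query expression configured")
            query = read_expression_table(config.query_expression, scale="tpm")
        if query.n_samples == 0:
            raise ValueError("query table has no samples")
        if pat_labels is None:
            pat_path = out / "pats.tsv"
            if not pat_path.exists():
                raise FileNotFoundError(f"missing PAT table: {pat_path}")
            pat_labels = pd.read_csv(pat_path, sep="\t",
                                     index_col="sample_id")["pat_label"]
        timings[name] = _time.perf_counter() - t0

        name = "harmonize"
        t0 = _time.perf_counter()
        ref_h, qry_h = harmonize(reference, query, config.tpm_floor,
                                 config.low_expression_frac)
        timings[name] = _time.perf_counter() - t0

        name = "train_supsom"
        t0 = _time.perf_counter()
        pm = train_supsom(model, ref_h, radius=config.radius)
        timings[name] = _time.perf_counter() - t0

        name = "validate"
        t0 = _time.perf_counter()
        report = validate_projection(model, ref_h, pat_labels,
                                     radius=config.radius,
                                     split=config.validation_split,
                                     seed=config.seed)
        report.per_class.to_csv(out / "validation_per_class.tsv", sep="\t")
        report.confusion.to_csv(out / "validation_confusion.tsv", sep="\t")
        timings[name] = _time.perf_counter() - t0

        name = "predict"
        t0 = _time.perf_counter()
        from .som import portrait as som_portrait
        pat_means = {lab: np.mean([som_portrait(model, s).values
                                   for s in pat_labels.index[pat_labels == lab]
                                   if s in model.sample_ids], axis=0)
                     for lab in sorted(pat_labels.unique())}
        predicted = predict_portraits(pm, qry_h)
        rows, corr_rows = [], []
        for p in predicted:
            lab, corr = assign_pat(p, pat_means)
            rows.append({"sample_id": p.sample_id, "pat_label": lab,
                         "correlation": corr[lab]})
            corr_rows.append(corr.rename(p.sample_id))
            pd.DataFrame(p.values).to_csv(
                out / f"predicted_portrait_{p.sample_id}.tsv", sep="\t",
                header=False, index=False)
            if config.write_png:
                portrait_png(p, out / f"predicted_portrait_{p.sample_id}.png")
        assignments = pd.DataFrame(rows).set_index("sample_id")
        assignments.to_csv(out / "assignments.tsv", sep="\t")
        pd.DataFrame(corr_rows).to_csv(out / "pat_correlations.tsv", sep="\t",
                                       index_label="sample_id")
        timings[name] = _time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"project stage {name!r} failed: {exc}") from exc

    _manifest(out, "project", config,
              {"n_common_genes": len(pm.gene_ids),
               "n_covered_metagenes": pm.n_covered,
               "macro_sensitivity": report.macro_sensitivity,
               "macro_specificity": report.macro_specificity,
               "macro_balanced_accuracy": report.macro_balanced_accuracy,
               "aucs": report.aucs}, timings)
    return {"projection": pm, "predicted": predicted,
            "assignments": assignments, "report": report}
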