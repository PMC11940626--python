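"""Synthetic multi-cohort expression data with planted ground truth.

The generator emulates the statistical structure the portrayal pipeline
assumes: a gene-by-sample TPM matrix with planted co-expressed modules whose
group-specific activation defines sample subtypes, additive/multiplicative
per-cohort batch effects, clinical covariates correlated with module
activity, proportional-hazards survival tied to one module, and a degraded
"nanopore-like" companion dataset (high-expression gene subset, shallow
multinomial libraries).

Log-space model per gene g and sample s:

    x_gs = mu_g + delta * A[group(s), module(g)] + gamma_{g,b(s)} + sigma_b * eps

with mu_g ~ Normal(3, 2) log2-TPM baseline, eps ~ Normal(0, sigma^2), batch
additive effects gamma ~ Normal(0, batch_shift_sd) and batch noise-scale
factors sigma_b ~ exp(Normal(0, batch_scale_sd)). The matrix is
back-transformed (2^x - 1, clipped at 0) and column-rescaled to TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, SampleAnnotation

# 7 groups over 6 modules, rows/columns of an 8x8 Hadamard matrix with the
# all-ones row and column dropped: every group up- or down-regulates every
# module (entries +-1), the seven up-module combinations are distinct (each
# group is a distinct pattern type), and module activation profiles are
# pairwise near-orthogonal so planted modules stay decorrelated.
DEFAULT_ACTIVATION = np.array([
    [-1,  1, -1,  1, -1,  1],
    [ 1, -1, -1,  1,  1, -1],
    [-1, -1,  1,  1, -1, -1],
    [ 1,  1,  1, -1, -1, -1],
    [-1,  1, -1, -1,  1, -1],
    [ 1, -1, -1, -1, -1,  1],
    [-1, -1,  1, -1,  1,  1],
], dtype=float)


@dataclass
class SimulationDesign:
    """Study-scale defaults: 5,000 genes x 300 samples, 6 cohorts, 6 modules."""

    n_genes: int = 5000
    n_samples: int = 300
    n_modules: int = 6
    module_size: int = 80
    activation: np.ndarray = field(
        default_factory=lambda: DEFAULT_ACTIVATION.copy())
    effect_size: float = 1.5          # delta, log2 units
    noise_sd: float = 0.7             # sigma, log2 units
    n_batches: int = 6
    batch_shift_sd: float = 0.4       # additive batch effect SD (log2)
    batch_scale_sd: float = 0.1       # log of multiplicative noise-scale SD
    baseline_mean: float = 3.0        # mu_g ~ Normal(baseline_mean, baseline_sd)
    baseline_sd: float = 2.0
    # survival: hazard tied to module 0 ("spot-I-like") plus gender
    baseline_hazard: float = 0.02
    log_hr: np.ndarray = field(
        default_factory=lambda: np.array([0.7, 0.0, 0.0, 0.0, 0.0, 0.0]))
    gender_log_hr: float = 0.5
    censoring_rate: float = 0.3
    # nanopore-like degradation
    retained_fraction: float = 0.3
    library_size_mean: float = 64444.0
    library_size_sigma: float = 0.83  # log-normal sigma (CV ~ 0.97)
    seed: int = 0

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape[1] != self.n_modules:
            raise ValueError("activation matrix must have n_modules columns")
        if not np.isin(self.activation, (-1.0, 0.0, 1.0)).all():
            raise ValueError("activation entries must be in {-1, 0, +1}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules cannot cover more genes than n_genes")
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be positive")
        hr = np.zeros(self.n_modules)
        given = np.asarray(self.log_hr, dtype=float)[:self.n_modules]
        hr[:len(given)] = given
        self.log_hr = hr

    @property
    def n_groups(self) -> int:
        return self.activation.shape[0]


@dataclass
class GroundTruth:
    gene_module: pd.Series       # gene_id -> module index (-1 = background)
    sample_group: pd.Series      # sample_id -> group index
    sample_batch: pd.Series
    clinical: pd.DataFrame
    design: SimulationDesign

    def module_genes(self, k: int) -> set[str]:
        return set(self.gene_module.index[self.gene_module == k])

    def active_modules(self, sample_id: str) -> set[int]:
        g = int(self.sample_group[sample_id])
        return set(np.flatnonzero(self.design.activation[g] > 0))


# ---------------------------------------------------------------------------

def simulate_cohort(design: SimulationDesign
                    ) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Generate the TPM matrix, annotation table and planted ground truth."""
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    samples = [f"s{i:04d}" for i in range(design.n_samples)]

    module = np.full(design.n_genes, -1, dtype=int)
    for k in range(design.n_modules):
        module[k * design.module_size:(k + 1) * design.module_size] = k

    group = rng.integers(0, design.n_groups, size=design.n_samples)
    batch = rng.integers(0, design.n_batches, size=design.n_samples)

    mu = rng.normal(design.baseline_mean, design.baseline_sd, design.n_genes)
    x = np.tile(mu[:, None], (1, design.n_samples))
    in_module = module >= 0
    x[in_module] += design.effect_size \
        * design.activation[group][:, module[in_module]].T
    # batch effects: per (gene, batch) additive shift, per-batch noise scale
    gamma = rng.normal(0.0, design.batch_shift_sd,
                       (design.n_genes, design.n_batches))
    scale_b = np.exp(rng.normal(0.0, design.batch_scale_sd, design.n_batches))
    x += gamma[:, batch]
    x += rng.standard_normal((design.n_genes, design.n_samples)) \
        * design.noise_sd * scale_b[batch]

    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6

    # clinical covariates: gender and ighv correlate with module-0 activity
    # (the planted poor-prognosis module); epitype is independent noise.
    m0_active = design.activation[group, 0] > 0
    p_male = np.where(m0_active, 0.7, 0.4)
    gender = np.where(rng.random(design.n_samples) < p_male, "male", "female")
    p_unmut = np.where(m0_active, 0.8, 0.25)
    ighv = np.where(rng.random(design.n_samples) < p_unmut, "U-CLL", "M-CLL")
    epitype = rng.choice(["n-CLL", "i-CLL", "m-CLL"], design.n_samples)

    clinical = pd.DataFrame({
        "batch": [f"cohort{b}" for b in batch],
        "gender": gender, "ighv": ighv, "epitype": epitype,
    }, index=samples)

    truth = GroundTruth(pd.Series(module, index=genes, name="module"),
                        pd.Series(group, index=samples, name="group"),
                        clinical["batch"], clinical.copy(), design)
    time, event = simulate_survival(truth, design, rng)
    clinical["time"] = time
    clinical["event"] = event

    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples),
                            scale="tpm")
    return expr, SampleAnnotation(clinical), truth


def simulate_survival(truth: GroundTruth, design: SimulationDesign,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with hazard tied to module activation and gender.

    h_s = h0 * exp(sum_m beta_m * active_m(s) + beta_gender * male(s)).
    Censoring is independent Uniform(0, c_max) with c_max tuned by bisection
    to hit the design's target censoring rate.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    group = truth.sample_group.to_numpy()
    active = (design.activation[group] > 0).astype(float)
    male = (truth.clinical["gender"] == "male").to_numpy(dtype=float)
    lin = active @ np.asarray(design.log_hr) + design.gender_log_hr * male
    hazard = design.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    if design.censoring_rate <= 0:
        return t_event, np.ones(len(t_event), dtype=int)
    u = rng.random(len(t_event))
    lo, hi = 1e-6, float(t_event.max()) * 100
    for _ in range(200):  # bisection: censoring fraction decreases in c_max
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(u * mid < t_event))
        if rate > design.censoring_rate:
            lo = mid
        else:
            hi = mid
    c = u * 0.5 * (lo + hi)
    event = (t_event <= c).astype(int)
    return np.minimum(t_event, c), event


def degrade_to_nanopore(m: ExpressionMatrix, design: SimulationDesign,
                        seed: int | None = None,
                        sample_prefix: str = "ont_") -> ExpressionMatrix:
    """Shallow-library companion dataset: top genes, multinomial counts.

    Keeps the top ``retained_fraction`` of genes by mean expression, draws
    per-sample library sizes from a log-normal around the design mean, samples
    counts from a multinomial with the retained TPM proportions, and converts
    back to TPM. Samples are re-labeled with ``sample_prefix`` since the
    companion behaves as a cohort of its own.
    """
    if m.scale != "tpm":
        raise ValueError(f"expected tpm, got scale={m.scale!r}")
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    arr = m.to_numpy()
    n_keep = max(1, int(round(design.retained_fraction * m.n_genes)))
    order = np.argsort(-arr.mean(axis=1), kind="stable")[:n_keep]
    order.sort()
    sub = arr[order]
    # log-normal library sizes with the requested mean
    mu_log = np.log(design.library_size_mean) - design.library_size_sigma ** 2 / 2
    lib = np.exp(rng.normal(mu_log, design.library_size_sigma, m.n_samples))
    lib = np.maximum(lib, 1.0).astype(int)
    if (lib < 1000).any():
        import warnings
        warnings.warn(f"{int((lib < 1000).sum())} sample(s) with library "
                      "size < 1000")
    counts = np.empty_like(sub)
    for j in range(m.n_samples):
        p = sub[:, j] / sub[:, j].sum()
        counts[:, j] = rng.multinomial(lib[j], p)
    tot = counts.sum(axis=0)
    tot[tot == 0] = 1
    tpm = counts / tot * 1e6
    cols = [f"{sample_prefix}{s}" for s in m.sample_ids]
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=m.values.index[order], columns=cols),
        scale="tpm", strict_tpm=False)
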