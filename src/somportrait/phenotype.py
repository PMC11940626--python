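"""Phenotype maps and survival analysis.

Phenotype maps regress every metagene profile on a categorical clinical
variable with a no-intercept indicator model, so each category's coefficient
is exactly that category's mean metagene value; the coefficient grids are
then read as "phenotype portraits" on the SOM grid. Survival uses
Kaplan-Meier product-limit curves, log-rank tests and Cox proportional
hazards (Efron tie handling, the lifelines default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SampleAnnotation
from .som import SOMGrid, SOMModel
from .spots import SpotExpressionTable

ALPHA = 0.05  # significance level used throughout the phenotype maps


@dataclass
class PhenotypeMap:
    """Per-category coefficient/p-value grids for one clinical variable."""

    variable: str
    categories: list[str]
    coefficients: dict[str, np.ndarray]   # category -> (rows, cols)
    p_values: dict[str, np.ndarray]
    q_values: dict[str, np.ndarray]

    def significant(self, category: str) -> np.ndarray:
        return self.p_values[category] < ALPHA


@dataclass
class SurvivalResult:
    strata: str
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_p: float | None = None
    hazard_ratios: pd.DataFrame | None = None   # covariate, HR, CI, p
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# No-intercept categorical regression
# ---------------------------------------------------------------------------

def _no_intercept_fit(y: np.ndarray, cat: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized OLS of each row of ``y`` on category indicators, no intercept.

    With a pure indicator design the coefficient for category c is the mean of
    y over that category's samples; its standard error is s/sqrt(n_c) with s
    the residual standard deviation on n - k degrees of freedom. Returns
    (coefficients, two-sided p-values, category levels), both (n_rows, k).
    """
    levels, inv = np.unique(cat, return_inverse=True)
    k = len(levels)
    n = y.shape[1]
    counts = np.bincount(inv, minlength=k).astype(float)
    sums = np.zeros((y.shape[0], k))
    np.add.at(sums.T, inv, y.T)
    means = sums / counts[None, :]
    resid = y - means[:, inv]
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples for residual degrees of freedom")
    s2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(s2[:, None] / counts[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, means / se, np.inf * np.sign(means))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), 1.0, p)
    return means, p, [str(v) for v in levels]


def _clean_variable(annotation: SampleAnnotation, variable: str,
                    sample_ids: list[str], min_per_level: int = 2
                    ) -> tuple[np.ndarray, np.ndarray]:
    col = annotation.table.loc[sample_ids, variable]
    keep = col.notna().to_numpy()
    cat = col[keep].astype(str).to_numpy()
    counts = pd.Series(cat).value_counts()
    small = counts.index[counts < min_per_level].tolist()
    if small:
        warnings.warn(f"{variable}: level(s) {small} have <{min_per_level} "
                      "samples; excluded")
        ok = ~pd.Series(cat).isin(small).to_numpy()
        idx = np.flatnonzero(keep)[ok]
        keep = np.zeros_like(keep)
        keep[idx] = True
        cat = cat[ok]
    if len(np.unique(cat)) < 2:
        raise ValueError(f"{variable}: needs >=2 usable levels")
    return keep, cat


def fit_phenotype_map(model: SOMModel, annotation: SampleAnnotation,
                      variable: str) -> PhenotypeMap:
    """Phenotype portrait: no-intercept categorical fit per metagene."""
    keep, cat = _clean_variable(annotation, variable, model.sample_ids)
    y = model.codebook[:, keep]
    coef, p, levels = _no_intercept_fit(y, cat)
    q = np.stack([multipletests(p[:, j], method="fdr_bh")[1]
                  for j in range(p.shape[1])], axis=1)
    shape = (model.grid.rows, model.grid.cols)
    return PhenotypeMap(
        variable, levels,
        {lev: coef[:, j].reshape(shape) for j, lev in enumerate(levels)},
        {lev: p[:, j].reshape(shape) for j, lev in enumerate(levels)},
        {lev: q[:, j].reshape(shape) for j, lev in enumerate(levels)})


def fit_spot_phenotype(spot_table: SpotExpressionTable,
                       annotation: SampleAnnotation, variable: str
                       ) -> pd.DataFrame:
    """Spot-level no-intercept categorical fit; long table of coefficients."""
    sample_ids = spot_table.values.index.tolist()
    keep, cat = _clean_variable(annotation, variable, sample_ids)
    y = spot_table.values.to_numpy().T[:, keep]   # spots x samples
    coef, p, levels = _no_intercept_fit(y, cat)
    rows = []
    for i, spot in enumerate(spot_table.values.columns):
        for j, lev in enumerate(levels):
            rows.append({"spot": spot, "variable": variable, "category": lev,
                         "coefficient": coef[i, j], "p_value": p[i, j],
                         "significant": bool(p[i, j] < ALPHA)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_estimate(time: pd.Series, event: pd.Series, groups: pd.Series
                ) -> SurvivalResult:
    """Kaplan-Meier product-limit estimate per group + log-rank across groups."""
    time = pd.Series(time).astype(float)
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")
    event = pd.Series(event).astype(int)
    groups = pd.Series(groups).astype(str)
    res = SurvivalResult(strata="groups")
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=g)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curve["at_risk"] = [int(kmf.event_table.at[t, "at_risk"])
                            for t in curve["time"]]
        res.km_curves[g] = curve
        if event[sel].sum() == 0:
            res.flags.append(f"group {g!r} has zero events")
    if groups.nunique() > 1:
        lr = multivariate_logrank_test(time, groups, event)
        res.logrank_p = float(lr.p_value)
    return res


def cox_fit(time: pd.Series, event: pd.Series, covariates: pd.DataFrame
            ) -> SurvivalResult:
    """Cox proportional-hazards fit; HR = exp(coef) with Wald 95% CI.

    Categorical covariate columns are dummy-coded (first level as reference).
    Non-convergence or separation is flagged, never silently dropped.
    """
    if pd.Series(event).astype(int).sum() < 1:
        raise ValueError("need at least one event")
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    df = X.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    res = SurvivalResult(strata=",".join(covariates.columns))
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        res.flags.append(f"cox fit failed: {exc}")
        return res
    summ = cph.summary
    res.hazard_ratios = pd.DataFrame({
        "covariate": summ.index,
        "coef": summ["coef"].to_numpy(),
        "se": summ["se(coef)"].to_numpy(),
        "HR": summ["exp(coef)"].to_numpy(),
        "HR_lower95": summ["exp(coef) lower 95%"].to_numpy(),
        "HR_upper95": summ["exp(coef) upper 95%"].to_numpy(),
        "p_value": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return res


def stratified_survival(time: pd.Series, event: pd.Series, gender: pd.Series,
                        spotI_active: pd.Series, pat: pd.Series,
                        min_stratum: int = 5
                        ) -> dict[tuple[str, str], SurvivalResult]:
    """KM + Cox across PATs within each gender x spot-activation stratum."""
    time, event = pd.Series(time).astype(float), pd.Series(event).astype(int)
    gender, pat = pd.Series(gender).astype(str), pd.Series(pat).astype(str)
    act = pd.Series(spotI_active).astype(bool)
    out: dict[tuple[str, str], SurvivalResult] = {}
    for g in sorted(gender.unique()):
        for a in (False, True):
            sel = ((gender == g) & (act == a)).to_numpy()
            key = (g, "spotI_high" if a else "spotI_low")
            if sel.sum() < min_stratum:
                warnings.warn(f"stratum {key} has <{min_stratum} samples; omitted")
                continue
            res = km_estimate(time[sel], event[sel], pat[sel])
            res.strata = f"gender={g},{key[1]}"
            if pat[sel].nunique() > 1 and event[sel].sum() > 0:
                cox = cox_fit(time[sel], event[sel],
                              pd.DataFrame({"pat": pat[sel]}))
                res.hazard_ratios = cox.hazard_ratios
                res.flags += cox.flags
            out[key] = res
    return out


def survival_table(results: dict[tuple[str, str], SurvivalResult]
                   ) -> pd.DataFrame:
    """Flatten stratified results into one TSV-ready table."""
    rows = []
    for key, res in results.items():
        for g, curve in res.km_curves.items():
            rows.append({"stratum": "/".join(key), "group": g,
                         "n": int(curve["at_risk"].iloc[0]),
                         "final_survival": float(curve["survival"].iloc[-1]),
                         "logrank_p": res.logrank_p})
    return pd.DataFrame(rows)
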