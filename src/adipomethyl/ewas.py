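"""Per-cohort EWAS: phenotype preprocessing and per-CpG linear models.

The base model regresses methylation β at each CpG on natural-log
adipokine concentration, adjusting for age (years), a female indicator,
five cell-type proportions (CD8T, CD4T, NK, Mono, B; granulocytes are the
implicit reference) and numeric technical factors.  Sensitivity variants
add smoking dummies, BMI, or swap in the 11 extended cell proportions
(neutrophils excluded to avoid collinearity, since proportions sum to 1).

Phenotype cleaning removes values below the limit of detection and then
values more than three IQRs from the nearest quartile (quartiles by
linear interpolation), on the raw scale, before the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EXTENDED_CELLS, MAIN_CELLS, CohortDataset

__all__ = ["ModelSpec", "flag_outliers", "preprocess_adipokine", "fit_probe",
           "run_model", "filter_probes", "MODEL_TAGS"]

MODEL_TAGS = ("base", "smoking", "bmi", "extended_cells")

BASE_COVARIATES = ["age", "sex_female", *MAIN_CELLS, "technical_1", "technical_2"]


@dataclass(frozen=True)
class ModelSpec:
    """Which adipokine to analyse and which covariate set to adjust for."""

    phenotype: str = "adiponectin"
    model_tag: str = "base"

    def __post_init__(self):
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")

    def covariate_columns(self) -> list[str]:
        if self.model_tag == "extended_cells":
            # extended proportions replace the five aggregate ones
            return ["age", "sex_female", *EXTENDED_CELLS,
                    "technical_1", "technical_2"]
        cols = list(BASE_COVARIATES)
        if self.model_tag == "smoking":
            cols += ["smoking_former", "smoking_current"]
        elif self.model_tag == "bmi":
            cols += ["bmi"]
        return cols


def flag_outliers(values) -> pd.DataFrame:
    """Flag values more than three IQRs outside the nearest quartile.

    Quartiles use linear interpolation between order statistics.  Returns
    a DataFrame with boolean ``outlier`` and ``missing`` columns aligned
    to the input.  Requires at least four non-missing values.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    missing = v.isna()
    clean = v[~missing]
    if clean.size < 4:
        raise ValueError(
            f"outlier rule needs >= 4 non-missing values, got {clean.size}")
    q1, q3 = np.quantile(clean, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    outlier = (~missing) & ((v < lo) | (v > hi))
    return pd.DataFrame({"outlier": outlier.to_numpy(),
                         "missing": missing.to_numpy()})


def preprocess_adipokine(values, lod: float = 0.0):
    """LOD-censor, remove outliers on the raw scale, then natural-log.

    Returns ``(log_values, report)`` where ``log_values`` is a Series
    (NaN at removed positions, index preserved) and ``report`` counts
    removals per reason.  Raises if nothing survives.
    """
    if lod < 0:
        raise ValueError("limit of detection must be non-negative")
    v = pd.Series(np.asarray(values, dtype=float))
    n_missing = int(v.isna().sum())
    below = v < lod
    n_lod = int(below.sum())
    v = v.mask(below)
    if v.notna().sum() == 0:
        raise ValueError("all adipokine values removed during preprocessing")
    flags = flag_outliers(v)
    n_outlier = int(flags["outlier"].sum())
    v = v.mask(flags["outlier"].to_numpy())
    if v.notna().sum() == 0:
        raise ValueError("all adipokine values removed during preprocessing")
    if (v <= 0).any():
        raise ValueError("non-positive adipokine values cannot be log-transformed")
    report = {"missing": n_missing, "below_lod": n_lod, "outlier": n_outlier,
              "kept": int(v.notna().sum())}
    return np.log(v), report


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS effect/SE/p for the column-1 coefficient; multi-column y allowed.

    y: (n,) or (n, m); X: (n, p) with the exposure in column 1 (column 0
    is the intercept).  Returns (beta, se, pval) each scalar or (m,).
    """
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need >= {p + 2} complete cases, got {n}")
    q, r = np.linalg.qr(X)
    if np.any(np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())):
        bad = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 *
                             max(1.0, np.abs(np.diag(r)).max()))
        raise np.linalg.LinAlgError(
            f"rank-deficient design: collinear column index(es) {bad.tolist()}")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - p
    sigma2 = np.sum(resid * resid, axis=0) / df
    xtx_inv_11 = np.linalg.inv(r.T @ r)[1, 1]
    se = np.sqrt(sigma2 * xtx_inv_11)
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    return beta, se, pval


def fit_probe(y, x, covariates=None, cpg_id: str = "cpg",
              cohort_id: str = "cohort", model_tag: str = "base") -> dict:
    """OLS of one CpG's methylation on log adipokine plus covariates.

    Complete-case: rows with any missing value are dropped.  Returns a
    dict with cpg_id, cohort_id, model_tag, beta, se, pval, n; the
    p-value is two-sided from the t distribution on the residual df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None:
        C = np.empty((y.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
    y, x, C = y[keep], x[keep], C[keep]
    X = np.column_stack([np.ones_like(x), x, C])
    beta, se, pval = _ols(y, X)
    return {"cpg_id": cpg_id, "cohort_id": cohort_id, "model_tag": model_tag,
            "beta": float(beta), "se": float(se), "pval": float(pval),
            "n": int(y.size)}


def _design_frame(dataset: CohortDataset, spec: ModelSpec) -> pd.DataFrame:
    cov = dataset.covariates
    if "adipokine_raw" not in cov.columns:
        raise ValueError("phenotype column 'adipokine_raw' absent from cohort")
    frame = cov.copy()
    if spec.model_tag == "smoking":
        smoking = frame["smoking"]
        frame["smoking_former"] = np.where(
            smoking.isna(), np.nan, (smoking == "former").astype(float))
        frame["smoking_current"] = np.where(
            smoking.isna(), np.nan, (smoking == "current").astype(float))
    return frame


def run_model(dataset: CohortDataset, spec: ModelSpec,
              lod: float = 0.0) -> pd.DataFrame:
    """Fit the per-CpG model across the whole methylation matrix.

    The phenotype is preprocessed once (LOD + outlier removal + log);
    rows with a missing phenotype or covariate are dropped for the whole
    model (BMI/smoking missingness therefore shrinks those sensitivity
    analyses).  Methylation is complete in the synthetic cohorts, so the
    per-CpG fits share one design matrix and are solved in one batched
    least-squares pass; CpGs with missing β values fall back to per-CpG
    complete-case fits.
    """
    frame = _design_frame(dataset, spec)
    log_adipo, _ = preprocess_adipokine(frame["adipokine_raw"].to_numpy(), lod=lod)
    frame = frame.assign(log_adipokine=log_adipo.to_numpy())
    cols = ["log_adipokine", *spec.covariate_columns()]
    missing_cols = [c for c in cols if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"covariates absent from cohort: {missing_cols}")
    sub = frame[cols].astype(float)
    keep = sub.notna().all(axis=1)
    sub = sub[keep]
    Y = dataset.beta.loc[keep.index[keep]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), sub.to_numpy()])

    cpg_ids = list(dataset.beta.columns)
    complete = np.all(np.isfinite(Y), axis=0)
    beta = np.full(len(cpg_ids), np.nan)
    se = np.full(len(cpg_ids), np.nan)
    pval = np.full(len(cpg_ids), np.nan)
    nobs = np.zeros(len(cpg_ids), dtype=int)
    if complete.any():
        b, s, p = _ols(Y[:, complete], X)
        beta[complete], se[complete], pval[complete] = b, s, p
        nobs[complete] = X.shape[0]
    for j in np.flatnonzero(~complete):
        rec = fit_probe(Y[:, j], X[:, 1], X[:, 2:], cpg_id=cpg_ids[j])
        beta[j], se[j], pval[j], nobs[j] = rec["beta"], rec["se"], rec["pval"], rec["n"]

    return pd.DataFrame({
        "cpg_id": cpg_ids,
        "cohort_id": dataset.cohort_id,
        "model_tag": spec.model_tag,
        "beta": beta, "se": se, "pval": pval, "n": nobs,
    })


@dataclass
class ProbeFilterReport:
    dropped: dict = field(default_factory=dict)
    kept: int = 0


def filter_probes(records: pd.DataFrame, annotation: pd.DataFrame,
                  min_n: int = 50):
    """Drop probes on sex chromosomes, blacklisted, variant/ambiguous, or
    estimated from fewer than ``min_n`` observations.

    Returns ``(filtered, report)``; raises if any record's CpG is missing
    from the annotation.
    """
    ann = annotation.set_index("cpg_id")
    unknown = sorted(set(records["cpg_id"]) - set(ann.index))
    if unknown:
        raise ValueError(f"unannotated CpG ids: {unknown[:10]}"
                         + (" ..." if len(unknown) > 10 else ""))
    flags = ann.loc[records["cpg_id"],
                    ["on_sex_chrom", "blacklisted", "variant_or_ambiguous"]]
    flags = flags.reset_index(drop=True)
    low_n = (records["n"] < min_n).reset_index(drop=True)
    report = ProbeFilterReport(dropped={
        "on_sex_chrom": int(flags["on_sex_chrom"].sum()),
        "blacklisted": int(flags["blacklisted"].sum()),
        "variant_or_ambiguous": int(flags["variant_or_ambiguous"].sum()),
        "low_n": int(low_n.sum()),
    })
    drop = flags.any(axis=1).to_numpy() | low_n.to_numpy()
    out = records.loc[~drop].reset_index(drop=True)
    report.kept = len(out)
    return out, report
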