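"""Fixed-effects inverse-variance meta-analysis across cohorts.

Per CpG, bias/inflation-corrected cohort effects are pooled with weights
w_i = 1/se_i²; Cochran's Q and I² quantify between-cohort heterogeneity
(CpGs with I² ≥ 80% are removed — none are expected under the generative
model's shared effects); Benjamini–Hochberg FDR is applied across all
surviving CpGs and significance is declared at q ≤ 0.05.  A CpG is
*robust* when it stays significant in every sensitivity model (smoking,
BMI, extended cell proportions); BMI-sensitive CpGs are reported apart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inflation import bh_adjust

__all__ = ["pool_fixed", "cochran_heterogeneity", "meta_analyse",
           "robust_set", "cross_adipokine_summary"]


def pool_fixed(betas, ses):
    """Inverse-variance fixed-effects pooling.

    Returns ``(beta_pooled, se_pooled, z, pval)`` with w_i = 1/se_i²,
    beta = Σw·b/Σw, se = (Σw)^{-1/2} and a two-sided normal p-value.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("cannot pool an empty set of cohort effects")
    if np.any(~(s > 0)):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / (s * s)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, float(z), p


def cochran_heterogeneity(betas, ses):
    """Cochran's Q, its df and I² = max(0, (Q−df)/Q)·100.

    Requires >= 2 cohorts; I² is clamped at 0 and capped at 100.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs >= 2 cohorts")
    w = 1.0 / (s * s)
    pooled = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    i2 = 0.0 if Q <= 0 else max(0.0, (Q - df) / Q) * 100.0
    return Q, df, float(min(i2, 100.0))


def meta_analyse(cohort_tables: list[pd.DataFrame], alpha: float = 0.05,
                 i2_max: float = 80.0, min_n: int = 50) -> pd.DataFrame:
    """Pool per-CpG association records from >= 2 cohorts.

    Cohort rows with n < ``min_n`` or missing effect/SE are dropped before
    pooling; a CpG is pooled over whichever cohorts report it (single-
    cohort CpGs are pooled trivially and flagged with i2 = NaN); CpGs
    with I² >= ``i2_max`` are removed; BH-FDR runs over the survivors.
    """
    if len(cohort_tables) < 2:
        raise ValueError("meta-analysis needs >= 2 cohort tables")
    stacked = pd.concat(cohort_tables, ignore_index=True)
    stacked = stacked[(stacked["n"] >= min_n)
                      & stacked["beta"].notna() & (stacked["se"] > 0)]
    if stacked.empty:
        raise ValueError("no CpG reported by any cohort after row filters")

    # pivot to CpG x cohort matrices; pooling is then fully vectorized
    cohort_order = list(dict.fromkeys(stacked["cohort_id"]))
    B = stacked.pivot(index="cpg_id", columns="cohort_id", values="beta")
    B = B.reindex(columns=cohort_order)
    S = stacked.pivot(index="cpg_id", columns="cohort_id", values="se")
    S = S.reindex(columns=cohort_order)
    N = stacked.pivot(index="cpg_id", columns="cohort_id", values="n")
    N = N.reindex(columns=cohort_order)
    b = B.to_numpy(float)
    present = ~np.isnan(b)
    w = np.where(present, 1.0 / (S.to_numpy(float) ** 2), 0.0)
    sw = w.sum(axis=1)
    beta = np.nansum(w * b, axis=1) / sw
    se = 1.0 / np.sqrt(sw)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    k = present.sum(axis=1)
    Q = np.nansum(w * (b - beta[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q) * 100.0, 0.0)
    i2 = np.minimum(i2, 100.0)
    Q = np.where(k >= 2, Q, np.nan)
    i2 = np.where(k >= 2, i2, np.nan)
    sign = np.where(present, np.where(b > 0, "+", "-"), "?")
    direction = ["".join(row) for row in sign]
    table = pd.DataFrame({
        "cpg_id": B.index, "beta_pooled": beta, "se_pooled": se, "z": z,
        "pval": pval, "n_total": np.nansum(N.to_numpy(float), axis=1).astype(int),
        "n_cohorts": k, "Q": Q, "i2": i2,
        "direction": direction, "single_cohort": k == 1,
    }).reset_index(drop=True)
    keep = ~(table["i2"] >= i2_max)  # NaN i2 (single cohort) is kept, flagged
    table = table.loc[keep].reset_index(drop=True)
    table["qval"] = bh_adjust(table["pval"].to_numpy())
    table["significant"] = table["qval"] <= alpha
    return table


def robust_set(base: pd.DataFrame,
               sensitivity: dict[str, pd.DataFrame],
               alpha: float = 0.05):
    """CpGs significant in the base model and in every sensitivity model.

    ``sensitivity`` maps model tag → MetaRecord table (each with its own
    within-model FDR).  Returns ``(robust_ids, survival)`` where
    ``survival`` has one row per base-significant CpG with a boolean
    column per model and a ``bmi_sensitive`` flag (significant in every
    model except BMI).  A CpG absent from a sensitivity table (e.g.
    removed there by the heterogeneity filter) counts as not surviving
    that model.
    """
    required = set(sensitivity)
    if not required:
        raise ValueError("no sensitivity tables supplied")
    base_sig = base.loc[base["significant"], "cpg_id"]
    survival = pd.DataFrame({"cpg_id": base_sig})
    for tag, table in sensitivity.items():
        qmap = table.set_index("cpg_id")["qval"]
        q = qmap.reindex(base_sig).to_numpy()
        survival[tag] = np.where(np.isnan(q), False, q <= alpha)
    model_cols = list(sensitivity)
    survival["robust"] = survival[model_cols].all(axis=1)
    non_bmi = [c for c in model_cols if c != "bmi"]
    if "bmi" in sensitivity:
        survival["bmi_sensitive"] = (survival[non_bmi].all(axis=1)
                                     & ~survival["bmi"])
    robust_ids = set(survival.loc[survival["robust"], "cpg_id"])
    return robust_ids, survival


def cross_adipokine_summary(table_a: pd.DataFrame, table_b: pd.DataFrame):
    """Overlap and effect-size correlations between two adipokine analyses.

    Returns a dict with the count of CpGs significant in both, Pearson r
    (and p) of pooled effects over the union of significant CpGs, and the
    same over CpGs uniquely significant in one analysis.
    """
    a = table_a.set_index("cpg_id")
    b = table_b.set_index("cpg_id")
    sig_a = set(a.index[a["significant"]])
    sig_b = set(b.index[b["significant"]])
    union = sorted((sig_a | sig_b) & set(a.index) & set(b.index))
    if not union:
        raise ValueError("no CpG significant in either analysis")
    overlap = sig_a & sig_b
    unique = sorted((sig_a ^ sig_b) & set(a.index) & set(b.index))

    def corr(ids):
        if len(ids) < 3:
            return np.nan, np.nan
        r, p = stats.pearsonr(a.loc[ids, "beta_pooled"],
                              b.loc[ids, "beta_pooled"])
        return float(r), float(p)

    r_union, p_union = corr(union)
    r_unique, p_unique = corr(unique)
    return {
        "n_overlap": len(overlap),
        "n_union": len(union),
        "n_unique": len(unique),
        "r_union": r_union, "p_union": p_union,
        "r_unique": r_unique, "p_unique": p_unique,
    }
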