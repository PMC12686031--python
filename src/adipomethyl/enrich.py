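"""Enrichment of CpG sets for catalogue traits, chromatin states and gene
sets.

Trait and chromatin-state enrichment use logistic regression of feature
membership on target membership over the CpG background — the fitted odds
ratio equals the 2×2 cross-product ratio in this covariate-free setting.
When any cell of the 2×2 table is zero, the Haldane–Anscombe +0.5
continuity correction replaces the regression and the result is flagged.
Gene-set over-representation uses the one-sided hypergeometric tail.
BH-FDR is applied within each family (traits, states, one GMT library).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inflation import bh_adjust

__all__ = ["EnrichmentResult", "filter_catalogue", "two_by_two_enrichment",
           "run_state_enrichment", "run_trait_enrichment", "overrepresentation"]

ADULT_TISSUES = {"whole blood", "leukocytes"}


@dataclass
class EnrichmentResult:
    feature: str
    a: int  # target ∩ feature
    b: int  # target \ feature
    c: int  # non-target ∩ feature
    d: int  # non-target \ feature
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    qval: float = np.nan
    continuity_corrected: bool = False


def filter_catalogue(records: pd.DataFrame,
                     recode: dict[str, str] | None = None,
                     min_n: int = 500,
                     min_cpgs: int = 100) -> pd.DataFrame:
    """Apply the catalogue quality filters and merge trait synonyms.

    Keeps rows with a PubMed ID, study n >= ``min_n``, at least
    ``min_cpgs`` CpGs reported, nominal p-values present, adult samples,
    and whole-blood/leukocyte tissue.  ``recode`` maps raw trait names to
    canonical ones (e.g. 'body mass index' → 'BMI'); rows merging onto
    the same trait have their CpG lists unioned.
    """
    required = ["trait", "pubmed_id", "n", "n_cpgs_reported", "has_pval",
                "age_group", "tissue", "cpgs"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"catalogue missing required column(s) {missing}")
    df = records.copy()
    keep = (df["pubmed_id"].astype(str).str.len() > 0) \
        & (df["pubmed_id"].notna()) \
        & (df["n"] >= min_n) \
        & (df["n_cpgs_reported"] >= min_cpgs) \
        & df["has_pval"].astype(bool) \
        & (df["age_group"] == "adult") \
        & (df["tissue"].isin(ADULT_TISSUES))
    df = df.loc[keep].copy()
    if recode:
        df["trait"] = df["trait"].map(lambda t: recode.get(t, t))
        merged = (df.groupby("trait", sort=False)
                    .agg({"cpgs": lambda s: ",".join(
                        sorted(set(c for row in s for c in str(row).split(",") if c)))})
                    .reset_index())
        first = df.drop_duplicates("trait").drop(columns="cpgs")
        df = first.merge(merged, on="trait")
    return df.reset_index(drop=True)


def _wald_or(a, b, c, d, continuity: bool):
    """OR and 95% Wald CI from a 2×2 table, optionally +0.5-corrected."""
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if continuity else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    log_se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(or_)
    ci = (np.exp(log_or - 1.96 * log_se), np.exp(log_or + 1.96 * log_se))
    z = log_or / log_se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(or_), float(ci[0]), float(ci[1]), float(p)


def two_by_two_enrichment(target_set, feature_set, background,
                          continuity: bool = True) -> EnrichmentResult:
    """Enrichment of ``feature_set`` membership among ``target_set`` CpGs.

    Fits a logistic regression of feature membership on a target
    indicator across the background universe; with any zero cell it falls
    back to the +0.5-corrected cross-product ratio (flagged).  The target
    must be a subset of the background.
    """
    background = set(background)
    target = set(target_set)
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    if not target <= background:
        raise ValueError("target CpGs must all lie in the background universe")
    feature = set(feature_set) & background
    a = len(target & feature)
    b = len(target - feature)
    c = len(feature - target)
    d = len(background) - a - b - c

    if min(a, b, c, d) == 0:
        or_, lo, hi, p = _wald_or(a, b, c, d, continuity=continuity)
        return EnrichmentResult("feature", a, b, c, d, or_, lo, hi, p,
                                continuity_corrected=True)
    # logistic regression: feature membership ~ target indicator
    import statsmodels.api as sm
    y = np.concatenate([np.ones(a + c), np.zeros(b + d)])
    x = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    coef, se = fit.params[1], fit.bse[1]
    or_ = float(np.exp(coef))
    lo, hi = float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))
    return EnrichmentResult("feature", a, b, c, d, or_, lo, hi,
                            float(fit.pvalues[1]))


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["qval"] = bh_adjust(df["pval"].to_numpy())
    return df


def run_state_enrichment(target_set, annotation: pd.DataFrame,
                         epigenome_id: str = "E062",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-state enrichment of the target CpGs in one reference epigenome.

    One 2×2 test per 15-state label present in the background, BH-FDR
    across states; states absent from the background are skipped with a
    note row (NaN statistics).  The background is the full annotation.
    """
    col = f"state_{epigenome_id}"
    if col not in annotation.columns:
        raise ValueError(f"annotation lacks epigenome {epigenome_id!r}")
    background = list(annotation["cpg_id"])
    states = annotation[col]
    results = []
    from .io import CHROMATIN_STATES
    for state in CHROMATIN_STATES:
        members = set(annotation.loc[states == state, "cpg_id"])
        if not members:
            continue  # state absent from background: skipped
        r = two_by_two_enrichment(target_set, members, background)
        r.feature = state
        results.append(r)
    df = _results_frame(results)
    df["enriched"] = (df["qval"] <= alpha) & (df["odds_ratio"] > 1)
    df["depleted"] = (df["qval"] <= alpha) & (df["odds_ratio"] < 1)
    return df


def run_trait_enrichment(target_set, catalogue: pd.DataFrame,
                         background) -> pd.DataFrame:
    """Per-trait enrichment against a (filtered) trait catalogue.

    Traits with no catalogue CpG inside the background are skipped;
    BH-FDR across the tested traits.
    """
    background = set(background)
    results = []
    for _, row in catalogue.iterrows():
        members = {c for c in str(row["cpgs"]).split(",") if c} & background
        if not members:
            continue
        r = two_by_two_enrichment(target_set, members, background)
        r.feature = row["trait"]
        results.append(r)
    return _results_frame(results)


def overrepresentation(gene_list, library: dict[str, list[str]],
                       universe=None) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    ``universe`` defaults to the union of the library's genes; the query
    list is intersected with it.  P(X >= overlap) under sampling
    len(query) genes from the universe with the set as successes; BH-FDR
    within the library.
    """
    if universe is None:
        universe = set().union(*library.values()) if library else set()
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(gene_list) & universe
    rows = []
    for name, members in library.items():
        mset = set(members) & universe
        if not mset:
            continue
        k = len(query & mset)
        # P(X >= k), X ~ Hypergeom(N=|universe|, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(mset), len(query)))
        rows.append({"set_name": name, "n_set": len(mset),
                     "n_query": len(query), "overlap": k,
                     "n_universe": len(universe), "pval": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["qval"] = bh_adjust(df["pval"].to_numpy())
    return df
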