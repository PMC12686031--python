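"""Bidirectional two-sample Mendelian randomization and triangulation.

Exposure and outcome summary statistics are harmonized to a common
effect allele (sign flips for swapped alleles, strand-flip resolution via
A↔T/C↔G complements, palindromic SNPs dropped above a minor-allele-
frequency threshold).  Causal effects use the Wald ratio for a single
instrument and fixed-effect inverse-variance weighting for several; the
same machinery serves CpG→adipokine, adipokine→CpG (trans-mQTL outcomes)
and CpG→metabolic-trait designs, with BH-FDR across tested exposures.

Triangulation correlates, across CpGs, the *observed* effect of an
instrument on the outcome with the effect *predicted* through the
exposure path: forward, β_mQTL × β_EWAS against the lead instrument's
GWAS effect; reverse, an EAF-weighted polygenic-score effect on DNAm
against (PGS→adipokine) × (adipokine→CpG).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inflation import bh_adjust

__all__ = ["harmonize", "wald_ratio", "ivw", "run_mr",
           "predicted_effect_forward", "reverse_observed_predicted",
           "triangulate"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_MAF_MAX = 0.42


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_maf_max: float | None = PALINDROMIC_MAF_MAX
              ) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele per variant.

    Returns an InstrumentPair table (one row per shared variant) with a
    ``harmonization_action`` of kept / flipped / dropped_palindromic /
    dropped_incompatible.  Palindromic (A/T or C/G) variants are dropped
    when their minor-allele frequency exceeds ``palindromic_maf_max``
    (pass None to disable).  Duplicated variants in either table raise.
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        if tab["variant_id"].duplicated().any():
            dup = tab.loc[tab["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicated variant {dup!r} in {name} table")
    exp = exposure.set_index("variant_id")
    out = outcome.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    rows = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        action = None
        flip = False
        if _is_palindromic(e_ea, e_oa):
            maf = min(e["eaf"], 1.0 - e["eaf"])
            if palindromic_maf_max is not None and maf > palindromic_maf_max:
                action = "dropped_palindromic"
            elif (o_ea, o_oa) == (e_ea, e_oa):
                action = "kept"
            elif (o_ea, o_oa) == (e_oa, e_ea):
                action, flip = "flipped", True
            else:
                action = "dropped_incompatible"
        elif (o_ea, o_oa) == (e_ea, e_oa):
            action = "kept"
        elif (o_ea, o_oa) == (e_oa, e_ea):
            action, flip = "flipped", True
        elif (COMPLEMENT[o_ea], COMPLEMENT[o_oa]) == (e_ea, e_oa):
            action = "kept"  # same alleles reported on the other strand
        else:
            # complement-plus-swap (e.g. A/G vs C/T) is ambiguous between a
            # strand flip and a genuine mismatch: dropped, not guessed
            action = "dropped_incompatible"
        rows.append({
            "variant_id": vid,
            "effect_allele": e_ea,
            "beta_exposure": float(e["beta"]),
            "se_exposure": float(e["se"]),
            "beta_outcome": float(-o["beta"] if flip else o["beta"]),
            "se_outcome": float(o["se"]),
            "eaf": float(e["eaf"]),
            "harmonization_action": action,
        })
    return pd.DataFrame(rows, columns=[
        "variant_id", "effect_allele", "beta_exposure", "se_exposure",
        "beta_outcome", "se_outcome", "eaf", "harmonization_action"])


def _usable(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs[pairs["harmonization_action"].isin(["kept", "flipped"])]


def wald_ratio(pair) -> dict:
    """Single-instrument causal estimate β_Y/β_X with first-order SE."""
    bx = float(pair["beta_exposure"])
    by = float(pair["beta_outcome"])
    sy = float(pair["se_outcome"])
    if bx == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    beta = by / bx
    se = sy / abs(bx)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return {"method": "wald", "n_instruments": 1, "beta": beta, "se": se,
            "pval": p}


def ivw(pairs: pd.DataFrame) -> dict:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments.

    Equivalent to a zero-intercept WLS of β_Y on β_X with weights
    1/se_Y²: beta = Σ(β_Xβ_Y/se_Y²)/Σ(β_X²/se_Y²), se = (Σβ_X²/se_Y²)^-½.
    """
    if len(pairs) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    bx = pairs["beta_exposure"].to_numpy(float)
    by = pairs["beta_outcome"].to_numpy(float)
    sy = pairs["se_outcome"].to_numpy(float)
    w = 1.0 / (sy * sy)
    denom = float(np.sum(bx * bx * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return {"method": "ivw", "n_instruments": int(len(pairs)), "beta": beta,
            "se": se, "pval": p}


def run_mr(exposure_instruments: dict[str, pd.DataFrame],
           outcome_stats: pd.DataFrame,
           outcome_id: str = "outcome"):
    """Wald/IVW MR for every exposure with usable instruments.

    ``exposure_instruments`` maps exposure id (CpG or adipokine) to its
    instrument summary stats; ``outcome_stats`` is one table covering the
    outcome associations of those variants.  Exposures whose instruments
    all drop during harmonization (or are absent from the outcome table)
    are returned in the ``untested`` list.  BH-FDR across tested
    exposures.  Returns ``(results, untested)``.
    """
    if not exposure_instruments:
        raise ValueError("empty instrument map")
    rows, untested = [], []
    for exp_id, instruments in exposure_instruments.items():
        pairs = _usable(harmonize(instruments, outcome_stats))
        pairs = pairs[pairs["beta_exposure"] != 0.0]
        if pairs.empty:
            untested.append(exp_id)
            continue
        est = wald_ratio(pairs.iloc[0]) if len(pairs) == 1 else ivw(pairs)
        rows.append({"exposure_id": exp_id, "outcome_id": outcome_id, **est})
    if not rows:
        return pd.DataFrame(columns=["exposure_id", "outcome_id", "method",
                                     "n_instruments", "beta", "se", "pval",
                                     "qval"]), untested
    results = pd.DataFrame(rows)
    results["qval"] = bh_adjust(results["pval"].to_numpy())
    return results, untested


def predicted_effect_forward(beta_mqtl: float, beta_ewas: float) -> float:
    """Path-product prediction of an instrument's effect on the adipokine."""
    return beta_mqtl * beta_ewas


def forward_observed_predicted(cis_mqtl: pd.DataFrame, gwas: pd.DataFrame,
                               ewas: pd.DataFrame) -> pd.DataFrame:
    """Per CpG: observed = lead cis-mQTL's GWAS effect on the adipokine;
    predicted = β_mQTL × β_EWAS for that instrument.

    The lead instrument is the cis-mQTL with the smallest p-value.
    """
    gw = gwas.set_index("variant_id")
    ew = ewas.set_index("cpg_id")
    rows = []
    for cpg, grp in cis_mqtl.groupby("trait_id", sort=True):
        lead = grp.loc[grp["pval"].idxmin()]
        vid = lead["variant_id"]
        if vid not in gw.index or cpg not in ew.index:
            continue
        rows.append({
            "cpg_id": cpg,
            "observed": float(gw.loc[vid, "beta"]),
            "predicted": predicted_effect_forward(
                float(lead["beta"]), float(ew.loc[cpg, "beta"])),
            "direction": "forward",
        })
    return pd.DataFrame(rows)


def reverse_observed_predicted(adipokine_instruments: pd.DataFrame,
                               trans_mqtl: pd.DataFrame,
                               ewas: pd.DataFrame) -> pd.DataFrame:
    """EAF-weighted polygenic-score triangulation for adipokine→DNAm.

    For CpG j with adipokine instruments k (weights w_k = EAF_k,
    normalized): observed_j = Σ w_k β(SNP_k→CpG_j); predicted_j =
    (Σ w_k β(SNP_k→adipokine)) × β_EWAS,j.
    """
    inst = adipokine_instruments
    w = inst["eaf"].to_numpy(float)
    if w.size == 0 or np.sum(w) <= 0:
        raise ValueError("no instruments / zero EAF weights for the score")
    w = w / w.sum()
    pgs_adipo = float(np.sum(w * inst["beta"].to_numpy(float)))
    tm = trans_mqtl.pivot(index="trait_id", columns="variant_id", values="beta")
    tm = tm.reindex(columns=inst["variant_id"])
    ew = ewas.set_index("cpg_id")["beta"]
    rows = []
    for cpg in tm.index:
        if cpg not in ew.index or tm.loc[cpg].isna().any():
            continue
        observed = float(np.sum(w * tm.loc[cpg].to_numpy(float)))
        rows.append({"cpg_id": cpg, "observed": observed,
                     "predicted": pgs_adipo * float(ew.loc[cpg]),
                     "direction": "reverse"})
    return pd.DataFrame(rows)


def triangulate(records: pd.DataFrame):
    """Pearson correlation of observed vs predicted effects across CpGs."""
    if len(records) < 3:
        raise ValueError("triangulation needs >= 3 records")
    obs = records["observed"].to_numpy(float)
    pred = records["predicted"].to_numpy(float)
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("zero variance in observed or predicted effects")
    r, p = stats.pearsonr(obs, pred)
    scatter = records[["cpg_id", "observed", "predicted"]].copy()
    return float(r), float(p), scatter
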