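"""Shared settings for the analysis drivers.

The synthetic consortium mirrors the published study layout: five
cohorts with the published per-cohort sample sizes per adipokine and
2000 CpGs.  Planted truth per adipokine (independent between the two,
from different child seeds): two position-adjacent clusters of CpGs —
so the DMR stage has regions to find — plus scattered single CpGs, 30%
of which act through BMI.  Cohort-level data are regenerated
deterministically from SEED instead of being stored (the beta matrices
alone would be ~100 MB of text).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from adipomethyl import simulate

SEED = 2026
N_CPGS = 2000
EFFECT_SD = 0.02
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
RESULTS.mkdir(parents=True, exist_ok=True)

_OFFSET = {"adiponectin": 0, "leptin": 1}


def annotation():
    return simulate.generate_annotation(N_CPGS, n_genes=400, n_traits=30,
                                        seed=SEED)


def _clusters(ann: pd.DataFrame, min_size: int = 3) -> list[list[str]]:
    """Runs of >= min_size unflagged CpGs with consecutive gaps < 1 kb."""
    clean = ann[~ann[["on_sex_chrom", "blacklisted",
                      "variant_or_ambiguous"]].any(axis=1)]
    runs = []
    for _, sub in clean.sort_values("pos").groupby("chrom"):
        pos = sub["pos"].to_numpy()
        ids = sub["cpg_id"].to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= 1000:
                if i - start >= min_size:
                    runs.append(list(ids[start:i]))
                start = i
    return runs


def planted_truth(adipokine: str, ann: pd.DataFrame) -> simulate.TruthTable:
    rng = np.random.default_rng(SEED + 100 + _OFFSET[adipokine])
    cpg_ids = list(ann["cpg_id"])
    beta = np.zeros(len(cpg_ids))
    mediated = np.zeros(len(cpg_ids), dtype=bool)
    index = {c: j for j, c in enumerate(cpg_ids)}

    runs = _clusters(ann)
    picked = [runs[k] for k in rng.choice(len(runs), size=2, replace=False)]
    for run in picked:
        sign = rng.choice([-1.0, 1.0])
        for c in run[:4]:
            beta[index[c]] = sign * rng.normal(1.5, 0.25) * EFFECT_SD
    clustered = {c for run in picked for c in run[:4]}

    singles = rng.choice([c for c in cpg_ids if c not in clustered],
                         size=14, replace=False)
    for k, c in enumerate(singles):
        beta[index[c]] = rng.choice([-1.0, 1.0]) * rng.normal(1.2, 0.4) * EFFECT_SD
        mediated[index[c]] = k < round(0.3 * len(singles))
    return simulate.TruthTable(effects=pd.DataFrame({
        "cpg_id": cpg_ids, "true_beta": beta, "mediated_by_bmi": mediated,
        "smoking_confounded": False}))


def consortium(adipokine: str):
    ann, *_ = annotation()
    truth = planted_truth(adipokine, ann)
    configs = simulate.default_consortium_configs(
        adipokine, seed=SEED + _OFFSET[adipokine], n_cpgs=N_CPGS,
        frac_causal=0.0, effect_size_sd=EFFECT_SD)
    return simulate.generate_consortium(configs, truth=truth)
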