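"""Synthetic multi-cohort data with known ground truth.

Every downstream stage (per-CpG regression, bias/inflation correction,
meta-analysis, DMR calling, enrichment, eQTM, Mendelian randomization,
triangulation) is exercised on data from the generators here, which run
the downstream models *forward*:

* methylation β values are baseline + planted adipokine effect +
  covariate effects + Gaussian noise, clipped to [0, 1];
* adipokine levels are log-normal, correlated with BMI (strongly and
  positively for leptin, weakly and negatively for adiponectin);
* cell proportions come from a Dirichlet over 12 leukocyte types whose
  reference cell (neutrophils) is implicit, so included proportions sum
  to less than 1;
* genetic summary statistics come from explicit structural models
  (forward DNAm→adipokine, reverse adipokine→DNAm, confounded, null)
  with sampling noise scaled as 1/sqrt(2·n·EAF·(1−EAF)).

Determinism: one global integer seed expands into per-stage child seeds
through fixed spawn keys (:data:`STAGE_KEYS`); the same seed and config
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CHROMATIN_STATES

__all__ = [
    "CohortConfig", "CohortDataset", "TruthTable", "GeneticScenarioConfig",
    "generate_cohort", "generate_consortium", "generate_annotation",
    "generate_genetic_scenario", "generate_expression",
    "default_consortium_configs", "CONSORTIUM_SIZES",
]

#: fixed spawn keys expanding the global seed into per-stage streams
STAGE_KEYS = {
    "truth": 0,
    "cohort": 1,
    "annotation": 2,
    "genetic": 3,
    "expression": 4,
}

#: published per-cohort sample sizes of the two meta-analyses
CONSORTIUM_SIZES = {
    "adiponectin": (807, 718, 701, 124, 441),
    "leptin": (1702, 723, 701, 94, 441),
}

COHORT_NAMES = ("KORA", "LLS", "LLD", "TwinsUK", "SHIP-TREND")

#: Dirichlet mean composition over 12 leukocyte types (neutrophils are the
#: implicit reference cell and are never included as a covariate).
CELL_MEANS = {
    "Neu": 0.500, "Eos": 0.025, "Baso": 0.005, "Mono": 0.080, "NK": 0.060,
    "Bmem": 0.020, "Bnv": 0.030, "CD4Tmem": 0.100, "CD4Tnv": 0.070,
    "Treg": 0.030, "CD8Tmem": 0.045, "CD8Tnv": 0.035,
}
CELL_CONCENTRATION = 150.0

MAIN_CELLS = ["CD8T", "CD4T", "NK", "Mono", "B"]
EXTENDED_CELLS = [c for c in CELL_MEANS if c != "Neu"]

#: default BMI–log(adipokine) correlations
BMI_CORR = {"adiponectin": -0.3, "leptin": 0.7}

#: default log-normal parameters (log µg/ml resp. log ng/ml)
ADIPOKINE_LOGNORMAL = {"adiponectin": (1.95, 0.5), "leptin": (2.5, 0.8)}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one cohort."""

    cohort_id: str = "cohort"
    n_samples: int = 500
    n_cpgs: int = 1000
    adipokine: str = "adiponectin"
    adipokine_location: float | None = None  # log-scale mean; default per adipokine
    adipokine_scale: float | None = None     # log-scale SD
    bmi_corr: float | None = None            # corr(BMI, log adipokine)
    frac_causal: float = 0.05
    effect_size_sd: float = 0.01       # DNAm β per unit log-adipokine
    frac_bmi_mediated: float = 0.0     # fraction of planted effects routed via BMI
    frac_smoking_confounded: float = 0.0  # fraction of null CpGs driven by smoking
    noise_sd: float = 0.05             # residual DNAm SD
    effect_heterogeneity_sd: float = 0.0  # between-cohort SD of planted effects
    intercept_shift_sd: float = 0.01   # cohort-level baseline shift
    frac_missing_smoking: float = 0.05
    frac_missing_bmi: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_causal", "frac_bmi_mediated", "frac_smoking_confounded",
                     "frac_missing_smoking", "frac_missing_bmi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.adipokine not in ADIPOKINE_LOGNORMAL:
            raise ValueError(f"unknown adipokine {self.adipokine!r}")

    @property
    def location(self) -> float:
        return (ADIPOKINE_LOGNORMAL[self.adipokine][0]
                if self.adipokine_location is None else self.adipokine_location)

    @property
    def scale(self) -> float:
        return (ADIPOKINE_LOGNORMAL[self.adipokine][1]
                if self.adipokine_scale is None else self.adipokine_scale)

    @property
    def r_bmi(self) -> float:
        return BMI_CORR[self.adipokine] if self.bmi_corr is None else self.bmi_corr


@dataclass
class TruthTable:
    """Planted effects (and, for genetic scenarios, the causal scenario)."""

    effects: pd.DataFrame  # cpg_id, true_beta, mediated_by_bmi, smoking_confounded
    scenario: str | None = None

    def causal_ids(self) -> list[str]:
        eff = self.effects
        return list(eff.loc[eff["true_beta"] != 0.0, "cpg_id"])


@dataclass
class CohortDataset:
    """One cohort's methylation matrix plus phenotype/covariate table.

    ``covariates`` columns: adipokine_raw, age, sex_female, bmi, smoking
    (never/former/current, possibly NA), the five main cell proportions,
    the 11 extended cell proportions, technical_1, technical_2.
    """

    cohort_id: str
    adipokine: str
    beta: pd.DataFrame
    covariates: pd.DataFrame
    clip_fraction: float


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# shared per-CpG architecture (baselines, covariate effects, planted truth)
# ---------------------------------------------------------------------------

@dataclass
class _Architecture:
    cpg_ids: list[str]
    baseline: np.ndarray
    age_coef: np.ndarray
    sex_coef: np.ndarray
    cell_coef: np.ndarray       # (n_cpgs, 5) on the main proportions
    tech_coef: np.ndarray       # (n_cpgs, 2)
    true_beta: np.ndarray       # marginal DNAm-per-log-adipokine slope
    mediated: np.ndarray        # bool
    smoking_coef: np.ndarray    # DNAm shift per smoking score unit
    truth: TruthTable


def _build_architecture(config: CohortConfig) -> _Architecture:
    rng = _rng(config.seed, "truth")
    m = config.n_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(m)]
    baseline = rng.uniform(0.1, 0.9, size=m)
    age_coef = rng.normal(0.0, 2e-4, size=m)
    sex_coef = rng.normal(0.0, 5e-3, size=m)
    cell_coef = rng.normal(0.0, 2e-2, size=(m, len(MAIN_CELLS)))
    tech_coef = rng.normal(0.0, 2e-3, size=(m, 2))

    n_causal = int(round(config.frac_causal * m))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    true_beta = np.zeros(m)
    true_beta[causal_idx] = rng.normal(0.0, config.effect_size_sd, size=n_causal)
    # guard against effects planted at numerically-zero size
    tiny = np.abs(true_beta[causal_idx]) < 1e-6
    true_beta[causal_idx[tiny]] = 1e-6

    mediated = np.zeros(m, dtype=bool)
    n_med = int(round(config.frac_bmi_mediated * n_causal))
    if n_med:
        mediated[rng.choice(causal_idx, size=n_med, replace=False)] = True

    smoking_coef = np.zeros(m)
    null_idx = np.setdiff1d(np.arange(m), causal_idx)
    n_smk = int(round(config.frac_smoking_confounded * null_idx.size))
    if n_smk:
        smk_idx = rng.choice(null_idx, size=n_smk, replace=False)
        smoking_coef[smk_idx] = rng.choice([-1.0, 1.0], size=n_smk) * \
            rng.uniform(2.0, 4.0, size=n_smk) * config.effect_size_sd

    truth = TruthTable(effects=pd.DataFrame({
        "cpg_id": cpg_ids,
        "true_beta": true_beta,
        "mediated_by_bmi": mediated,
        "smoking_confounded": smoking_coef != 0.0,
    }))
    return _Architecture(cpg_ids, baseline, age_coef, sex_coef, cell_coef,
                         tech_coef, true_beta, mediated, smoking_coef, truth)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: multiplicative smoking effect on the adipokine (log scale), making
#: smoking a genuine confounder for the smoking-driven CpGs
SMOKING_LOG_EFFECT = {"never": 0.0, "former": -0.05, "current": -0.10}
SMOKING_LEVELS = ("never", "former", "current")
SMOKING_PROBS = (0.45, 0.35, 0.20)


def generate_cohort(config: CohortConfig,
                    _arch: _Architecture | None = None,
                    _cohort_index: int = 0) -> tuple[CohortDataset, TruthTable]:
    """Simulate one cohort under the forward regression model.

    Methylation at CpG j for individual i is
    ``baseline_j + b_j·log(adipokine)_i + covariate effects + N(0, noise_sd)``
    clipped to [0, 1] (for BMI-mediated CpGs the planted effect is carried
    by standardized BMI with the coefficient chosen so the *marginal*
    slope on log adipokine equals the recorded ``true_beta``).  Raises
    :class:`GenerationError` when more than half the β values clip.
    """
    arch = _arch if _arch is not None else _build_architecture(config)
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed, spawn_key=(STAGE_KEYS["cohort"], _cohort_index)))
    n, m = config.n_samples, config.n_cpgs

    age = np.clip(rng.normal(55.0, 10.0, size=n), 20.0, 90.0)
    sex_female = (rng.random(n) < 0.55).astype(float)
    bmi = np.clip(rng.normal(26.0, 4.0, size=n), 16.0, 45.0)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    smoke_score = np.where(smoking == "current", 1.0,
                           np.where(smoking == "former", 0.5, 0.0))

    cells = rng.dirichlet(CELL_CONCENTRATION * np.array(list(CELL_MEANS.values())),
                          size=n)
    cells = pd.DataFrame(cells, columns=list(CELL_MEANS))
    main = pd.DataFrame({
        "CD8T": cells["CD8Tmem"] + cells["CD8Tnv"],
        "CD4T": cells["CD4Tmem"] + cells["CD4Tnv"] + cells["Treg"],
        "NK": cells["NK"],
        "Mono": cells["Mono"],
        "B": cells["Bmem"] + cells["Bnv"],
    })

    z_bmi = (bmi - 26.0) / 4.0
    r = config.r_bmi
    u = rng.standard_normal(n)
    log_adipo = (config.location
                 + config.scale * (r * z_bmi + np.sqrt(1.0 - r * r) * u)
                 + np.vectorize(SMOKING_LOG_EFFECT.get)(smoking))
    adipokine_raw = np.exp(log_adipo)

    technical = rng.standard_normal((n, 2))

    # cohort-level perturbations
    intercept_shift = rng.normal(0.0, config.intercept_shift_sd, size=m)
    beta_here = arch.true_beta.copy()
    if config.effect_heterogeneity_sd > 0:
        beta_here = beta_here + np.where(
            arch.true_beta != 0.0,
            rng.normal(0.0, config.effect_heterogeneity_sd, size=m), 0.0)

    direct = np.where(arch.mediated, 0.0, beta_here)
    # mediated effect routed through BMI with marginal slope = true_beta
    bmi_coef = np.where(arch.mediated, beta_here * config.scale / r, 0.0)

    signal = (arch.baseline[None, :]
              + intercept_shift[None, :]
              + np.outer(log_adipo, direct)
              + np.outer(z_bmi, bmi_coef)
              + np.outer(smoke_score, arch.smoking_coef)
              + np.outer(age, arch.age_coef)
              + np.outer(sex_female, arch.sex_coef)
              + main.to_numpy() @ arch.cell_coef.T
              + technical @ arch.tech_coef.T)
    beta_values = signal + rng.normal(0.0, config.noise_sd, size=(n, m))
    clipped = (beta_values < 0.0) | (beta_values > 1.0)
    clip_fraction = float(clipped.mean())
    if clip_fraction > 0.5:
        raise GenerationError(
            f"infeasible config: {clip_fraction:.0%} of beta values clip")
    beta_values = np.clip(beta_values, 0.0, 1.0)

    smoking_col = pd.Series(smoking, dtype="object")
    smoking_col[rng.random(n) < config.frac_missing_smoking] = np.nan
    bmi_col = pd.Series(bmi)
    bmi_col[rng.random(n) < config.frac_missing_bmi] = np.nan

    sample_ids = [f"{config.cohort_id}_s{i:05d}" for i in range(n)]
    covariates = pd.DataFrame({
        "adipokine_raw": adipokine_raw,
        "age": age, "sex_female": sex_female,
        "bmi": bmi_col.to_numpy(), "smoking": smoking_col.to_numpy(),
        "technical_1": technical[:, 0], "technical_2": technical[:, 1],
    }, index=sample_ids)
    for c in MAIN_CELLS:
        covariates[c] = main[c].to_numpy()
    for c in EXTENDED_CELLS:
        covariates[c] = cells[c].to_numpy()
    covariates.index.name = "sample_id"

    beta_df = pd.DataFrame(beta_values, index=sample_ids, columns=arch.cpg_ids)
    beta_df.index.name = "sample_id"
    dataset = CohortDataset(config.cohort_id, config.adipokine, beta_df,
                            covariates, clip_fraction)
    return dataset, arch.truth


def default_consortium_configs(adipokine: str = "adiponectin",
                               seed: int = 0,
                               n_cpgs: int = 1000,
                               **overrides) -> list[CohortConfig]:
    """Five cohort configs with the published per-cohort sample sizes."""
    sizes = CONSORTIUM_SIZES[adipokine]
    return [CohortConfig(cohort_id=name, n_samples=size, n_cpgs=n_cpgs,
                         adipokine=adipokine, seed=seed, **overrides)
            for name, size in zip(COHORT_NAMES, sizes)]


def generate_consortium(configs: list[CohortConfig],
                        truth: TruthTable | None = None
                        ) -> tuple[list[CohortDataset], TruthTable]:
    """Simulate >= 2 cohorts sharing one set of planted effects.

    All configs must agree on ``n_cpgs``; the per-CpG architecture
    (baselines, covariate effects, planted truth) derives from the first
    config's seed, so cohorts differ only in sampling noise, size and
    cohort-level intercept/batch structure.
    """
    if len(configs) < 2:
        raise ValueError("a consortium needs at least two cohorts")
    if len({c.n_cpgs for c in configs}) != 1:
        raise ValueError("all cohorts must share one CpG set (equal n_cpgs)")
    arch = _build_architecture(configs[0])
    if truth is not None:
        eff = truth.effects.set_index("cpg_id").reindex(arch.cpg_ids)
        if eff["true_beta"].isna().any():
            raise ValueError("supplied TruthTable does not cover the CpG set")
        arch.true_beta = eff["true_beta"].to_numpy(float)
        arch.mediated = eff["mediated_by_bmi"].to_numpy(bool)
        arch.truth = truth
    datasets = []
    for k, cfg in enumerate(configs):
        ds, _ = generate_cohort(cfg, _arch=arch, _cohort_index=k)
        datasets.append(ds)
    return datasets, arch.truth


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

#: baseline chromatin-state frequencies (PBMC-like: mostly quiescent)
STATE_FREQS = np.array([0.06, 0.05, 0.01, 0.06, 0.12, 0.02, 0.08, 0.01,
                        0.02, 0.02, 0.015, 0.02, 0.04, 0.10, 0.375])


def generate_annotation(n_cpgs: int, n_genes: int, n_traits: int, seed: int,
                        epigenome_id: str = "E062",
                        enriched_state: str = "7_Enh",
                        enriched_cpgs: list[str] | None = None,
                        enrichment_or: float = 1.0,
                        target_cpgs: list[str] | None = None,
                        window: int = 100_000):
    """Generate probe annotation, gene models, a trait catalogue and a
    chromatin-state segmentation.

    ``enriched_cpgs`` get their odds of carrying ``enriched_state``
    multiplied by ``enrichment_or``; ``target_cpgs`` seed the planted
    catalogue trait.  Returns ``(annotation, genes, catalogue, state_bed)``.
    """
    if min(n_cpgs, n_genes, n_traits) <= 0:
        raise ValueError("counts must be positive")
    rng = _rng(seed, "annotation")
    cpg_ids = [f"cg{j:08d}" for j in range(n_cpgs)]
    chroms = [f"chr{c}" for c in rng.integers(1, 23, size=n_cpgs)]
    # a few percent of probes carry exclusion flags
    on_sex = rng.random(n_cpgs) < 0.02
    for j in np.flatnonzero(on_sex):
        chroms[j] = "chrX"
    # array-like geometry: probes fall in island-style clusters of 1-5
    # CpGs spaced a few hundred bp, separated by multi-kb gaps
    pos = np.zeros(n_cpgs, dtype=np.int64)
    for chrom in set(chroms):
        idx = [j for j, c in enumerate(chroms) if c == chrom]
        cursor = int(rng.integers(10_000, 1_000_000))
        placed = []
        while len(placed) < len(idx):
            k = min(int(rng.integers(1, 6)), len(idx) - len(placed))
            for _ in range(k):
                placed.append(cursor)
                cursor += int(rng.integers(100, 900))
            cursor += int(rng.integers(5_000, 2_000_000))
        pos[idx] = placed
    blacklisted = rng.random(n_cpgs) < 0.02
    variant = rng.random(n_cpgs) < 0.03

    # chromatin states, with optional odds-multiplied enrichment
    base_p = STATE_FREQS / STATE_FREQS.sum()
    s_idx = CHROMATIN_STATES.index(enriched_state)
    states = np.array([str(s) for s in
                       rng.choice(CHROMATIN_STATES, size=n_cpgs, p=base_p)],
                      dtype=object)
    if enriched_cpgs and enrichment_or != 1.0:
        p0 = base_p[s_idx]
        p1 = enrichment_or * p0 / (1 - p0 + enrichment_or * p0)
        alt = base_p.copy()
        alt[s_idx] = 0.0
        alt = alt / alt.sum() * (1 - p1)
        alt[s_idx] = p1
        target = np.isin(cpg_ids, enriched_cpgs)
        states[target] = rng.choice(CHROMATIN_STATES, size=int(target.sum()), p=alt)

    # gene models: half anchored near a random probe (so cis windows are
    # populated), half placed independently along each chromosome
    g_chrom, g_start = [], []
    for g in range(n_genes):
        if g % 2 == 0:
            j = int(rng.integers(0, n_cpgs))
            g_chrom.append(chroms[j])
            g_start.append(max(1, int(pos[j]) + int(rng.integers(-150_000,
                                                                 150_000))))
        else:
            g_chrom.append(f"chr{int(rng.integers(1, 23))}")
            g_start.append(int(rng.integers(1, 40_000_000)))
    g_start = np.array(g_start)
    g_len = rng.integers(5_000, 200_000, size=n_genes)
    genes = pd.DataFrame({
        "gene_id": [f"GENE{g:05d}" for g in range(n_genes)],
        "chrom": g_chrom, "start": g_start, "end": g_start + g_len,
    })

    from .eqtm import pair_cpgs_genes
    ann = pd.DataFrame({
        "cpg_id": cpg_ids, "chrom": chroms, "pos": pos,
        "on_sex_chrom": on_sex, "blacklisted": blacklisted,
        "variant_or_ambiguous": variant,
        f"state_{epigenome_id}": states,
    })
    pairs = pair_cpgs_genes(ann, genes, window=window)
    nearest = pairs.loc[pairs["is_nearest_gene"]].set_index("cpg_id")["gene_id"]
    win = pairs.groupby("cpg_id")["gene_id"].apply(lambda g: ",".join(sorted(g)))
    ann["nearest_gene"] = ann["cpg_id"].map(nearest).fillna("")
    ann["genes_within_window"] = ann["cpg_id"].map(win).fillna("")

    catalogue = _trait_catalogue(rng, n_traits, cpg_ids, target_cpgs)
    state_bed = _segmentation_from_states(ann, f"state_{epigenome_id}")
    ann = ann[["cpg_id", "chrom", "pos", "on_sex_chrom", "blacklisted",
               "variant_or_ambiguous", "nearest_gene", "genes_within_window",
               f"state_{epigenome_id}"]]
    return ann, genes, catalogue, state_bed


def _trait_catalogue(rng, n_traits, cpg_ids, target_cpgs):
    """Trait-association rows exercising every catalogue filter."""
    rows = []
    for t in range(n_traits):
        n_member = int(rng.integers(100, max(101, len(cpg_ids) // 10)))
        members = rng.choice(cpg_ids, size=min(n_member, len(cpg_ids)),
                             replace=False)
        rows.append({
            "trait": f"trait_{t:03d}",
            "pubmed_id": str(30000000 + t) if rng.random() > 0.1 else "",
            "n": int(rng.integers(200, 20_000)),
            "n_cpgs_reported": int(rng.integers(50, 5_000)),
            "has_pval": bool(rng.random() > 0.1),
            "age_group": "adult" if rng.random() > 0.15 else "child",
            "tissue": str(rng.choice(
                ["whole blood", "leukocytes", "saliva", "adipose"],
                p=[0.6, 0.15, 0.15, 0.1])),
            "cpgs": ",".join(sorted(members)),
        })
    if target_cpgs:
        # planted trait: half the target set plus 1% background
        extra = rng.choice(cpg_ids, size=max(1, len(cpg_ids) // 100), replace=False)
        members = sorted(set(list(target_cpgs)[: len(target_cpgs) // 2]) | set(extra))
        rows.append({
            "trait": "planted_trait", "pubmed_id": "31000000", "n": 5000,
            "n_cpgs_reported": 500, "has_pval": True, "age_group": "adult",
            "tissue": "whole blood", "cpgs": ",".join(members),
        })
    return pd.DataFrame(rows)


def _segmentation_from_states(ann: pd.DataFrame, state_col: str) -> pd.DataFrame:
    """Tile each chromosome into half-open intervals consistent with the
    per-CpG state labels (boundaries at midpoints between adjacent CpGs)."""
    rows = []
    for chrom, sub in ann.sort_values("pos").groupby("chrom"):
        pos = sub["pos"].to_numpy()
        states = sub[state_col].to_numpy()
        mids = (pos[:-1] + pos[1:]) // 2
        starts = np.concatenate([[max(0, pos[0] - 100)], mids])
        ends = np.concatenate([mids, [pos[-1] + 100]])
        keep = starts < ends
        for s, e, st in zip(starts[keep], ends[keep], states[keep]):
            rows.append((chrom, int(s), int(e), st))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


# ---------------------------------------------------------------------------
# genetic scenarios (summary statistics for 2SMR and triangulation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticScenarioConfig:
    """Structural-model settings for one causal scenario.

    ``gamma`` is the causal effect of DNAm on the adipokine (forward),
    ``lam`` the effect of the adipokine on DNAm (reverse); instrument
    counts follow the published range of one to four independent
    cis-mQTLs per CpG, and adipokines carry their own small set of GWAS
    instruments with trans-mQTL data.
    """

    n_cpgs: int = 100
    frac_causal: float = 1.0
    gamma: float = 0.3
    lam: float = 0.3
    n_adipokine_instruments: int = 5
    n_mqtl: int = 25_000      # mQTL study size
    n_gwas: int = 100_000     # adipokine GWAS size
    n_ewas: int = 2791        # EWAS meta-analysis size
    sigma_cpg: float = 1.0    # phenotypic SD of (standardized) DNAm
    sigma_adipo: float = 1.0  # phenotypic SD of log adipokine
    confounder_sd: float = 0.2
    min_instruments: int = 1
    max_instruments: int = 4

    def __post_init__(self):
        if self.n_mqtl < 100 or self.n_gwas < 100 or self.n_ewas < 100:
            raise ValueError("sample sizes too small for stable standard errors")


_BASES = np.array(list("ACGT"))
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def _se(sigma: float, n: int, eaf: np.ndarray) -> np.ndarray:
    return sigma / np.sqrt(n * 2.0 * eaf * (1.0 - eaf))


def generate_genetic_scenario(scenario: str,
                              config: GeneticScenarioConfig | None = None,
                              seed: int = 0):
    """Generate cis-mQTL, adipokine GWAS, trans-mQTL, EWAS tables and truth
    under one of four structural models.

    forward:    SNP→CpG (β_mQTL), CpG→adipokine (γ); implied SNP→adipokine
                = β_mQTL·γ; adipokine instruments have null trans-mQTL effects.
    reverse:    SNP→adipokine (δ), adipokine→CpG (λ); implied trans-mQTL
                = δ·λ; cis-mQTLs have null adipokine-GWAS effects.
    confounded: cis SNPs affect the adipokine only through a latent
                pleiotropic path, not via the CpG.
    null:       no cross-trait effects at all.

    Returns ``(cis_mqtl, gwas, trans_mqtl, ewas, truth)``; the first three
    are summary-statistics tables, ``ewas`` has cpg_id/beta/se, ``truth``
    records per-CpG γ/λ and the scenario label.
    """
    if scenario not in ("forward", "reverse", "confounded", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    cfg = config or GeneticScenarioConfig()
    rng = _rng(seed, "genetic")
    m = cfg.n_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(m)]
    causal = np.zeros(m, dtype=bool)
    n_causal = int(round(cfg.frac_causal * m))
    if n_causal:
        causal[rng.choice(m, size=n_causal, replace=False)] = True
    # per-CpG causal effects: magnitudes spread around the configured level
    # with random signs, so cross-CpG triangulation has real variation
    signs = rng.choice([-1.0, 1.0], size=m)
    spread = rng.uniform(0.5, 1.5, size=m)
    gamma = np.where(causal & (scenario == "forward"),
                     signs * spread * cfg.gamma, 0.0)
    lam = np.where(causal & (scenario == "reverse"),
                   signs * spread * cfg.lam, 0.0)

    # --- cis-mQTL instruments, 1..4 per CpG -------------------------------
    n_inst = rng.integers(cfg.min_instruments, cfg.max_instruments + 1, size=m)
    rows_cis, rows_gwas_cis = [], []
    snp_counter = 0
    for j in range(m):
        for _ in range(n_inst[j]):
            vid = f"rs{snp_counter:07d}"
            snp_counter += 1
            ea, oa = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
            eaf = float(rng.uniform(0.05, 0.95))
            chrom = f"chr{1 + j % 22}"
            posn = int(1_000_000 + 1000 * snp_counter)
            b_mqtl = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.8))
            se_m = float(_se(cfg.sigma_cpg, cfg.n_mqtl, np.array(eaf)))
            b_hat = b_mqtl + rng.normal(0.0, se_m)
            rows_cis.append((vid, chrom, posn, ea, oa, eaf, b_hat, se_m,
                             _p(b_hat, se_m), cfg.n_mqtl, cpg_ids[j]))
            if scenario == "confounded":
                pleio = float(rng.normal(0.0, cfg.confounder_sd))
                true_gwas = pleio
            else:
                true_gwas = b_mqtl * gamma[j]
            se_g = float(_se(cfg.sigma_adipo, cfg.n_gwas, np.array(eaf)))
            g_hat = true_gwas + rng.normal(0.0, se_g)
            rows_gwas_cis.append((vid, chrom, posn, ea, oa, eaf, g_hat, se_g,
                                  _p(g_hat, se_g), cfg.n_gwas, "adipokine"))

    # --- adipokine GWAS instruments with trans-mQTL data ------------------
    rows_gwas_inst, rows_trans = [], []
    for k in range(cfg.n_adipokine_instruments):
        vid = f"rs9{k:06d}"
        ea, oa = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        eaf = float(rng.uniform(0.1, 0.9))
        chrom = f"chr{1 + k % 22}"
        posn = int(900_000_000 + 1000 * k)  # far from the cis regions
        # instruments reported for the adipokine-increasing allele
        delta = float(rng.uniform(0.05, 0.15))
        se_g = float(_se(cfg.sigma_adipo, cfg.n_gwas, np.array(eaf)))
        d_hat = delta + rng.normal(0.0, se_g)
        rows_gwas_inst.append((vid, chrom, posn, ea, oa, eaf, d_hat, se_g,
                               _p(d_hat, se_g), cfg.n_gwas, "adipokine"))
        se_t = _se(cfg.sigma_cpg, cfg.n_mqtl, np.full(m, eaf))
        true_trans = delta * lam
        t_hat = true_trans + rng.normal(0.0, se_t)
        for j in range(m):
            rows_trans.append((vid, f"chr{1 + k % 22}", posn, ea, oa, eaf,
                               float(t_hat[j]), float(se_t[j]),
                               _p(t_hat[j], se_t[j]), cfg.n_mqtl, cpg_ids[j]))

    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n", "trait_id"]
    cis_mqtl = pd.DataFrame(rows_cis, columns=cols)
    gwas = pd.DataFrame(rows_gwas_cis + rows_gwas_inst, columns=cols)
    trans_mqtl = pd.DataFrame(rows_trans, columns=cols)

    # --- EWAS table (DNAm-on-adipokine regression slopes) -----------------
    # forward: the EWAS slope is proportional to γ; reverse: equals λ.
    ewas_true = np.where(gamma != 0.0, gamma, lam)
    se_e = np.full(m, cfg.sigma_cpg / (cfg.sigma_adipo * np.sqrt(cfg.n_ewas)))
    ewas = pd.DataFrame({
        "cpg_id": cpg_ids,
        "beta": ewas_true + rng.normal(0.0, se_e),
        "se": se_e,
    })

    truth = TruthTable(effects=pd.DataFrame({
        "cpg_id": cpg_ids, "true_beta": np.where(causal, ewas_true, 0.0),
        "mediated_by_bmi": False, "smoking_confounded": False,
        "gamma": gamma, "lam": lam, "causal": causal,
    }), scenario=scenario)
    return cis_mqtl, gwas, trans_mqtl, ewas, truth


def _p(beta, se):
    from scipy import stats
    return float(2.0 * stats.norm.sf(abs(beta) / se))


# ---------------------------------------------------------------------------
# expression counts for the eQTM stage
# ---------------------------------------------------------------------------

def generate_expression(n_samples: int, n_genes: int,
                        planted_pairs: pd.DataFrame | None = None,
                        seed: int = 0,
                        effect_scale: float = 2.0,
                        frac_negative: float = 0.7,
                        dispersion: float = 0.1):
    """Negative-binomial counts whose log2 mean depends linearly on paired
    CpG methylation.

    ``planted_pairs`` columns: cpg_id, gene_id and optionally ``effect``
    (log2 expression per unit β).  When effects are not given they are
    drawn with magnitude ``effect_scale`` and a ``frac_negative`` share of
    negative signs, mirroring the predominance of inverse CpG–expression
    relationships in blood.  Returns ``(counts, covariates, methylation,
    truth)``.
    """
    if n_samples <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    rng = _rng(seed, "expression")
    gene_ids = [f"GENE{g:05d}" for g in range(n_genes)]
    if planted_pairs is None:
        planted_pairs = pd.DataFrame(columns=["cpg_id", "gene_id"])
    planted_pairs = planted_pairs.copy()
    if "effect" not in planted_pairs.columns:
        k = len(planted_pairs)
        signs = np.where(rng.random(k) < frac_negative, -1.0, 1.0)
        planted_pairs["effect"] = signs * effect_scale

    cpgs = list(dict.fromkeys(planted_pairs["cpg_id"])) or ["cg00000000"]
    meth = pd.DataFrame(
        np.clip(rng.uniform(0.2, 0.8, size=len(cpgs))[None, :]
                + rng.normal(0.0, 0.15, size=(n_samples, len(cpgs))), 0, 1),
        columns=cpgs)

    age = np.clip(rng.normal(55, 10, n_samples), 20, 90)
    sex = (rng.random(n_samples) < 0.55).astype(float)
    tech = rng.standard_normal((n_samples, 3))
    cells = rng.dirichlet(CELL_CONCENTRATION * np.array(list(CELL_MEANS.values())),
                          size=n_samples)
    covariates = pd.DataFrame({"age": age, "sex_female": sex,
                               "row": tech[:, 0], "plate": tech[:, 1],
                               "flowcell": tech[:, 2]})
    for i, c in enumerate(CELL_MEANS):
        if c != "Neu":
            covariates[c] = cells[:, i]

    log2_mu = np.tile(rng.uniform(3.0, 9.0, size=n_genes), (n_samples, 1))
    for _, row in planted_pairs.iterrows():
        g = gene_ids.index(row["gene_id"])
        x = meth[row["cpg_id"]].to_numpy()
        log2_mu[:, g] = log2_mu[:, g] + row["effect"] * (x - x.mean())
    mu = 2.0 ** log2_mu
    # NB via gamma-Poisson: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam_nb = rng.gamma(shape, mu / shape)
    counts = pd.DataFrame(rng.poisson(lam_nb), columns=gene_ids)
    sample_ids = [f"s{i:05d}" for i in range(n_samples)]
    for df in (counts, covariates, meth):
        df.index = pd.Index(sample_ids, name="sample_id")

    truth = TruthTable(effects=planted_pairs.rename(
        columns={"effect": "true_beta"}).assign(
            mediated_by_bmi=False, smoking_confounded=False))
    return counts, covariates, meth, truth
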