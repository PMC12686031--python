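"""cis-eQTM analysis: linking CpG methylation to nearby gene expression.

Counts are normalized to log2 counts-per-million (with 0.5/1.0
pseudo-counts for finiteness at zero), lowly expressed and non-autosomal
genes are dropped, each kept gene is rank-inverse-normal (Blom)
transformed, and per CpG–gene pair an OLS of transformed expression on
methylation β (with age, sex, technical and 12-cell-type covariates) is
fitted; BH-FDR runs across all tested pairs.  Pairing uses a ±100 kb
window from the CpG to the nearest gene boundary (distance 0 inside the
gene body).  A plain Pearson correlation is provided for small adipocyte-
style fixtures where no covariate model applies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inflation import bh_adjust

__all__ = ["log2_cpm", "rin", "pair_cpgs_genes", "fit_eqtm",
           "simple_correlation"]

AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


def log2_cpm(counts: pd.DataFrame, gene_models: pd.DataFrame | None = None,
             min_cpm: float = 1.0, min_fraction: float = 0.5):
    """log2 counts-per-million with expression and autosome filtering.

    ``log2((count + 0.5) / (library_size + 1) * 1e6)`` per sample/gene.
    Genes kept when CPM >= ``min_cpm`` in at least ``min_fraction`` of
    samples and (when ``gene_models`` given) located on an autosome.
    Returns ``(matrix, kept_genes)``.
    """
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    raw = counts.to_numpy(dtype=float)
    cpm = raw / lib[:, None] * 1e6
    keep = (cpm >= min_cpm).mean(axis=0) >= min_fraction
    if gene_models is not None:
        chrom = gene_models.set_index("gene_id")["chrom"]
        autosomal = counts.columns.map(
            lambda g: chrom.get(g, "chr?") in AUTOSOMES)
        keep = keep & np.asarray(autosomal, dtype=bool)
    kept_genes = list(counts.columns[keep])
    transformed = np.log2((raw[:, keep] + 0.5) / (lib[:, None] + 1.0) * 1e6)
    return pd.DataFrame(transformed, index=counts.index, columns=kept_genes), kept_genes


def rin(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom (3/8) offset.

    ``Φ⁻¹((rank − 3/8)/(n + 1/4))`` using average ranks for ties;
    strictly monotone in the input.  Raises on constant vectors.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("RIN transform needs >= 3 values")
    if np.ptp(v) == 0:
        raise ValueError("RIN transform undefined for a constant vector")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (v.size + 0.25))


def pair_cpgs_genes(annotation: pd.DataFrame, genes: pd.DataFrame,
                    window: int = 100_000) -> pd.DataFrame:
    """All CpG–gene pairs within ``window`` bp, plus nearest-gene flags.

    Distance is from the CpG position to the nearer gene boundary, 0 when
    the CpG falls inside the gene body (strand ignored).  The nearest
    gene per CpG breaks ties by smaller start, then lexicographic id.
    """
    rows = []
    genes_by_chrom = dict(tuple(genes.groupby("chrom")))
    for _, cpg in annotation.iterrows():
        sub = genes_by_chrom.get(cpg["chrom"])
        if sub is None:
            continue
        pos = int(cpg["pos"])
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        dist = np.where(pos < start, start - pos,
                        np.where(pos > end, pos - end, 0))
        hit = dist <= window
        for gid, d, s in zip(sub.loc[hit, "gene_id"], dist[hit], start[hit]):
            rows.append({"cpg_id": cpg["cpg_id"], "gene_id": gid,
                         "distance": int(d), "gene_start": int(s)})
    pairs = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "distance",
                                        "gene_start"])
    if pairs.empty:
        pairs["is_nearest_gene"] = pd.Series(dtype=bool)
        return pairs
    pairs = pairs.sort_values(
        ["cpg_id", "distance", "gene_start", "gene_id"]).reset_index(drop=True)
    pairs["is_nearest_gene"] = ~pairs.duplicated("cpg_id")
    return pairs.drop(columns="gene_start")


def fit_eqtm(pairs: pd.DataFrame, expression: pd.DataFrame,
             methylation: pd.DataFrame, covariates: pd.DataFrame,
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair OLS of (RIN log2CPM) expression on methylation β.

    Expression, methylation and covariates are aligned on their shared
    samples.  The covariates are projected out of both sides once
    (Frisch–Waugh–Lovell), so each pair reduces to a simple regression
    with the degrees of freedom of the full model; this is numerically
    identical to refitting the full design per pair.
    """
    samples = expression.index.intersection(methylation.index)
    samples = samples.intersection(covariates.index)
    C = covariates.loc[samples].to_numpy(dtype=float)
    if len(samples) < C.shape[1] + 3:
        raise ValueError(
            f"only {len(samples)} overlapping samples for {C.shape[1]} covariates")
    X = np.column_stack([np.ones(len(samples)), C])
    # hat-matrix projection via QR
    q, _ = np.linalg.qr(X)

    def residualize(M):
        return M - q @ (q.T @ M)

    E = residualize(expression.loc[samples].to_numpy(dtype=float))
    M = residualize(methylation.loc[samples].to_numpy(dtype=float))
    e_idx = {g: k for k, g in enumerate(expression.columns)}
    m_idx = {c: k for k, c in enumerate(methylation.columns)}

    df_resid = len(samples) - X.shape[1] - 1  # full model: covariates + β term
    rows = []
    for _, pr in pairs.iterrows():
        g, c = pr["gene_id"], pr["cpg_id"]
        if g not in e_idx or c not in m_idx:
            continue
        y = E[:, e_idx[g]]
        x = M[:, m_idx[c]]
        sxx = float(x @ x)
        if sxx <= 0:
            continue
        beta = float(x @ y) / sxx
        rss = float(y @ y) - beta * float(x @ y)
        se = np.sqrt(max(rss, 0.0) / df_resid / sxx)
        if se == 0:
            continue
        p = float(2.0 * stats.t.sf(abs(beta / se), df_resid))
        rows.append({"cpg_id": c, "gene_id": g, "beta": beta, "se": se,
                     "pval": p,
                     "is_nearest_gene": bool(pr.get("is_nearest_gene", False))})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable CpG-gene pairs (no overlapping data)")
    out["qval"] = bh_adjust(out["pval"].to_numpy())
    out["significant"] = out["qval"] <= alpha
    return out


def simple_correlation(x, y):
    """Pearson r with a two-sided t-based p-value (>= 3 paired values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
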