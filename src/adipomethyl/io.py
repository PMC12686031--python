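"""Readers/writers for the delimited tables the pipeline exchanges.

Conventions
-----------
* All delimited files are tab-separated with a header row; missing values
  are written as the literal ``NA``.
* BED files (chromatin-state segmentations) are 0-based half-open on disk;
  every in-memory position — summary-statistic ``pos``, probe ``pos``, gene
  ``start``/``end`` — is 1-based (inclusive for gene intervals).  The
  conversion happens exactly once, at parse time.
* Readers validate and reject; they never silently coerce a bad row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

SUMMARY_STATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "trait_id",
]

PROBE_ANNOTATION_COLUMNS = [
    "cpg_id",
    "chrom",
    "pos",
    "on_sex_chrom",
    "blacklisted",
    "variant_or_ambiguous",
    "nearest_gene",
    "genes_within_window",
]

#: Roadmap 15-state chromHMM vocabulary.
CHROMATIN_STATES = [
    "1_TssA",
    "2_TssAFlnk",
    "3_TxFlnk",
    "4_Tx",
    "5_TxWk",
    "6_EnhG",
    "7_Enh",
    "8_ZNF/Rpts",
    "9_Het",
    "10_TssBiv",
    "11_BivFlnk",
    "12_EnhBiv",
    "13_ReprPC",
    "14_ReprPCWk",
    "15_Quies",
]


class SchemaError(ValueError):
    """A required column is absent or mistyped."""


class ValidationError(ValueError):
    """A row violates a field invariant; the message carries the line number."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# summary statistics (SNP-trait GWAS rows and SNP-CpG mQTL rows)
# ---------------------------------------------------------------------------

def read_summary_stats(path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table.

    Returns a DataFrame with :data:`SUMMARY_STATS_COLUMNS`, row order
    preserved.  Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (with the offending 1-based data line) for
    invalid alleles, non-positive SEs, out-of-range EAF/p-values or
    duplicated (variant_id, trait_id) keys.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"variant_id": str, "chrom": str, "trait_id": str,
                            "effect_allele": str, "other_allele": str})
    _require_columns(df, SUMMARY_STATS_COLUMNS, path)
    df = df[SUMMARY_STATS_COLUMNS].copy()
    validate_summary_stats(df, path=path)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return df.reset_index(drop=True)


def validate_summary_stats(df: pd.DataFrame, path="<memory>") -> None:
    """Check every SummaryStats invariant; raise on first violating row."""

    def bad(mask, why):
        if mask.to_numpy().any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValidationError(f"{path}: line {line}: {why}")

    bad(~df["effect_allele"].isin(VALID_ALLELES), "effect_allele not one of A/C/G/T")
    bad(~df["other_allele"].isin(VALID_ALLELES), "other_allele not one of A/C/G/T")
    bad(df["effect_allele"] == df["other_allele"], "effect_allele equals other_allele")
    bad(~(df["se"] > 0), "se must be > 0")
    bad((df["pval"] < 0) | (df["pval"] > 1) | df["pval"].isna(), "pval outside [0,1]")
    bad((df["eaf"] < 0) | (df["eaf"] > 1) | df["eaf"].isna(), "eaf outside [0,1]")
    bad(~(df["n"] > 0), "n must be a positive integer")
    bad(~(df["pos"] >= 1), "pos must be >= 1")
    dup = df.duplicated(subset=["variant_id", "trait_id"], keep="first")
    bad(dup, "duplicate (variant_id, trait_id)")


def write_summary_stats(records: pd.DataFrame, path) -> None:
    """Write a validated summary-statistics table as TSV (NA for missing)."""
    _require_columns(records, SUMMARY_STATS_COLUMNS, path)
    validate_summary_stats(records, path=path)
    records[SUMMARY_STATS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# methylation beta matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> pd.DataFrame:
    """Read a samples x CpGs matrix of methylation β values.

    First column holds sample ids, header row holds CpG ids.  Every
    non-missing entry must lie in [0,1]; a violation raises
    :class:`ValidationError` naming the (sample, CpG) coordinate.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | ((values >= 0.0) & (values <= 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: beta value {values[i, j]!r} outside [0,1] at "
            f"(sample={df.index[i]!r}, cpg={df.columns[j]!r})")
    df.index.name = "sample_id"
    return df.astype(float)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    values = beta.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | ((values >= 0.0) & (values <= 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: beta value outside [0,1] at "
            f"(sample={beta.index[i]!r}, cpg={beta.columns[j]!r})")
    out = beta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene-set libraries
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT library into {set_name: member gene list}.

    Duplicate members within a set are dropped (first occurrence kept);
    duplicate set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} fields, "
                    "need name, description and at least one member")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# BED chromatin-state segmentations
# ---------------------------------------------------------------------------

def read_state_bed(path) -> pd.DataFrame:
    """Read a 4-column BED of chromatin states (0-based half-open on disk).

    Returns columns chrom/start/end/state with the on-disk half-open
    convention preserved in start/end; use :func:`state_at` for 1-based
    point queries.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "state"],
                     dtype={"chrom": str, "state": str})
    if df[["start", "end"]].isna().any().any():
        raise ValidationError(f"{path}: non-numeric BED coordinates")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"{path}: line {lineno}: require 0 <= start < end")
    return df


def write_state_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", index=False, header=False)


def state_at(intervals: pd.DataFrame, chrom: str, pos: int) -> str | None:
    """State covering position ``pos``, or None if uncovered.

    The half-open rule is applied directly: a point hits [start, end)
    iff start <= pos < end, so the boundary position ``end`` misses.
    """
    sub = intervals[(intervals["chrom"] == chrom)
                    & (intervals["start"] <= pos)
                    & (pos < intervals["end"])]
    if sub.empty:
        return None
    return str(sub.iloc[0]["state"])


# ---------------------------------------------------------------------------
# probe annotation and gene models
# ---------------------------------------------------------------------------

def read_probe_annotation(path) -> pd.DataFrame:
    """Read a probe-annotation TSV.

    Required columns are :data:`PROBE_ANNOTATION_COLUMNS`; any column named
    ``state_<epigenome>`` carries that epigenome's 15-state label per CpG.
    ``genes_within_window`` is a comma-joined gene-id list (empty allowed).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype=str)
    _require_columns(df, PROBE_ANNOTATION_COLUMNS, path)
    df["pos"] = df["pos"].astype(np.int64)
    for flag in ("on_sex_chrom", "blacklisted", "variant_or_ambiguous"):
        df[flag] = df[flag].astype(int).astype(bool)
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: probe pos must be >= 1")
    if df["cpg_id"].duplicated().any():
        dup = df.loc[df["cpg_id"].duplicated(), "cpg_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate cpg_id {dup!r}")
    state_cols = [c for c in df.columns if c.startswith("state_")]
    for col in state_cols:
        bad = ~df[col].isin(CHROMATIN_STATES)
        if bad.any():
            raise ValidationError(
                f"{path}: column {col}: unknown chromatin state "
                f"{df.loc[bad, col].iloc[0]!r}")
    return df.reset_index(drop=True)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    for flag in ("on_sex_chrom", "blacklisted", "variant_or_ambiguous"):
        out[flag] = out[flag].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_models(path) -> pd.DataFrame:
    """Read a gene-model table (gene_id, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    _require_columns(df, ["gene_id", "chrom", "start", "end"], path)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"{path}: line {lineno}: gene start > end")
    return df


def write_gene_models(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Generic TSV reader used for covariate/phenotype/result tables."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
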