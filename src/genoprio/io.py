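"""Readers and writers for every on-disk format the pipeline touches.

All internal coordinates are 1-based inclusive. The only 0-based surface is
BED on disk (0-based half-open), converted on read/write. p-values are stored
as floats with an underflow clamp at 1e-300: real summary statistics contain
p-values below the double-denormal threshold that print as 0, which would
otherwise violate the p in (0, 1] invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_UNDERFLOW = 1e-300

#: canonical GWAS summary-statistic columns (internal dialect)
GWAS_COLUMNS = ["rsid", "chrom", "pos", "ea", "oa", "beta", "se", "pvalue", "n"]
EQTL_COLUMNS = ["rsid", "gene_id", "pvalue", "beta", "dataset_label"]


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad row)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene span; start/end are 1-based inclusive basepair coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end}]"
            )


@dataclass
class GenotypePanel:
    """Reference genotype panel: dosage matrix (samples x SNPs) in [0, 2]."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # shape (n_samples, n_snps)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match sample/SNP ids")
        if np.isnan(self.dosages).any():
            raise ValueError("panel contains missing dosages")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a group label per sample."""

    values: pd.DataFrame  # rows = genes, columns = samples
    groups: pd.Series  # index = sample ids, values = group labels

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def group_samples(self, group: str) -> list[str]:
        samples = self.groups.index[self.groups == group]
        return [s for s in self.values.columns if s in set(samples)]

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def _clamp_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.where((p > 0) & (p < P_UNDERFLOW), P_UNDERFLOW, p)


def read_gwas_tsv(path, col_map: dict | None = None, strict: bool = True,
                  check_consistency: bool = True) -> pd.DataFrame:
    """Read a GWAS summary TSV into the internal dialect.

    Parameters
    ----------
    col_map
        Optional mapping from on-disk column names to the canonical names
        (``rsid/chrom/pos/ea/oa/beta/se/pvalue/n``) for foreign dialects.
    strict
        If True (default) any row violating an invariant raises a
        :class:`FormatError` naming the 1-based data line; if False bad rows
        are dropped with a warning.
    check_consistency
        When beta, se and pvalue are all present, flag rows where the
        two-sided normal p of beta/se disagrees with the stated p by more
        than 10% relative (column ``inconsistent``); flagged, never rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    if col_map:
        df = df.rename(columns=col_map)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"GWAS TSV missing mandatory column(s): {missing}")
    df = df[GWAS_COLUMNS].copy()
    if len(df) == 0:
        df["inconsistent"] = pd.Series(dtype=bool)
        return df
    df["pvalue"] = _clamp_p(pd.to_numeric(df["pvalue"], errors="coerce"))
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["se"] = pd.to_numeric(df["se"], errors="coerce")

    problems = []
    bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    for i in df.index[bad.fillna(True)]:
        problems.append((i, "pvalue out of (0,1]"))
    bad_pos = df["pos"].isna() | (df["pos"] < 1)
    for i in df.index[bad_pos]:
        problems.append((i, "pos must be >= 1"))
    bad_se = df["se"].isna() | (df["se"] <= 0)
    for i in df.index[bad_se]:
        problems.append((i, "se must be > 0"))
    if problems:
        msgs = "; ".join(f"line {i + 2}: {m}" for i, m in sorted(problems))
        if strict:
            raise FormatError(f"invalid GWAS rows: {msgs}")
        warnings.warn(f"dropping invalid GWAS rows: {msgs}")
        df = df.drop(index=sorted({i for i, _ in problems}))

    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)
    df["inconsistent"] = False
    if check_consistency and len(df):
        z = (df["beta"] / df["se"]).abs()
        implied = 2 * stats.norm.sf(z)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(implied - df["pvalue"]) / df["pvalue"]
        flag = (rel > 0.10) & np.isfinite(rel)
        if flag.any():
            warnings.warn(
                f"{int(flag.sum())} GWAS rows have beta/se inconsistent with "
                "the stated p-value (>10% relative); flagged, not removed"
            )
        df["inconsistent"] = flag.to_numpy()
    return df.reset_index(drop=True)


def write_gwas_tsv(df: pd.DataFrame, path) -> None:
    out = df[GWAS_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eQTL association tables
# ---------------------------------------------------------------------------

def read_eqtl_tsv(path, strict: bool = True) -> pd.DataFrame:
    """Read an eQTL association TSV (rsid, gene_id, pvalue, beta, dataset_label)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene_id": str,
                                            "dataset_label": str})
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"eQTL TSV missing mandatory column(s): {missing}")
    keep = EQTL_COLUMNS + (["cis_trans"] if "cis_trans" in df.columns else [])
    df = df[keep].copy()
    if len(df) == 0:
        return df
    df["pvalue"] = _clamp_p(pd.to_numeric(df["pvalue"], errors="coerce"))
    bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    bad |= df["dataset_label"].isna() | (df["dataset_label"] == "")
    if bad.any():
        msgs = "; ".join(f"line {i + 2}" for i in df.index[bad])
        if strict:
            raise FormatError(f"invalid eQTL rows (pvalue/dataset_label): {msgs}")
        warnings.warn(f"dropping invalid eQTL rows: {msgs}")
        df = df[~bad]
    return df.reset_index(drop=True)


def write_eqtl_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def classify_cis_trans(eqtl: pd.DataFrame, snp_map: pd.DataFrame,
                       genes: list[GeneModel],
                       window_bp: int = 1_000_000) -> pd.DataFrame:
    """Label each SNP-gene pair cis or trans by distance.

    A pair is *cis* when the SNP lies on the gene's chromosome within the
    gene span extended by ``window_bp`` on each side (the conventional 1 Mb
    bound), else *trans*. ``snp_map`` must have columns rsid/chrom/pos.
    """
    gmap = {g.gene_id: g for g in genes}
    smap = snp_map.set_index("rsid")
    out = eqtl.copy()
    labels = []
    for rsid, gene_id in zip(out["rsid"], out["gene_id"]):
        g = gmap.get(gene_id)
        if g is None or rsid not in smap.index:
            labels.append("trans")
            continue
        chrom, pos = smap.at[rsid, "chrom"], smap.at[rsid, "pos"]
        cis = (str(chrom) == g.chrom
               and g.start - window_bp <= int(pos) <= g.end + window_bp)
        labels.append("cis" if cis else "trans")
    out["cis_trans"] = labels
    return out


# ---------------------------------------------------------------------------
# Gene models (BED)
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> list[GeneModel]:
    """Read BED3+name gene models; 0-based half-open on disk -> 1-based inclusive."""
    models: list[GeneModel] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"BED line {lineno}: expected >= 4 fields")
            chrom, s, e, gene_id = fields[0], fields[1], fields[2], fields[3]
            bed_start, bed_end = int(s), int(e)
            if bed_start >= bed_end:
                raise FormatError(
                    f"BED line {lineno}: start {bed_start} >= end {bed_end}"
                )
            if gene_id in seen:
                raise FormatError(
                    f"duplicate gene_id {gene_id!r} (lines {seen[gene_id]}, {lineno})"
                )
            seen[gene_id] = lineno
            models.append(GeneModel(gene_id, chrom, bed_start + 1, bed_end))
    return models


def write_gene_bed(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in models:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into an ordered term_id -> (description, members) map.

    Duplicate members within one term are collapsed, keeping first occurrence
    order; a line with fewer than 3 fields is a format error.
    """
    collection: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields"
                )
            term, desc = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"GMT line {lineno}: term {term!r} has no members")
            collection[term] = (desc, members)
    return collection


def write_gmt(collection: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Genotype dosage panel
# ---------------------------------------------------------------------------

def read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypePanel(sample_ids=[str(s) for s in df.index],
                         snp_ids=[str(c) for c in df.columns],
                         dosages=df.to_numpy(dtype=float))


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids,
                      columns=panel.snp_ids)
    df.index.name = "sample_id"
    # dosages are small integers after thresholding; keep text compact
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(expr_csv, meta_tsv) -> ExpressionMatrix:
    values = pd.read_csv(expr_csv, index_col=0)
    meta = pd.read_csv(meta_tsv, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(meta.columns):
        raise FormatError("sample metadata must have columns sample_id, group")
    groups = meta.set_index("sample_id")["group"]
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(matrix: ExpressionMatrix, expr_csv, meta_tsv) -> None:
    matrix.values.to_csv(expr_csv)
    meta = pd.DataFrame({"sample_id": matrix.groups.index,
                         "group": matrix.groups.values})
    meta.to_csv(meta_tsv, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
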