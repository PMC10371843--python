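"""Differential expression calling and gene-anchored region derivation.

Tumor-vs-normal differential expression is called per gene with a Welch
two-sample t-test (or a two-sample Kolmogorov-Smirnov test).  Promoter and
association windows around the TSS/TES are derived strand-aware: an oriented
window "-U / +D" around a base t covers [t - U, t + D + 1) on the plus strand
and the coordinate reflection [t - D - 1, t + U) on the minus strand, then is
clipped to the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCHEMES = ("promoter1k", "promoter10k", "assoc4")


@dataclass
class GeneRegions:
    """Strand-aware genomic windows anchored on one gene's TSS/TES."""

    gene: str
    chrom: str
    strand: str
    windows: dict[str, tuple[int, int]]  # category -> (start, end), 0-based half-open


def call_degs(
    matrix: pd.DataFrame,
    groups: pd.Series,
    method: str = "t",
    alpha: float = 0.05,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided tumor-vs-normal test.

    Returns a DataFrame indexed by gene with columns p_value and is_deg.
    Genes that are constant and equal across both groups get p = 1.
    """
    if method not in ("t", "ks"):
        raise ValueError(f"unknown method {method!r}; use 't' or 'ks'")
    tumor_cols = groups.index[groups == "tumor"]
    normal_cols = groups.index[groups == "normal"]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    X = matrix[tumor_cols].to_numpy(dtype=float)
    Y = matrix[normal_cols].to_numpy(dtype=float)
    if log2_transform:
        X = np.log2(X + 1)
        Y = np.log2(Y + 1)
    if method == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(X, Y, axis=1, equal_var=False)
    else:
        p = np.array([stats.ks_2samp(x, y).pvalue for x, y in zip(X, Y)])
    # degenerate genes: zero variance in both groups
    const = (X.std(axis=1) == 0) & (Y.std(axis=1) == 0)
    equal = const & (X.mean(axis=1) == Y.mean(axis=1))
    p = np.where(equal, 1.0, p)
    # constant but different: infinitely strong evidence under the t model
    p = np.where(const & ~equal, 0.0, p)
    out = pd.DataFrame({"p_value": p}, index=matrix.index)
    out["is_deg"] = out["p_value"] < alpha
    return out


def _oriented_window(
    tss_or_tes: int, strand: str, upstream: int, downstream: int
) -> tuple[int, int]:
    """Window covering ``upstream`` bp before and ``downstream`` bp after a
    base, measured along the direction of transcription."""
    t = tss_or_tes
    if strand == "-":
        return (t - downstream - 1, t + upstream)
    return (t - upstream, t + downstream + 1)


def derive_regions(
    annotation: pd.DataFrame,
    scheme: str = "promoter1k",
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, GeneRegions]:
    """Derive per-gene scan/association windows from a gene annotation table.

    Schemes:
      promoter1k  — TSS +/- 1000 bp (symmetric)
      promoter10k — TSS +/- 10000 bp (symmetric)
      assoc4      — gene body [TSS, TES], TSS window (-5000/+1000),
                    TES window (-1000/+5000), distal 5' (-1 Mb .. -5 kb),
                    all measured along the direction of transcription
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    out: dict[str, GeneRegions] = {}
    for gene, row in annotation.iterrows():
        chrom, strand = row["chrom"], row["strand"]
        tss, tes = int(row["tss"]), int(row["tes"])
        length = (chrom_lengths or {}).get(chrom)
        windows: dict[str, tuple[int, int]] = {}
        if scheme == "promoter1k":
            windows["promoter"] = (tss - 1000, tss + 1001)
        elif scheme == "promoter10k":
            windows["promoter"] = (tss - 10000, tss + 10001)
        else:
            wrong_way = (strand == "+" and tes < tss) or (strand == "-" and tes > tss)
            if wrong_way:
                logger.warning(
                    "gene %s: TES before TSS on strand %s; using oriented span",
                    gene, strand,
                )
            lo, hi = min(tss, tes), max(tss, tes)
            windows["gene_body"] = (lo, hi + 1)
            windows["TSS"] = _oriented_window(tss, strand, 5000, 1000)
            windows["TES"] = _oriented_window(tes, strand, 1000, 5000)
            windows["distal5p"] = _oriented_window(tss, strand, 1_000_000, -5000)
        clipped: dict[str, tuple[int, int]] = {}
        for cat, (s, e) in windows.items():
            s = max(0, s)
            if length is not None:
                e = min(e, length)
            if e > s:
                clipped[cat] = (s, e)
        out[gene] = GeneRegions(gene=gene, chrom=chrom, strand=strand, windows=clipped)
    return out


def filter_low_expression_tfs(
    tf_expression: dict[str, float], tf_names, threshold: float = 0.03
) -> list[str]:
    """Drop TFs whose expression (RPKM) is strictly below the threshold.

    TFs absent from the expression map are retained — unknown is not the same
    as unexpressed.
    """
    return [
        tf
        for tf in tf_names
        if tf not in tf_expression or not (tf_expression[tf] < threshold)
    ]


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index_label="gene")
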