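"""Baseline comparisons for the subnetwork signature: individually
differentially expressed gene markers, signature overlap, and proteomic
yield / rate-of-return analysis.

"Individual gene markers" are selected without any interaction structure:
genes passing a two-sided fold-change filter on raw-scale group means are
ranked by the magnitude of t = (mean_LTS - mean_STS) / pooled sd, where the
pooled sd is sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).  The proteomic
yield of a ranked gene set is how many of its top-n genes were identified
in a proteomics experiment and how many of those were differentially
expressed; the "rate of return" is the fitted least-squares slope of the DE
count against the gene-set size, reported as a percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LTS, STS, ExpressionMatrix, PhenotypeLabels

log = logging.getLogger(__name__)


def rank_individual_gene_markers(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    fc_threshold: float = 2.0,
    top_n: int = 200,
    fc_scale: str = "raw",
) -> pd.DataFrame:
    """Fold-change-filtered, |t|-ranked individual gene markers.

    The fold-change filter is two-sided on raw group means (ratio >=
    ``fc_threshold`` or <= 1/``fc_threshold``); ``fc_scale="log2"``
    instead requires |mean log2 difference| >= log2(fc_threshold), for
    matrices already on a log scale.  Genes with zero pooled sd are
    excluded with a warning.  Returns the top ``top_n`` rows sorted by |t|
    descending, with columns gene, mean_sts, mean_lts, fold_change,
    pooled_sd, t, rank.
    """
    if fc_scale not in ("raw", "log2"):
        raise ValueError(f"fc_scale must be raw or log2, got {fc_scale!r}")
    sts_cols = [s for s in labels.sts_samples if s in expr.values.columns]
    lts_cols = [s for s in labels.lts_samples if s in expr.values.columns]
    if not sts_cols or not lts_cols:
        raise ValueError("both phenotype classes must be present in the matrix")
    A = expr.values[sts_cols].to_numpy(dtype=float)
    B = expr.values[lts_cols].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    s1 = A.std(axis=1, ddof=1)
    s2 = B.std(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))

    if fc_scale == "raw":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = m2 / m1
        passes = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
        passes &= np.isfinite(fc) & (fc > 0)
    else:
        fc = m2 - m1  # log2 difference
        passes = np.abs(fc) >= np.log2(fc_threshold)

    zero_sd = pooled == 0
    if (zero_sd & passes).any():
        warnings.warn(f"excluding {int((zero_sd & passes).sum())} gene(s) with zero pooled sd")
    passes &= ~zero_sd

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / pooled
    df = pd.DataFrame(
        {
            "gene": expr.values.index,
            "mean_sts": m1,
            "mean_lts": m2,
            "fold_change": fc,
            "pooled_sd": pooled,
            "t": t,
        }
    )[passes]
    df = df.reindex(df["t"].abs().sort_values(ascending=False, kind="mergesort").index)
    df = df.head(top_n).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def signature_overlap(list_a, list_b) -> tuple[int, set[str]]:
    """Case-normalized intersection of two gene lists."""
    a = {str(g).upper() for g in list_a}
    b = {str(g).upper() for g in list_b}
    shared = a & b
    return len(shared), shared


@dataclass
class YieldCurve:
    """Proteomic yield of nested gene-set prefixes, with the fitted rate
    of return (slope of DE count vs prefix size, as a percentage)."""

    table: pd.DataFrame  # columns: size, n_identified, n_de
    slope: float
    intercept: float

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.slope


def proteomic_yield_analysis(
    ranked_genes,
    proteome: set,
    de_proteins: set,
    sizes=None,
    gene_to_protein: pd.Series | None = None,
) -> YieldCurve:
    """Per prefix size, count the ranked genes identified in the proteome
    and the subset differentially expressed; fit an ordinary least-squares
    line (fitted intercept) of DE count on prefix size.

    ``gene_to_protein`` optionally maps gene symbols to proteome
    identifiers (2-column table semantics); by default symbols are compared
    case-insensitively.
    """
    genes = [str(g) for g in ranked_genes]
    if gene_to_protein is not None:
        mapped = [gene_to_protein.get(g) for g in genes]
        if all(m is None for m in mapped):
            raise ValueError("gene-to-protein mapping matches no ranked gene")
        mapped = [m if m is not None else f"__unmapped_{g}" for g, m in zip(genes, mapped)]
    else:
        mapped = [g.upper() for g in genes]
        proteome = {str(p).upper() for p in proteome}
        de_proteins = {str(p).upper() for p in de_proteins}
    if sizes is None:
        sizes = list(range(10, len(genes) + 1, 10)) or [len(genes)]
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > len(genes):
        raise ValueError(f"prefix size {sizes[-1]} exceeds ranking length {len(genes)}")

    rows = []
    for n in sizes:
        prefix = mapped[:n]
        ident = [p for p in prefix if p in proteome]
        de = [p for p in ident if p in de_proteins]
        rows.append({"size": n, "n_identified": len(ident), "n_de": len(de)})
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["size"].nunique() > 1:
        fit = stats.linregress(table["size"], table["n_de"])
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = 0.0, float(table["n_de"].iloc[0])
    return YieldCurve(table=table, slope=slope, intercept=intercept)
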