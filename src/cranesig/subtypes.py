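"""Centroid-based molecular subtype assignment.

Samples are assigned to the predefined expression subtype (e.g. the four
GBM classes Proneural, Classical, Neural, Mesenchymal) whose centroid
profile they correlate with best, using the Spearman rank correlation over
the genes shared between sample and centroid panel.  Because Spearman
depends only on ranks, assignments are invariant to monotone per-sample
transforms of expression.

Test-set preprocessing follows the standard array recipe: log2 transform,
median-center each array, scale by the array's standard deviation, and
average probe-level rows into gene-level values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


def load_centroids(path) -> pd.DataFrame:
    """Centroid table: genes x subtypes TSV, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 subtype columns")
    return df.astype(float)


def preprocess_for_centroids(
    expr: ExpressionMatrix,
    probe_map: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Per-array normalization for centroid correlation.

    Each sample (array) is log2-transformed, centered on its median, and
    divided by its standard deviation (n-1 form).  Non-positive values are
    shifted by ``pseudocount - min`` before the log (the log transform
    requires positive input).  Constant samples are dropped with a warning.
    If ``probe_map`` (probe id -> gene symbol) is given, processed
    probe-level rows are averaged into gene-level rows.
    """
    v = expr.values.astype(float)
    if (v.to_numpy() <= 0).any():
        shift = pseudocount - float(v.to_numpy().min())
        log.info("shifting expression by %.4g before log transform", shift)
        v = v + shift
    logged = np.log2(v)
    sd = logged.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(logged.columns[constant])
        warnings.warn(f"dropping {len(dropped)} constant sample(s): {dropped[:5]}")
        logged = logged.loc[:, ~constant]
        sd = sd[~constant]
    centered = logged - logged.median(axis=0)
    scaled = centered / sd
    if probe_map is not None:
        scaled = scaled.groupby(probe_map.reindex(scaled.index)).mean()
        scaled.index.name = expr.values.index.name
    return ExpressionMatrix(scaled)


def assign_subtypes(
    expr: ExpressionMatrix,
    centroids: pd.DataFrame,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Assign each sample to the subtype with maximal Spearman correlation.

    Correlations use the genes shared between the sample's matrix and the
    centroid panel.  Ties in the argmax break to the first subtype in
    declared column order (warned).  Samples with fewer than
    ``min_overlap`` shared genes are left unassigned (NaN, warned).

    Returns a DataFrame indexed by sample with a ``subtype`` column and one
    ``rho_<subtype>`` column per centroid.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need >= 2 subtypes in centroid table")
    subtype_names = list(centroids.columns)
    shared = expr.values.index.intersection(centroids.index)
    rows = []
    if len(shared) < min_overlap:
        warnings.warn(
            f"only {len(shared)} genes shared with centroid panel; no sample assignable"
        )
        out = pd.DataFrame(
            {
                "subtype": pd.Series(np.nan, index=expr.sample_ids, dtype=object),
                **{f"rho_{s}": np.nan for s in subtype_names},
            }
        )
        out.index.name = "sample"
        return out

    sample_vals = expr.values.loc[shared]
    cent_vals = centroids.loc[shared]
    for sample in expr.sample_ids:
        x = sample_vals[sample].to_numpy()
        rhos = {}
        for st in subtype_names:
            rho = stats.spearmanr(x, cent_vals[st].to_numpy()).statistic
            rhos[st] = float(rho)
        vec = np.array([rhos[st] for st in subtype_names])
        best = float(np.nanmax(vec))
        winners = [st for st, r in zip(subtype_names, vec) if r == best]
        if len(winners) > 1:
            warnings.warn(
                f"sample {sample!r}: Spearman tie between {winners}; "
                f"assigning first in declared order"
            )
        rows.append(
            {"sample": sample, "subtype": winners[0], **{f"rho_{s}": rhos[s] for s in subtype_names}}
        )
    return pd.DataFrame(rows).set_index("sample")
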