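"""Peptide-level differential-expression pipeline for label-free
proteomics validation of a gene signature.

The data are peptide intensities over a small two-group cohort (the study
design is 10 short-term + 6 long-term survivors), with each peptide mapped
to exactly one protein and missing values allowed.  The pipeline is:

1. **Imputation** — a missing cell is replaced by the median intensity of
   that peptide among observed samples of the same survival group; peptides
   with no observation in a group are dropped.
2. **Standard normalization** — each peptide is z-scored (mean 0, sd 1)
   across all samples.  A direct consequence is the zero-sum law
   ``n_STS * m_STS + n_LTS * m_LTS = 0`` for every protein's group means on
   the normalized scale; with the 10/6 design the LTS mean is exactly -5/3
   of the STS mean.
3. **Mixed model** — per protein, intensity ~ group (fixed) + peptide
   (random intercept), fitted by maximum likelihood; the group effect is
   tested with a likelihood-ratio test against the no-group null
   (chi-square, 1 df).  Single-peptide proteins reduce to an ordinary
   two-group linear model, LRT-tested the same way.  ML (not REML) is used
   because the LRT compares fixed-effect structures.
4. **Reporting** — per protein: group means on the normalized scale, the
   LTS/STS ratio on the raw scale, the LRT p-value, and a significance flag
   at alpha with no multiplicity adjustment (deliberate: the protein sets
   are pre-specified, not discovered).

A small CART (Gini, depth <= 2) classifier over protein-level features
expresses compact protein panels such as a two-protein STS/LTS rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.tree import DecisionTreeClassifier

from .io import LTS, STS

log = logging.getLogger(__name__)


@dataclass
class PeptideTable:
    """Peptide intensities with peptide -> protein mapping and sample
    groups.

    ``intensities``: DataFrame peptides x samples (NaN = missing);
    ``protein_map``: Series peptide -> protein;
    ``groups``: Series sample -> {STS, LTS}.
    """

    intensities: pd.DataFrame
    protein_map: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise ValueError("duplicate peptide ids")
        unmapped = self.intensities.index.difference(self.protein_map.index)
        if len(unmapped):
            raise ValueError(f"peptides without protein mapping: {list(unmapped[:5])}")
        self.protein_map = self.protein_map.loc[self.intensities.index]
        missing_groups = self.intensities.columns.difference(self.groups.index)
        if len(missing_groups):
            raise ValueError(f"samples without group: {list(missing_groups[:5])}")
        self.groups = self.groups.loc[self.intensities.columns]
        bad = set(self.groups.unique()) - {STS, LTS}
        if bad:
            raise ValueError(f"groups must be STS/LTS, got {sorted(bad)}")
        for g in (STS, LTS):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"no samples in group {g}")

    @property
    def n_peptides(self) -> int:
        return len(self.intensities)

    @property
    def n_proteins(self) -> int:
        return self.protein_map.nunique()

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @classmethod
    def from_long(cls, df: pd.DataFrame, groups: pd.Series) -> "PeptideTable":
        """Build from a long table with columns peptide, protein, sample,
        intensity (absent combinations = missing)."""
        wide = df.pivot(index="peptide", columns="sample", values="intensity")
        pmap = df.drop_duplicates("peptide").set_index("peptide")["protein"]
        multi = df.groupby("peptide")["protein"].nunique()
        if (multi > 1).any():
            raise ValueError(
                f"peptides mapped to multiple proteins: {list(multi.index[multi > 1][:5])}"
            )
        return cls(wide, pmap, groups)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.intensities.reset_index(names="peptide")
            .melt(id_vars="peptide", var_name="sample", value_name="intensity")
            .dropna(subset=["intensity"])
        )
        long["protein"] = self.protein_map.loc[long["peptide"]].to_numpy()
        return long[["peptide", "protein", "sample", "intensity"]]


def impute_missing_by_group_median(table: PeptideTable) -> PeptideTable:
    """Replace each missing cell with the median of that peptide's observed
    intensities within the sample's survival group.  Peptides fully missing
    in either group cannot be imputed and are dropped (count logged)."""
    vals = table.intensities.copy()
    dropped = pd.Series(False, index=vals.index)
    for g in (STS, LTS):
        cols = table.samples_in(g)
        sub = vals[cols]
        med = sub.median(axis=1)
        dropped |= med.isna()
        vals[cols] = sub.T.fillna(med).T
    if dropped.any():
        log.info("dropped %d peptide(s) fully missing in a group", int(dropped.sum()))
    vals = vals.loc[~dropped]
    out = PeptideTable(vals, table.protein_map.loc[vals.index], table.groups)
    out.n_dropped_peptides = int(dropped.sum())
    return out


def standard_normalize_peptides(table: PeptideTable, ddof: int = 1) -> PeptideTable:
    """Z-score each peptide across all samples (mean 0, sd 1).  Requires a
    complete table (impute first).  Zero-variance peptides are dropped with
    a warning."""
    vals = table.intensities
    if vals.isna().any().any():
        raise ValueError("normalize after imputation: missing values present")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance peptide(s)")
        vals = vals.loc[~flat]
        mean, sd = mean[~flat], sd[~flat]
    normed = vals.sub(mean, axis=0).div(sd, axis=0)
    return PeptideTable(normed, table.protein_map.loc[normed.index], table.groups)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


@dataclass
class ProteinDEResult:
    """Per-protein differential-expression summary (one results-table row)."""

    protein_id: str
    n_peptides: int
    sts_mean: float  # normalized scale
    lts_mean: float  # normalized scale
    ratio_lts_sts: float  # raw scale
    effect: float  # group fixed effect (LTS - STS) on the modeled scale
    p_value: float
    significant: bool = False
    converged: bool = True


def _lrt_p(llf_full: float, llf_null: float) -> float:
    lr = max(2.0 * (llf_full - llf_null), 0.0)
    return float(chi2.sf(lr, df=1))


def fit_protein_mixed_model(
    peptide_values: pd.DataFrame, groups: pd.Series
) -> tuple[float, float, bool]:
    """Fit intensity ~ group + (1 | peptide) by ML for one protein and
    LRT-test the group effect.

    ``peptide_values``: peptides x samples (complete); ``groups``: sample
    -> {STS, LTS}.  Returns (effect LTS - STS, LRT p-value, converged).
    For a single peptide the random effect is dropped and the model is the
    ordinary two-group linear model (same LRT).  A boundary fit (peptide
    variance estimated at 0) is accepted as-is; the test concerns the fixed
    effect.
    """
    groups = groups.loc[peptide_values.columns]
    for g in (STS, LTS):
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g}")
    x = (groups == LTS).astype(float).to_numpy()
    n_pep, n_samp = peptide_values.shape
    y = peptide_values.to_numpy(dtype=float).ravel()
    xs = np.tile(x, n_pep)
    X_full = sm.add_constant(xs)
    X_null = np.ones((len(y), 1))

    if n_pep == 1:
        full = sm.OLS(y, X_full).fit()
        null = sm.OLS(y, X_null).fit()
        return float(full.params[1]), _lrt_p(full.llf, null.llf), True

    pep_idx = np.repeat(np.arange(n_pep), n_samp)

    def _fit_ml(X):
        """ML fit of the random-intercept model; a non-converged fit (the
        peptide variance MLE often sits on the zero boundary, e.g. after
        per-peptide normalization) is retried with the variance floored at
        0, which is the ordinary linear model, and the better likelihood
        wins."""
        mixed, ok = None, False
        try:
            mixed = sm.MixedLM(y, X, groups=pep_idx).fit(reml=False)
            ok = bool(mixed.converged) and np.isfinite(mixed.llf)
        except Exception:
            pass
        if ok:
            return mixed.params, float(mixed.llf), True
        floored = sm.OLS(y, X).fit()
        if mixed is not None and np.isfinite(mixed.llf) and mixed.llf > floored.llf:
            return mixed.params, float(mixed.llf), True
        return floored.params, float(floored.llf), np.isfinite(floored.llf)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params_full, llf_full, ok_full = _fit_ml(X_full)
        _, llf_null, ok_null = _fit_ml(X_null)
    return float(params_full[1]), _lrt_p(llf_full, llf_null), ok_full and ok_null


def run_de_analysis(
    table: PeptideTable,
    alpha: float = 0.05,
    ratio_stat: str = "mean",
) -> pd.DataFrame:
    """Full differential-expression analysis on a raw-scale peptide table.

    Imputes (group medians), standard-normalizes per peptide, then fits the
    mixed model per protein on the normalized values.  Group means are
    means over the protein's normalized peptide-sample cells; the LTS/STS
    ratio is computed from the raw-scale (imputed) intensities, by group
    ``mean`` (default) or ``median`` over all peptide-sample cells.
    Significance is flagged at ``p <= alpha`` with **no** multiple-testing
    adjustment (pre-specified protein sets).

    Returns a DataFrame with one row per protein: protein, n_peptides,
    sts_mean, lts_mean, ratio_lts_sts, effect, p_value, significant,
    converged.  Per-protein failures are reported (converged=False), not
    fatal.
    """
    if ratio_stat not in ("mean", "median"):
        raise ValueError(f"ratio_stat must be mean or median, got {ratio_stat!r}")
    log.info("no multiple-testing correction applied (pre-specified protein sets)")
    imputed = impute_missing_by_group_median(table)
    normed = standard_normalize_peptides(imputed)

    sts_cols = normed.samples_in(STS)
    lts_cols = normed.samples_in(LTS)
    rows = []
    for protein, peptides in normed.protein_map.groupby(normed.protein_map).groups.items():
        sub_n = normed.intensities.loc[peptides]
        sub_raw = imputed.intensities.loc[imputed.intensities.index.intersection(peptides)]
        stat = np.mean if ratio_stat == "mean" else np.median
        raw_sts = float(stat(sub_raw[sts_cols].to_numpy()))
        raw_lts = float(stat(sub_raw[lts_cols].to_numpy()))
        try:
            effect, p, converged = fit_protein_mixed_model(sub_n, normed.groups)
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("protein %s: model failed (%s)", protein, exc)
            effect, p, converged = float("nan"), float("nan"), False
        rows.append(
            ProteinDEResult(
                protein_id=str(protein),
                n_peptides=len(peptides),
                sts_mean=float(sub_n[sts_cols].to_numpy().mean()),
                lts_mean=float(sub_n[lts_cols].to_numpy().mean()),
                ratio_lts_sts=raw_lts / raw_sts if raw_sts != 0 else float("nan"),
                effect=effect,
                p_value=p,
                significant=bool(p <= alpha) if np.isfinite(p) else False,
                converged=converged,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).rename(columns={"protein_id": "protein"})
    return df.sort_values("p_value").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CART panels
# ---------------------------------------------------------------------------


@dataclass
class DecisionTree:
    """Small axis-aligned decision tree over protein features."""

    tree: DecisionTreeClassifier | None
    feature_names: list[str]
    majority_class: str | None = None
    splits: list[dict] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        if self.tree is None:
            return pd.Series(self.majority_class, index=X.index)
        pred = self.tree.predict(X[self.feature_names].to_numpy())
        return pd.Series(pred, index=X.index)

    def performance(self, X: pd.DataFrame, y: pd.Series) -> dict:
        """Confusion counts plus sensitivity/specificity for STS (the
        clinically actionable call)."""
        pred = self.predict(X)
        tp = int(((pred == STS) & (y == STS)).sum())
        fn = int(((pred != STS) & (y == STS)).sum())
        tn = int(((pred != STS) & (y != STS)).sum())
        fp = int(((pred == STS) & (y != STS)).sum())
        return {
            "tp_sts": tp,
            "fn_sts": fn,
            "tn_sts": tn,
            "fp_sts": fp,
            "sensitivity_sts": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity_sts": tn / (tn + fp) if tn + fp else float("nan"),
            "accuracy": float((pred == y).mean()),
        }


def fit_cart_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    max_depth: int = 2,
    min_leaf: int = 2,
    seed: int = 0,
) -> DecisionTree:
    """Greedy Gini CART over samples x proteins features.

    ``max_depth=0`` or single-class input yields a majority-class stump.
    The fitted splits (protein, threshold) are exposed on ``.splits``.
    """
    y = labels.loc[features.index]
    if max_depth == 0 or y.nunique() < 2:
        majority = y.value_counts().idxmax()
        return DecisionTree(tree=None, feature_names=list(features.columns), majority_class=majority)
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=int(seed),
    )
    clf.fit(features.to_numpy(), y.to_numpy())
    splits = []
    t = clf.tree_
    for node in range(t.node_count):
        if t.children_left[node] != t.children_right[node]:  # internal node
            splits.append(
                {
                    "protein": features.columns[t.feature[node]],
                    "threshold": float(t.threshold[node]),
                    "node": int(node),
                }
            )
    return DecisionTree(tree=clf, feature_names=list(features.columns), splits=splits)
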