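"""Readers, containers, and cohort definitions for expression, clinical,
and protein-interaction data.

The containers here are thin, validated wrappers around pandas DataFrames
and a networkx Graph.  Two operations carry scientific content:

* :func:`define_survival_groups` — the short-term / long-term survivor
  (STS/LTS) phenotype: after excluding pretreated patients, patients with a
  prior glioma, and patients of unknown vital status, the remaining deceased
  patients are ranked by survival and the bottom and top quartiles become
  the two phenotype classes.
* :func:`binarize_expression` — per-gene quartile binarization: samples in
  the top quartile of a gene's expression are state ``H`` (high), all others
  ``L`` (low).  The H/L states are the alphabet of subnetwork state
  functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STS = "STS"
LTS = "LTS"

EDGE_DIRECT = "direct_interaction"
EDGE_COMPLEX = "complex_comembership"

# SIF relationship dialects seen in interaction-database exports
_EDGE_TYPE_MAP = {
    "pp": EDGE_DIRECT,
    "direct": EDGE_DIRECT,
    "direct_interaction": EDGE_DIRECT,
    "interaction": EDGE_DIRECT,
    "complex": EDGE_COMPLEX,
    "cm": EDGE_COMPLEX,
    "complex_comembership": EDGE_COMPLEX,
}


class FormatError(ValueError):
    """Malformed input file."""


class ParseError(ValueError):
    """Unparseable cell content; message names the offending location."""


class CohortError(ValueError):
    """Cohort is empty or too small after exclusions."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous expression intensities."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class ClinicalTable:
    """Per-patient survival and eligibility information.

    Required columns: ``sample_id``, ``survival_days``, ``vital_status``
    (one of dead/alive/unknown), ``pretreated``, ``prior_glioma``.
    Optional: ``age_years``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "survival_days", "vital_status", "pretreated", "prior_glioma")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        bad = set(t["vital_status"]) - {"dead", "alive", "unknown"}
        if bad:
            raise ValueError(f"unknown vital_status values: {sorted(bad)}")
        dead = t[t["vital_status"] == "dead"]
        if dead["survival_days"].isna().any():
            raise ValueError("survival_days missing for deceased patient(s)")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PhenotypeLabels:
    """Sample -> {STS, LTS} phenotype class with the survival-day cutoffs
    that induced the split.  Unlabeled (middle-survival) patients are absent.
    """

    labels: pd.Series  # sample_id -> "STS" | "LTS"
    cutoff_low_days: float
    cutoff_high_days: float

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {STS, LTS}
        if bad:
            raise ValueError(f"labels must be STS/LTS, got {sorted(bad)}")
        if (self.labels == STS).sum() == 0 or (self.labels == LTS).sum() == 0:
            raise CohortError("both phenotype classes must be non-empty")

    @property
    def sts_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == STS])

    @property
    def lts_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == LTS])

    @property
    def n_sts(self) -> int:
        return int((self.labels == STS).sum())

    @property
    def n_lts(self) -> int:
        return int((self.labels == LTS).sum())

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)


@dataclass
class BinarizedMatrix:
    """Genes x samples H/L state matrix (stored as booleans, True = H)."""

    states: pd.DataFrame  # bool
    threshold_quantile: float = 0.25
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.states.index.duplicated().any() or self.states.columns.duplicated().any():
            raise ValueError("duplicate gene or sample ids")
        self.states = self.states.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)

    def state_char(self, gene: str, sample: str) -> str:
        return "H" if bool(self.states.at[gene, sample]) else "L"

    def to_tsv(self, path) -> None:
        chars = self.states.replace({True: "H", False: "L"})
        chars.to_csv(path, sep="\t", index_label="gene")


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network.

    Edges carry an ``edge_type`` attribute: a physical interaction
    (:data:`EDGE_DIRECT`) or co-membership in a protein complex
    (:data:`EDGE_COMPLEX`).
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self loops present: {loops[:5]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def load_expression_matrix(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV (first column = gene ids) or
    GCT 1.2.  Duplicate gene rows are collapsed by their mean (warning).

    Non-numeric cells raise :class:`ParseError` naming the cell.
    """
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"unsupported GCT version line: {version!r}")
            fh.readline()  # dimensions line; trusted but unused
            raw = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        # GCT has a Description column between ids and samples
        if raw.columns[0].lower() == "description":
            raw = raw.drop(columns=raw.columns[0])
    else:
        raise FormatError(f"unknown expression format: {format!r}")
    if raw.shape[1] == 0:
        raise FormatError("expression file has no sample columns")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {raw.iat[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r}"
        )
    if numeric.isna().any().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing value at gene {numeric.index[gi]!r}, sample {numeric.columns[si]!r}"
        )

    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        warnings.warn(f"collapsing {n_dup} duplicate gene row(s) by mean")
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def load_ppi_network(path, format: str = "sif") -> PPINetwork:
    """Read a SIF or 2/3-column TSV edge list into an undirected,
    deduplicated graph.  Records are ``nodeA [edge_type] nodeB``; SIF files
    may be tab- or whitespace-delimited.  Self loops are dropped (logged).
    """
    if format not in ("sif", "tsv"):
        raise FormatError(f"unknown network format: {format!r}")
    graph = nx.Graph()
    n_self = 0
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) == 2:
                a, b = tokens
                etype = EDGE_DIRECT
            elif len(tokens) == 3:
                a, raw_type, b = tokens
                etype = _EDGE_TYPE_MAP.get(raw_type.lower(), EDGE_DIRECT)
            else:
                raise FormatError(f"line {lineno}: expected 2 or 3 fields, got {len(tokens)}")
            n_records += 1
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b, edge_type=etype)
    if n_records == 0:
        raise FormatError(f"network file {path} contains no edge records")
    if n_self:
        log.info("dropped %d self-loop record(s)", n_self)
    net = PPINetwork(graph)
    net.n_self_loops_dropped = n_self
    return net


# ---------------------------------------------------------------------------
# cohort phenotype
# ---------------------------------------------------------------------------


def define_survival_groups(
    clinical: ClinicalTable,
    lower_fraction: float = 0.25,
    upper_fraction: float = 0.25,
    admit_censored_lts: bool = False,
) -> PhenotypeLabels:
    """Split a cohort into short-term and long-term survivors.

    Patients with a pretreatment history, a prior glioma, or unknown vital
    status are excluded.  The remaining *deceased* patients are ranked by
    survival days; the bottom ``lower_fraction`` become STS and the top
    ``upper_fraction`` become LTS (counts are floors, so the split is
    independent of row order; ties break on sample id).  Patients between
    the cutoffs stay unlabeled.

    With ``admit_censored_lts`` alive patients whose follow-up already
    exceeds the LTS cutoff are additionally labeled LTS (off by default:
    the deceased-only split is the primary definition).
    """
    t = clinical.table
    eligible = t[
        ~t["pretreated"].astype(bool)
        & ~t["prior_glioma"].astype(bool)
        & (t["vital_status"] != "unknown")
    ]
    if eligible.empty:
        raise CohortError("no eligible patients after exclusions")
    dead = eligible[eligible["vital_status"] == "dead"].copy()
    n = len(dead)
    if n < 8:
        raise CohortError(f"only {n} deceased patients after exclusions; need >= 8")

    dead = dead.sort_values(["survival_days", "sample_id"], kind="mergesort")
    n_low = int(np.floor(lower_fraction * n))
    n_high = int(np.floor(upper_fraction * n))
    if n_low == 0 or n_high == 0:
        raise CohortError("fractions too small: a phenotype class would be empty")

    sts = dead.iloc[:n_low]
    lts = dead.iloc[n - n_high :]
    cutoff_low = float(dead.iloc[n_low]["survival_days"])
    cutoff_high = float(dead.iloc[n - n_high - 1]["survival_days"])

    labels = pd.concat(
        [
            pd.Series(STS, index=sts["sample_id"].to_numpy()),
            pd.Series(LTS, index=lts["sample_id"].to_numpy()),
        ]
    )
    if admit_censored_lts:
        alive = eligible[eligible["vital_status"] == "alive"]
        extra = alive[alive["survival_days"] > cutoff_high]
        if len(extra):
            labels = pd.concat([labels, pd.Series(LTS, index=extra["sample_id"].to_numpy())])
            log.info("admitted %d censored long-survival patients to LTS", len(extra))
    labels.index.name = "sample_id"
    return PhenotypeLabels(labels, cutoff_low_days=cutoff_low, cutoff_high_days=cutoff_high)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize_expression(
    expr: ExpressionMatrix, top_fraction: float = 0.25, scope: str = "per_gene"
) -> BinarizedMatrix:
    """Quartile-binarize expression: per gene, samples at or above the
    ``1 - top_fraction`` linear-interpolation sample quantile are H, the
    rest L.  Binarization depends only on within-gene ranks, so it is
    invariant to any strictly monotone per-gene transform.

    Constant genes have no top quartile and are set all-L with a warning.
    """
    if scope != "per_gene":
        raise ValueError(f"unsupported binarization scope: {scope!r}")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    v = expr.values
    if v.shape[1] < 4:
        raise ValueError(f"need >= 4 samples to binarize, got {v.shape[1]}")
    arr = v.to_numpy(dtype=float)
    thr = np.quantile(arr, 1.0 - top_fraction, axis=1, method="linear")
    states = arr >= thr[:, None]
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) set to all-L (no top quartile)"
        )
        states[constant, :] = False
    return BinarizedMatrix(
        states=pd.DataFrame(states, index=v.index, columns=v.columns),
        threshold_quantile=top_fraction,
        metadata={"quantile_method": "linear", "tie_rule": "ge", "scope": "per_gene"},
    )


def binarize_with_reference(
    expr: ExpressionMatrix,
    reference: ExpressionMatrix,
    top_fraction: float = 0.25,
) -> BinarizedMatrix:
    """Binarize ``expr`` using per-gene thresholds computed on a
    *reference* cohort (e.g. the training data), instead of the cohort's
    own quantiles.  Appropriate only when the two cohorts share a
    measurement scale; self-referenced binarization absorbs platform
    shifts and is the default elsewhere."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    shared = [g for g in expr.gene_ids if g in reference.values.index]
    if not shared:
        raise ValueError("no genes shared with the reference cohort")
    v = expr.values.loc[shared]
    ref = reference.values.loc[shared].to_numpy(dtype=float)
    thr = np.quantile(ref, 1.0 - top_fraction, axis=1, method="linear")
    states = v.to_numpy(dtype=float) >= thr[:, None]
    return BinarizedMatrix(
        states=pd.DataFrame(states, index=v.index, columns=v.columns),
        threshold_quantile=top_fraction,
        metadata={"quantile_method": "linear", "tie_rule": "ge", "reference": "train"},
    )


def intersect_with_network(expr: ExpressionMatrix, network: PPINetwork) -> ExpressionMatrix:
    """Restrict an expression matrix to genes present in the network
    (symbol intersection; counts logged, no identifier translation)."""
    shared = [g for g in expr.gene_ids if network.graph.has_node(g)]
    log.info(
        "gene overlap with network: %d of %d expression genes", len(shared), len(expr.gene_ids)
    )
    return ExpressionMatrix(expr.values.loc[shared])
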