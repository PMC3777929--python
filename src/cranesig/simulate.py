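"""Synthetic-data generators emulating the statistical structure the
pipeline assumes, so every stage can run and be validated without any
external download.

Three generators:

* **Expression cohorts** — a scale-free PPI network with planted connected
  subnetworks whose H/L state functions are class-conditionally associated
  with the survival phenotype (tunable confidence / anti-confidence per
  state).  Expression values are drawn from an upper-quartile component for
  H cells and a lower component for L cells, so per-gene quartile
  binarization recovers the planted states.  Survival days are
  class-conditional log-normal, placed so the short-term class falls below
  the 225-day cutoff and the long-term class above the 635-day cutoff used
  in the study design.
* **Peptide tables** — protein baseline + group fixed effect + per-peptide
  random intercept + residual on the log scale (the mixed model's exact
  generative form), exponentiated to a raw intensity scale, with optional
  group-structured missingness.  Default group sizes mirror the 10 STS / 6
  LTS proteomics cohort.
* **Centroid panels** — independent subtype centroids plus per-sample
  noise, with ground-truth subtype labels.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    EDGE_COMPLEX,
    EDGE_DIRECT,
    LTS,
    STS,
    ClinicalTable,
    ExpressionMatrix,
    PhenotypeLabels,
    PPINetwork,
)
from .proteomics import PeptideTable

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class PlantedState:
    """One phenotype-associated state of a planted subnetwork.

    ``confidence`` = P(state | LTS), ``anti_confidence`` = P(state | STS).
    """

    state: str
    confidence: float
    anti_confidence: float

    def __post_init__(self) -> None:
        if set(self.state) - {"H", "L"}:
            raise ConfigError(f"state must be over H/L: {self.state!r}")
        for v in (self.confidence, self.anti_confidence):
            if not 0.0 <= v <= 1.0:
                raise ConfigError("confidence/anti_confidence must be in [0, 1]")


@dataclass
class PlantedSubnetworkSpec:
    """Size and class-conditional state distribution of one planted
    subnetwork.  Probability mass not claimed by the listed states goes to
    a background state model (independent per-gene H at a rate chosen to
    bring each gene's marginal H fraction to the binarization quartile)."""

    size: int
    states: list[PlantedState]

    def __post_init__(self) -> None:
        for st in self.states:
            if len(st.state) != self.size:
                raise ConfigError(
                    f"state {st.state!r} length != subnetwork size {self.size}"
                )
        if sum(s.confidence for s in self.states) > 1.0 + 1e-9:
            raise ConfigError("state confidences sum above 1")
        if sum(s.anti_confidence for s in self.states) > 1.0 + 1e-9:
            raise ConfigError("state anti-confidences sum above 1")


def two_state_design(
    size: int, confidence: float = 0.5, anti_confidence: float = 0.02
) -> PlantedSubnetworkSpec:
    """Simple planted design: a long-survivor state with H on the first
    half of the genes and the mirrored short-survivor state, each seen in
    its own class with ``confidence`` and in the other with
    ``anti_confidence``.

    Note: under this design every planted gene is *individually*
    class-associated (its marginal H rate differs between classes), so it
    tests single-gene signal as much as combinatorial signal.  Use
    :func:`balanced_design` to plant purely combinatorial associations.
    """
    half = size // 2
    f_lts = "H" * half + "L" * (size - half)
    f_sts = "L" * half + "H" * (size - half)
    return PlantedSubnetworkSpec(
        size=size,
        states=[
            PlantedState(f_lts, confidence, anti_confidence),
            PlantedState(f_sts, anti_confidence, confidence),
        ],
    )


def balanced_design(
    size: int, confidence: float = 0.48, cross: float = 0.02
) -> PlantedSubnetworkSpec:
    """Purely combinatorial planted design: two states per class with
    identical per-gene H marginals across classes, so no single gene is
    informative but the joint state pattern is.

    Long-survivor states: H on the first half of the genes, and its
    complement.  Short-survivor states: H on alternating positions, and
    its complement (for size 2, the XOR construction HH/LL vs HL/LH).
    Each class shows its own two states with total probability
    ``confidence`` (split evenly) and the other class's states with total
    probability ``cross``; remaining mass goes to the background model.
    Every gene is H in exactly one state of each class, so its H rate is
    (confidence + cross)/4 per state pair in both classes — keep
    ``confidence + cross <= 2 * top_fraction`` so quartile binarization
    recovers the states.
    """
    if size < 2:
        raise ConfigError("balanced design needs size >= 2")
    if size == 2:
        lts_states = ["HH", "LL"]
        sts_states = ["HL", "LH"]
    else:
        half = (size + 1) // 2
        a = "H" * half + "L" * (size - half)
        b = "L" * half + "H" * (size - half)
        c = "".join("H" if i % 2 == 0 else "L" for i in range(size))
        d = "".join("L" if i % 2 == 0 else "H" for i in range(size))
        if a in (c, d) or b in (c, d):  # degenerate overlap at tiny sizes
            c, d = "H" * size, "L" * size
        lts_states, sts_states = [a, b], [c, d]
    return PlantedSubnetworkSpec(
        size=size,
        states=[
            PlantedState(lts_states[0], confidence / 2, cross / 2),
            PlantedState(lts_states[1], confidence / 2, cross / 2),
            PlantedState(sts_states[0], cross / 2, confidence / 2),
            PlantedState(sts_states[1], cross / 2, confidence / 2),
        ],
    )


@dataclass
class CohortSimConfig:
    """Study-condition parameters for a synthetic expression cohort.

    Defaults mirror the discovery design: quartile binarization
    (``top_fraction`` 0.25), survival cutoffs 225 / 635 days, and a
    scale-free interaction network.  ``n_middle`` adds unlabeled
    middle-survival patients so a quartile split over deceased patients
    recovers the planted classes (middle = 2x each class by default,
    matching a 25/25 split)."""

    n_genes: int = 500
    n_sts: int = 43
    n_lts: int = 43
    n_middle: int | None = None  # default: n_sts + n_lts (quartile geometry)
    planted: list[PlantedSubnetworkSpec] = field(default_factory=list)
    top_fraction: float = 0.25
    noise_sd: float = 0.2
    h_effect: float = 2.0
    network_attachment: int = 2
    complex_edge_fraction: float = 0.15
    sts_median_days: float = 120.0
    lts_median_days: float = 1000.0
    survival_log_sd: float = 0.35
    cutoff_low_days: int = 225
    cutoff_high_days: int = 635
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("need n_genes >= 10")
        if self.n_middle is None:
            self.n_middle = self.n_sts + self.n_lts
        total_planted = sum(p.size for p in self.planted)
        if total_planted > self.n_genes:
            raise ConfigError(
                f"planted genes ({total_planted}) exceed n_genes ({self.n_genes})"
            )


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def generate_ppi_network(
    config: CohortSimConfig, rng: np.random.Generator | None = None
) -> tuple[PPINetwork, list[tuple[str, ...]]]:
    """Scale-free (preferential-attachment) interaction network with the
    planted subnetwork gene sets embedded as disjoint connected subgraphs.

    Returns the network and the planted gene sets (one tuple per planted
    subnetwork spec, in spec order)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes
    g_int = nx.barabasi_albert_graph(
        n, config.network_attachment, seed=int(rng.integers(2**31 - 1))
    )
    names = [f"G{i:05d}" for i in range(n)]
    graph = nx.relabel_nodes(g_int, dict(zip(range(n), names)))
    for u, v in graph.edges:
        graph.edges[u, v]["edge_type"] = (
            EDGE_COMPLEX if rng.random() < config.complex_edge_fraction else EDGE_DIRECT
        )

    planted_sets: list[tuple[str, ...]] = []
    used: set[str] = set()
    for spec in config.planted:
        placed = None
        for _try in range(200):
            start = names[int(rng.integers(n))]
            if start in used:
                continue
            # grow a connected set by random BFS over unused nodes
            members = [start]
            frontier = set(graph.neighbors(start)) - used
            while len(members) < spec.size and frontier:
                nxt = sorted(frontier)[int(rng.integers(len(frontier)))]
                members.append(nxt)
                frontier |= set(graph.neighbors(nxt))
                frontier -= set(members) | used
            if len(members) == spec.size:
                placed = tuple(members)
                break
        if placed is None:
            raise ConfigError(
                f"could not embed a connected planted subnetwork of size {spec.size}"
            )
        used.update(placed)
        planted_sets.append(placed)
    return PPINetwork(graph), planted_sets


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSim:
    """A simulated cohort plus its ground truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    network: PPINetwork
    labels_true: PhenotypeLabels
    planted_sets: list[tuple[str, ...]]
    true_states: list[pd.Series]  # per planted subnetwork: sample -> state string
    config: CohortSimConfig


def generate_expression_cohort(
    network: PPINetwork,
    planted_sets: list[tuple[str, ...]],
    config: CohortSimConfig,
    rng: np.random.Generator | None = None,
) -> CohortSim:
    """Sample a cohort over a network with planted state-function signal.

    For each planted subnetwork, every sample draws a state from its
    class-conditional distribution (listed states by confidence /
    anti-confidence; remaining mass to a background category).  Each
    planted gene's H count is then topped up to the binarization quartile
    using background samples only, so per-gene quartile binarization
    reproduces the planted state strings exactly (up to expression noise);
    background top-ups are class-neutral.  H cells get expression
    ``h_effect`` above L cells, both with Gaussian noise ``noise_sd``;
    unplanted genes are pure standard-normal noise.  Middle (unlabeled)
    samples draw from the class-average state distribution.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_s, n_l, n_m = config.n_sts, config.n_lts, config.n_middle
    n = n_s + n_l + n_m
    samples = [f"S{i:04d}" for i in range(n)]
    classes = np.array([STS] * n_s + ["MID"] * n_m + [LTS] * n_l)

    genes = sorted(network.nodes)
    values = rng.normal(0.0, 1.0, size=(len(genes), n))
    gene_pos = {g: i for i, g in enumerate(genes)}

    true_states: list[pd.Series] = []
    for spec, gene_set in zip(config.planted, planted_sets):
        probs = {}
        for cls, attr in ((STS, "anti_confidence"), (LTS, "confidence")):
            p = np.array([getattr(s, attr) for s in spec.states])
            probs[cls] = np.append(p, 1.0 - p.sum())  # last slot = background
        probs["MID"] = (probs[STS] + probs[LTS]) / 2.0

        # marginal planted H rate per gene position, over the whole cohort
        w = np.array([n_s, n_m, n_l]) / n
        state_mat = np.array(
            [[c == "H" for c in s.state] for s in spec.states], dtype=float
        )  # (n_states, size)
        pf = (
            w[0] * probs[STS][:-1] + w[1] * probs["MID"][:-1] + w[2] * probs[LTS][:-1]
        )
        planted_rate = pf @ state_mat
        if (planted_rate > config.top_fraction + 0.05).any():
            log.warning(
                "planted H rate exceeds binarization quartile for some genes; "
                "state recovery will degrade"
            )

        drawn = np.empty(n, dtype=object)
        H = np.zeros((spec.size, n), dtype=bool)
        is_bg = np.zeros(n, dtype=bool)
        for j, cls in enumerate(classes):
            p = probs[cls]
            choice = rng.choice(len(p), p=p)
            if choice < len(spec.states):
                s = spec.states[choice].state
                drawn[j] = s
                H[:, j] = [c == "H" for c in s]
            else:
                is_bg[j] = True
        # top up each gene's H count to the binarization quartile using
        # background samples (class-neutral), so the quartile cut falls in
        # the gap between the H and L expression components
        target = int(round(config.top_fraction * n))
        bg_idx = np.where(is_bg)[0]
        for gi in range(spec.size):
            deficit = target - int(H[gi].sum())
            if deficit > 0:
                free = bg_idx[~H[gi, bg_idx]]
                if deficit > len(free):
                    log.warning(
                        "gene %d of a planted subnetwork cannot reach the "
                        "binarization quartile (deficit %d > %d background)",
                        gi, deficit, len(free),
                    )
                    deficit = len(free)
                chosen = rng.choice(free, size=deficit, replace=False)
                H[gi, chosen] = True
        for j in bg_idx:
            drawn[j] = "".join("H" if x else "L" for x in H[:, j])
        idx = [gene_pos[g] for g in gene_set]
        values[idx, :] = config.h_effect * H + rng.normal(
            0.0, config.noise_sd, size=(spec.size, n)
        )
        true_states.append(pd.Series(drawn, index=samples))

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    # survival: class-conditional log-normal, clipped inside the cutoffs
    days = np.empty(n, dtype=int)
    for cls, median, lo, hi in (
        (STS, config.sts_median_days, 5, config.cutoff_low_days - 1),
        (LTS, config.lts_median_days, config.cutoff_high_days + 1, 4000),
    ):
        mask = classes == cls
        d = rng.lognormal(np.log(median), config.survival_log_sd, size=mask.sum())
        days[mask] = np.clip(np.round(d), lo, hi).astype(int)
    mid = classes == "MID"
    days[mid] = rng.integers(
        config.cutoff_low_days, config.cutoff_high_days + 1, size=mid.sum()
    )

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "survival_days": days,
                "vital_status": "dead",
                "pretreated": False,
                "prior_glioma": False,
                "age_years": np.clip(rng.normal(58, 10, size=n), 20, 90).round(1),
            }
        )
    )
    labeled = classes != "MID"
    labels_true = PhenotypeLabels(
        pd.Series(classes[labeled], index=np.array(samples)[labeled]),
        cutoff_low_days=float(config.cutoff_low_days),
        cutoff_high_days=float(config.cutoff_high_days),
    )
    return CohortSim(
        expression=expr,
        clinical=clinical,
        network=network,
        labels_true=labels_true,
        planted_sets=planted_sets,
        true_states=true_states,
        config=config,
    )


def simulate_cohort(config: CohortSimConfig) -> CohortSim:
    """Network + cohort in one call, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    network, planted_sets = generate_ppi_network(config, rng)
    return generate_expression_cohort(network, planted_sets, config, rng)


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------


@dataclass
class ProteomicsSimConfig:
    """Generative parameters for a synthetic peptide table.  Defaults
    mirror the validation cohort scale (10 STS + 6 LTS) and the mixed
    model's structure: log-intensity = protein baseline + group effect +
    peptide random intercept (sd ``peptide_sd``) + residual (sd
    ``residual_sd``)."""

    n_proteins: int = 100
    peptides_per_protein_mean: float = 3.4
    n_sts: int = 10
    n_lts: int = 6
    effects: dict = field(default_factory=dict)  # protein name -> log-scale effect
    peptide_sd: float = 0.5
    residual_sd: float = 1.0
    missing_rate: float | dict = 0.1
    baseline_mean: float = 14.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sts < 2 or self.n_lts < 2:
            raise ConfigError("need >= 2 samples per group")
        rates = (
            self.missing_rate.values()
            if isinstance(self.missing_rate, dict)
            else [self.missing_rate]
        )
        for r in rates:
            if not 0.0 <= r < 1.0:
                raise ConfigError("missing rate must be in [0, 1)")


def generate_peptide_data(
    config: ProteomicsSimConfig,
) -> tuple[PeptideTable, pd.DataFrame]:
    """Simulate a raw-scale peptide intensity table.

    Returns (table, truth), where truth has one row per protein with its
    planted log-scale group effect (0 for null proteins) and peptide count.
    Raw intensities are the exponential of the simulated log scale, so they
    are strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    prot_names = [f"P{i:04d}" for i in range(config.n_proteins)]
    n_pep = 1 + rng.poisson(max(config.peptides_per_protein_mean - 1.0, 0.0), config.n_proteins)
    samples = [f"STS{i:02d}" for i in range(config.n_sts)] + [
        f"LTS{i:02d}" for i in range(config.n_lts)
    ]
    groups = pd.Series(
        [STS] * config.n_sts + [LTS] * config.n_lts, index=samples, name="group"
    )
    is_lts = (groups == LTS).to_numpy(dtype=float)

    pep_ids, pep_prot, blocks = [], [], []
    for name, k in zip(prot_names, n_pep):
        beta = float(config.effects.get(name, 0.0))
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        b = rng.normal(0.0, config.peptide_sd, size=k)
        eps = rng.normal(0.0, config.residual_sd, size=(k, len(samples)))
        block = baseline + beta * is_lts[None, :] + b[:, None] + eps
        blocks.append(block)
        pep_ids.extend(f"{name}_pep{j}" for j in range(k))
        pep_prot.extend([name] * k)
    logmat = np.vstack(blocks)

    if isinstance(config.missing_rate, dict):
        rate = np.array([config.missing_rate.get(g, 0.0) for g in groups])
    else:
        rate = np.full(len(samples), config.missing_rate)
    mask = rng.random(logmat.shape) < rate[None, :]
    raw = np.exp(logmat)
    raw[mask] = np.nan

    table = PeptideTable(
        intensities=pd.DataFrame(raw, index=pep_ids, columns=samples),
        protein_map=pd.Series(pep_prot, index=pep_ids, name="protein"),
        groups=groups,
    )
    truth = pd.DataFrame(
        {
            "protein": prot_names,
            "effect": [float(config.effects.get(p, 0.0)) for p in prot_names],
            "n_peptides": n_pep,
        }
    ).set_index("protein")
    return table, truth


# ---------------------------------------------------------------------------
# centroid panels
# ---------------------------------------------------------------------------


def generate_centroid_data(
    n_genes: int = 840,
    subtypes=("Proneural", "Classical", "Neural", "Mesenchymal"),
    n_samples: int = 40,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionMatrix, pd.Series]:
    """Independent subtype centroids plus noisy samples with true labels.

    Sample raw expression is ``2**(centroid + noise + 10)`` so the values
    are positive and the per-sample log/median/sd preprocessing is a
    monotone transform of the underlying profile.
    """
    if len(subtypes) < 2:
        raise ConfigError("need >= 2 subtypes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    centroids = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_genes, len(subtypes))),
        index=genes,
        columns=list(subtypes),
    )
    labels = pd.Series(
        [subtypes[int(i)] for i in rng.integers(len(subtypes), size=n_samples)],
        index=[f"S{i:04d}" for i in range(n_samples)],
        name="subtype",
    )
    profile = centroids[labels].to_numpy() + rng.normal(
        0.0, noise_sd, size=(n_genes, n_samples)
    )
    raw = np.power(2.0, profile + 10.0)
    expr = ExpressionMatrix(pd.DataFrame(raw, index=genes, columns=labels.index))
    return centroids, expr, labels
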