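"""Combinatorial subnetwork mining: state functions, mutual information,
and search for phenotype-informative connected subnetworks.

The model
---------
Expression is binarized per gene into H/L.  For an ordered list of genes
(g1..gk) forming a connected subgraph of the PPI network, each sample
exhibits a *state function* f — the length-k H/L string of its genes.  Let C
be the phenotype class (STS vs LTS) and F the subnetwork state random
variable.  The score of a subnetwork is the plug-in mutual information

    I(C;F) = H(C) - H(C|F)          (bits)

estimated from the labeled samples.  Each observed state f contributes a
*J-value*

    J(f) = sum_c p(f,c) * log2( p(c|f) / p(c) )

and the J-values decompose the mutual information exactly:
sum_f J(f) = I(C;F).  A state is informative (high J) when it has high
support and its class profile — confidence p(f|LTS) versus anti-confidence
p(f|STS) — is skewed toward one class.

The search
----------
Connected subnetworks of at most ``d_max`` genes are found either by
exhaustive enumeration of connected subgraphs (feasible on small inputs and
used automatically when it is, ranked by plug-in I(C;F)) or by a seeded
beam search: every network node seeds a candidate, candidates grow one
adjacent gene at a time, and at each size the ``beam_width`` best
extensions per seed are kept, scored by their best single-state J-value.
Beam-identified candidates are then ranked by a selection-bias-resistant
mutual information — supported states only, minimum over two stratified
sample folds, maximal subnetworks first among near-ties — because the raw
in-sample plug-in MI of large subnetworks saturates regardless of signal
(see :func:`mine_subnetworks`).  Everything is deterministic given the
seed, and the exhaustive enumerator is the correctness contract for the
beam search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LTS, STS, BinarizedMatrix, PhenotypeLabels, PPINetwork

log = logging.getLogger(__name__)

_DECOMP_TOL = 1e-10


# ---------------------------------------------------------------------------
# entropy and per-subnetwork scoring
# ---------------------------------------------------------------------------


def entropy(distribution) -> float:
    """Shannon entropy in bits of a probability vector, with 0*log0 = 0."""
    p = np.asarray(distribution, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class StateRecord:
    """One observed state function of a subnetwork, with its statistics."""

    state: str
    support: float  # sigma(f): fraction of labeled samples with state f
    confidence: float  # p(f | LTS)
    anti_confidence: float  # p(f | STS)
    j_value: float  # contribution to I(C;F), bits

    def posterior_lts(self, n_sts: int, n_lts: int) -> float:
        """Derived accessor: p(LTS | f) for the cohort class sizes given.
        Not used in scoring (confidence is read as p(f | LTS))."""
        num = self.confidence * n_lts
        den = num + self.anti_confidence * n_sts
        return num / den if den > 0 else float("nan")


@dataclass
class Subnetwork:
    """A connected gene set with its observed state table and I(C;F)."""

    genes: tuple[str, ...]
    state_table: list[StateRecord]
    mutual_information: float

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class SignatureSet:
    """Top-k mutually disjoint subnetworks, ranked by decreasing I(C;F)."""

    subnetworks: list[Subnetwork]
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for sub in self.subnetworks:
            out.extend(sub.genes)
        return out

    def __len__(self) -> int:
        return len(self.subnetworks)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "subnetworks": [
                {
                    "genes": list(sub.genes),
                    "mutual_information": sub.mutual_information,
                    "states": [
                        {
                            "state": r.state,
                            "support": r.support,
                            "confidence": r.confidence,
                            "anti_confidence": r.anti_confidence,
                            "j_value": r.j_value,
                        }
                        for r in sub.state_table
                    ],
                }
                for sub in self.subnetworks
            ],
        }


def state_string(binarized: BinarizedMatrix, gene_list, sample: str) -> str:
    """The H/L state function of ``gene_list`` (in order) in one sample."""
    missing = [g for g in gene_list if g not in binarized.states.index]
    if missing:
        raise KeyError(f"genes absent from binarized matrix: {missing}")
    if sample not in binarized.states.columns:
        raise KeyError(f"sample absent from binarized matrix: {sample!r}")
    col = binarized.states.loc[list(gene_list), sample].to_numpy()
    return "".join("H" if h else "L" for h in col)


def _labeled_arrays(binarized: BinarizedMatrix, labels: PhenotypeLabels):
    """Bool state matrix restricted to labeled samples + LTS indicator."""
    samples = [s for s in labels.samples if s in binarized.states.columns]
    if len(samples) != len(labels.samples):
        missing = sorted(set(labels.samples) - set(samples))
        raise KeyError(f"labeled samples absent from binarized matrix: {missing[:5]}")
    B = binarized.states[samples].to_numpy(dtype=bool)
    y = (labels.labels.loc[samples] == LTS).to_numpy(dtype=np.int64)
    return B, y, samples


def state_table(
    binarized: BinarizedMatrix, gene_list, labels: PhenotypeLabels
) -> list[StateRecord]:
    """All observed state functions of a gene list over the labeled cohort.

    support = n(f)/n, confidence = n(f, LTS)/n_LTS, anti-confidence =
    n(f, STS)/n_STS, and J as in the module docstring.  Unobserved states
    are omitted (they contribute nothing).  Records are sorted by
    decreasing support, ties by state string.
    """
    genes = list(gene_list)
    B, y, samples = _labeled_arrays(binarized, labels)
    idx = [binarized.gene_ids.index(g) if g in binarized.states.index else None for g in genes]
    missing = [g for g, i in zip(genes, idx) if i is None]
    if missing:
        raise KeyError(f"genes absent from binarized matrix: {missing}")
    sub = binarized.states.loc[genes, samples].to_numpy(dtype=bool)

    n = len(samples)
    n_lts = int(y.sum())
    n_sts = n - n_lts
    if n_lts == 0 or n_sts == 0:
        raise ValueError("need at least one labeled sample per phenotype class")

    # encode each sample's state string as an integer (gene i -> bit i)
    powers = 1 << np.arange(len(genes), dtype=np.int64)
    codes = sub.T @ powers
    uniq, inv = np.unique(codes, return_inverse=True)
    counts = np.zeros((len(uniq), 2), dtype=np.int64)
    np.add.at(counts, (inv, y), 1)

    p_lts = n_lts / n
    p_c = np.array([1.0 - p_lts, p_lts])
    records = []
    for u, (c_sts, c_lts) in zip(uniq, counts):
        chars = ["H" if (u >> i) & 1 else "L" for i in range(len(genes))]
        joint = np.array([c_sts, c_lts]) / n  # p(f, c)
        pf = joint.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (joint / pf) / p_c
            terms = np.where(joint > 0, joint * np.log2(np.where(joint > 0, ratio, 1.0)), 0.0)
        records.append(
            StateRecord(
                state="".join(chars),
                support=float(pf),
                confidence=float(c_lts / n_lts),
                anti_confidence=float(c_sts / n_sts),
                j_value=float(terms.sum()),
            )
        )
    records.sort(key=lambda r: (-r.support, r.state))
    return records


def subnetwork_mutual_information(records: list[StateRecord], labels: PhenotypeLabels) -> float:
    """Plug-in I(C;F) = H(C) - H(C|F) reconstructed from a state table.

    Computed through the conditional-entropy route, independent of the
    per-state J-values; the decomposition sum_f J(f) = I(C;F) holds to
    numerical tolerance and is asserted by the test suite.
    """
    n_sts, n_lts = labels.n_sts, labels.n_lts
    n = n_sts + n_lts
    p_lts = n_lts / n
    h_c = entropy([1.0 - p_lts, p_lts])
    h_c_given_f = 0.0
    total_support = 0.0
    for r in records:
        joint = np.array([r.anti_confidence * n_sts, r.confidence * n_lts]) / n
        pf = joint.sum()
        total_support += pf
        if pf <= 0:
            continue
        h_c_given_f += pf * entropy(joint / pf)
    if abs(total_support - 1.0) > 1e-6:
        raise ValueError(f"state supports sum to {total_support}, expected 1")
    mi = h_c - h_c_given_f
    return float(max(mi, 0.0))


# ---------------------------------------------------------------------------
# vectorized scoring backend used by the search
# ---------------------------------------------------------------------------


_MIN_STATE_COUNT = 2  # states below this count are overfit noise for ranking


def _score_counts(
    counts: np.ndarray, n_sts: int, n_lts: int, min_count: int = _MIN_STATE_COUNT
):
    """(MI, best single-state J, supported MI) from an (n_states, 2)
    count table.  Supported MI sums J over states seen in at least
    ``min_count`` samples — rare states inflate the plug-in MI of large
    subnetworks regardless of real signal."""
    n = n_sts + n_lts
    joint = counts / n
    pf = joint.sum(axis=1, keepdims=True)
    p_c = np.array([n_sts / n, n_lts / n])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pf * p_c)
        terms = np.where(joint > 0, joint * np.log2(np.where(joint > 0, ratio, 1.0)), 0.0)
    j = terms.sum(axis=1)
    supported = counts.sum(axis=1) >= min_count
    return float(j.sum()), float(j.max(initial=0.0)), float(j[supported].sum())


def _batch_best_j_mi(parent_codes, u, ext_rows, y, n_sts, n_lts):
    """Score every candidate extension of one parent subnetwork at once.

    parent_codes: (n,) compact state codes in [0, u); ext_rows: (m, n) bool
    H/L rows of the m candidate genes.  Returns (mi[m], best_j[m],
    supported_mi[m]).
    """
    m, n = ext_rows.shape
    codes = parent_codes[None, :] + u * ext_rows  # (m, n) in [0, 2u)
    nbins = 2 * u
    flat = (np.arange(m)[:, None] * nbins + codes) * 2 + y[None, :]
    counts = np.bincount(flat.ravel(), minlength=m * nbins * 2).reshape(m, nbins, 2)
    ntot = n_sts + n_lts
    joint = counts / ntot
    pf = joint.sum(axis=2, keepdims=True)
    p_c = np.array([n_sts / ntot, n_lts / ntot])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pf * p_c)
        terms = np.where(joint > 0, joint * np.log2(np.where(joint > 0, ratio, 1.0)), 0.0)
    j = terms.sum(axis=2)  # (m, nbins)
    supported = counts.sum(axis=2) >= _MIN_STATE_COUNT
    return j.sum(axis=1), j.max(axis=1), (j * supported).sum(axis=1)


# ---------------------------------------------------------------------------
# exhaustive enumeration of connected subgraphs (ESU-style)
# ---------------------------------------------------------------------------


def _connected_subsets(adj: dict, nodes: list, d_max: int, limit: int | None = None):
    """Yield every connected node subset of size <= d_max exactly once.

    Standard ordered-extension enumeration: subsets are grown only with
    neighbors larger (in node order) than the root, so each subset is
    produced from its smallest member alone.
    """
    order = {v: i for i, v in enumerate(nodes)}
    count = 0
    for root in nodes:
        sub = [root]
        ext = sorted((u for u in adj[root] if order[u] > order[root]), key=order.get)
        stack = [(sub, ext)]
        while stack:
            sub, ext = stack.pop()
            count += 1
            if limit is not None and count > limit:
                raise _EnumerationLimit
            yield tuple(sub)
            if len(sub) == d_max:
                continue
            for i, w in enumerate(ext):
                new_ext = ext[i + 1 :] + sorted(
                    (
                        u
                        for u in adj[w]
                        if order[u] > order[root] and u not in sub and u not in ext
                    ),
                    key=order.get,
                )
                stack.append((sub + [w], new_ext))


class _EnumerationLimit(Exception):
    pass


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def mine_subnetworks(
    network: PPINetwork,
    binarized: BinarizedMatrix,
    labels: PhenotypeLabels,
    d_max: int = 10,
    beam_width: int = 5,
    seed: int = 0,
    method: str = "auto",
    max_exhaustive: int = 200_000,
    top_n: int = 100,
    split_ranking: bool = True,
    min_support: float = 0.1,
    epsilon: float = 0.25,
) -> list[Subnetwork]:
    """Search for phenotype-informative connected subnetworks of at most
    ``d_max`` genes, restricted to genes present in both the network and
    the binarized matrix.

    ``method``: ``"beam"`` (seeded beam search), ``"exhaustive"`` (full
    enumeration), or ``"auto"`` (exhaustive when at most ``max_exhaustive``
    connected subsets exist, else beam).

    The beam identifies candidates by their best single-state J-value and
    the identified candidates are then sorted by mutual information.
    Three guards keep this honest at realistic sample sizes, where
    maximizing an in-sample statistic over a huge space of subnetworks is
    badly biased:

    * the sorting MI counts only *supported* states (per-fold support >=
      ``min_support``; low-support states push the plug-in MI of any large
      subnetwork toward H(C) regardless of signal);
    * with ``split_ranking`` (default) the labeled samples are split into
      two stratified folds (fixed by ``seed``) and a candidate's rank
      score is the *minimum* of its two fold scores, so chance structure
      that does not replicate across folds gains nothing;
    * candidates scoring within a fraction ``epsilon`` of the best score
      are treated as statistically indistinguishable and the maximal
      subnetworks among them are reported first (the maximality
      convention of subnetwork pattern mining).

    Exhaustive mode ranks every enumerated candidate by full-sample
    plug-in I(C;F) directly (its best candidate attains the enumeration
    maximum by construction).

    Tie-breaks are lexicographic on sorted gene lists, so runs are
    reproducible.  The ``top_n`` best candidates are returned with full
    state tables and full-sample mutual information.
    """
    if method not in ("auto", "beam", "exhaustive"):
        raise ValueError(f"unknown mining method: {method!r}")
    shared = sorted(g for g in binarized.states.index if network.graph.has_node(g))
    if len(shared) < d_max:
        raise ValueError(
            f"gene overlap between network and matrix is {len(shared)} < d_max={d_max}"
        )
    gidx = {g: i for i, g in enumerate(shared)}
    B = binarized.states.loc[shared]
    Bm, y, samples = _labeled_arrays(
        BinarizedMatrix(B, binarized.threshold_quantile), labels
    )
    n_lts = int(y.sum())
    n_sts = len(y) - n_lts
    adj = {
        g: sorted(u for u in network.graph.neighbors(g) if u in gidx) for g in shared
    }

    def _score_gene_set(genes: tuple[str, ...]) -> tuple[float, float, float]:
        rows = Bm[[gidx[g] for g in genes]]
        powers = 1 << np.arange(len(genes), dtype=np.int64)
        codes = rows.T @ powers
        uniq, inv = np.unique(codes, return_inverse=True)
        counts = np.zeros((len(uniq), 2), dtype=np.int64)
        np.add.at(counts, (inv, y), 1)
        return _score_counts(counts, n_sts, n_lts)

    scored: dict[frozenset, tuple[float, float, float]] = {}  # fs -> (mi, best_j, smi)

    use_exhaustive = method == "exhaustive"
    if method == "auto":
        try:
            for _ in _connected_subsets(adj, shared, d_max, limit=max_exhaustive):
                pass
            use_exhaustive = True
        except _EnumerationLimit:
            use_exhaustive = False

    if use_exhaustive:
        for genes in _connected_subsets(adj, shared, d_max):
            scored[frozenset(genes)] = _score_gene_set(genes)
        # full plug-in MI ranking: the best candidate attains the
        # enumeration maximum by construction
        ranked = sorted(
            scored.items(), key=lambda kv: (-kv[1][0], tuple(sorted(kv[0])))
        )[:top_n]
    else:
        adj_idx = [
            np.array([gidx[u] for u in adj[g]], dtype=np.int64) for g in shared
        ]
        Bi = Bm.astype(np.int64)
        int_scored = _beam_search(
            Bi, y, n_sts, n_lts, adj_idx, d_max, beam_width
        )
        cand_sets = sorted(int_scored, key=lambda fs: tuple(sorted(fs)))
        sizes = np.array([len(fs) for fs in cand_sets])
        do_split = split_ranking and min(n_sts, n_lts) >= 8
        if split_ranking and not do_split:
            warnings.warn(
                "too few labeled samples per class for split ranking; "
                "ranking in-sample"
            )
        if do_split:
            # two stratified folds: a candidate's rank score is the worse
            # of its two fold scores, so structure that does not replicate
            # across folds gains nothing
            rng = np.random.default_rng(seed)
            folds = [[], []]
            for cls in (0, 1):
                idx = np.where(y == cls)[0]
                rng.shuffle(idx)
                half = len(idx) // 2
                folds[0].append(idx[:half])
                folds[1].append(idx[half:])
            fold_scores = []
            for f in folds:
                cols = np.sort(np.concatenate(f))
                mc = max(_MIN_STATE_COUNT, int(np.ceil(min_support * len(cols))))
                fold_scores.append(
                    _score_sets(Bi[:, cols], y[cols], cand_sets, min_count=mc)
                )
            rank_scores = np.minimum(*fold_scores)
        else:
            rank_scores = np.array([int_scored[fs][2] for fs in cand_sets])
        order = sorted(
            range(len(cand_sets)),
            key=lambda i: (-rank_scores[i], tuple(sorted(cand_sets[i]))),
        )
        # epsilon-maximality: among candidates statistically
        # indistinguishable from the best (within `epsilon`), report the
        # maximal subnetworks first
        best = rank_scores[order[0]] if order else 0.0
        cut = best * (1.0 - epsilon)
        head = [i for i in order if rank_scores[i] >= cut]
        tail = [i for i in order if rank_scores[i] < cut]
        head.sort(
            key=lambda i: (
                -sizes[i],
                -rank_scores[i],
                tuple(sorted(cand_sets[i])),
            )
        )
        ranked = []
        for i in (head + tail)[:top_n]:
            genes_t = tuple(sorted(shared[g] for g in cand_sets[i]))
            mi, _, _ = _score_gene_set(genes_t)
            ranked.append((frozenset(genes_t), (mi, float("nan"), rank_scores[i])))
        scored = dict.fromkeys((frozenset(fs) for fs in int_scored), None)
    out = []
    for fs, (mi, _bj, _smi) in ranked:
        genes = tuple(sorted(fs))
        records = state_table(binarized, genes, labels)
        out.append(Subnetwork(genes=genes, state_table=records, mutual_information=mi))
    log.info(
        "mined %d candidate subnetworks (%s search), best I(C;F)=%.4f bits",
        len(scored),
        "exhaustive" if use_exhaustive else "beam",
        out[0].mutual_information if out else float("nan"),
    )
    return out


try:  # JIT-compiled scoring kernel; pure-numpy fallback below
    from numba import njit as _njit

    @_njit(cache=False)
    def _kernel_scores(pcodes, u, ext, y, n_sts, n_lts, logtab, min_count):
        m, n = ext.shape
        nbins = 2 * u
        mi = np.zeros(m)
        bj = np.zeros(m)
        smi = np.zeros(m)
        counts = np.zeros((nbins, 2), dtype=np.int64)
        visited = np.empty(nbins, dtype=np.int64)
        ln = logtab[n]
        ls = logtab[n_sts]
        ll = logtab[n_lts]
        for r in range(m):
            nv = 0
            for i in range(n):
                c = pcodes[i] + u * ext[r, i]
                if counts[c, 0] == 0 and counts[c, 1] == 0:
                    visited[nv] = c
                    nv += 1
                counts[c, y[i]] += 1
            tot_mi = 0.0
            tot_smi = 0.0
            best = 0.0
            for v in range(nv):
                c = visited[v]
                a = counts[c, 0]
                b = counts[c, 1]
                j = 0.0
                lab = logtab[a + b]
                if a > 0:
                    j += (a / n) * (logtab[a] + ln - lab - ls)
                if b > 0:
                    j += (b / n) * (logtab[b] + ln - lab - ll)
                tot_mi += j
                if a + b >= min_count:
                    tot_smi += j
                if j > best:
                    best = j
                counts[c, 0] = 0
                counts[c, 1] = 0
            mi[r] = tot_mi
            bj[r] = best
            smi[r] = tot_smi
        return mi, bj, smi

    @_njit(cache=False)
    def _kernel_set_scores(B, y, sets, sizes, n_sts, n_lts, logtab, min_count):
        n_c = sets.shape[0]
        n = B.shape[1]
        smi = np.zeros(n_c)
        max_bins = 1 << int(sizes.max())
        counts = np.zeros((max_bins, 2), dtype=np.int64)
        visited = np.empty(n, dtype=np.int64)
        codes = np.empty(n, dtype=np.int64)
        ln = logtab[n]
        ls = logtab[n_sts]
        ll = logtab[n_lts]
        for ci in range(n_c):
            k = sizes[ci]
            for i in range(n):
                code = 0
                for gi in range(k):
                    code |= B[sets[ci, gi], i] << gi
                codes[i] = code
            nv = 0
            for i in range(n):
                c = codes[i]
                if counts[c, 0] == 0 and counts[c, 1] == 0:
                    visited[nv] = c
                    nv += 1
                counts[c, y[i]] += 1
            tot = 0.0
            for v in range(nv):
                c = visited[v]
                a = counts[c, 0]
                b = counts[c, 1]
                if a + b >= min_count:
                    j = 0.0
                    lab = logtab[a + b]
                    if a > 0:
                        j += (a / n) * (logtab[a] + ln - lab - ls)
                    if b > 0:
                        j += (b / n) * (logtab[b] + ln - lab - ll)
                    tot += j
                counts[c, 0] = 0
                counts[c, 1] = 0
            smi[ci] = tot
        return smi

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _score_sets(
    Bcols: np.ndarray, y: np.ndarray, sets, min_count: int = _MIN_STATE_COUNT
) -> np.ndarray:
    """Supported MI of each candidate gene-index set on the given samples."""
    n = len(y)
    n_lts = int(y.sum())
    n_sts = n - n_lts
    sizes = np.array([len(fs) for fs in sets], dtype=np.int64)
    if _HAVE_NUMBA and sizes.max(initial=1) <= 20:
        padded = np.zeros((len(sets), int(sizes.max(initial=1))), dtype=np.int64)
        for i, fs in enumerate(sets):
            padded[i, : len(fs)] = sorted(fs)
        return _kernel_set_scores(
            np.ascontiguousarray(Bcols),
            y.astype(np.int64),
            padded,
            sizes,
            n_sts,
            n_lts,
            _log2_table(n),
            min_count,
        )
    out = np.empty(len(sets))
    for i, fs in enumerate(sets):
        rows = Bcols[sorted(fs)]
        powers = 1 << np.arange(len(fs), dtype=np.int64)
        codes = rows.T @ powers
        uniq, inv = np.unique(codes, return_inverse=True)
        counts = np.zeros((len(uniq), 2), dtype=np.int64)
        np.add.at(counts, (inv, y), 1)
        j, _, smi = _score_counts(counts, n_sts, n_lts, min_count=min_count)
        out[i] = smi
    return out


def _extension_scores(pcodes, u, ext_rows, y, n_sts, n_lts):
    """(mi, best_j, supported_mi) per extension row, kernel-accelerated."""
    if _HAVE_NUMBA:
        n = len(y)
        logtab = _log2_table(n)
        return _kernel_scores(
            pcodes, u, ext_rows, y, n_sts, n_lts, logtab, _MIN_STATE_COUNT
        )
    return _batch_best_j_mi(pcodes, u, ext_rows, y, n_sts, n_lts)


_LOGTAB_CACHE: dict[int, np.ndarray] = {}


def _log2_table(n: int) -> np.ndarray:
    tab = _LOGTAB_CACHE.get(n)
    if tab is None:
        tab = np.zeros(n + 1)
        tab[1:] = np.log2(np.arange(1, n + 1, dtype=float))
        _LOGTAB_CACHE[n] = tab
    return tab


def _beam_search(Bm, y, n_sts, n_lts, adj_idx, d_max, beam_width):
    """Seeded beam search over integer gene indices.

    Every gene seeds a candidate; per seed and per size the ``beam_width``
    best extensions (by best single-state J-value, ties broken
    lexicographically within the evaluation window) survive and are
    recorded as candidates.  Already-expanded gene sets are not grown
    again from later seeds.  Returns {frozenset(indices): (mi, best_j,
    supported_mi)} for every recorded candidate.
    """
    n_genes = Bm.shape[0]
    y = y.astype(np.int64)
    scored: dict[frozenset, tuple[float, float, float]] = {}
    expanded: set[frozenset] = set()
    window = max(4 * beam_width, 16)  # candidates lex-sorted per step

    # seed scores
    for g in range(n_genes):
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (Bm[g], y), 1)
        scored[frozenset((g,))] = _score_counts(counts, n_sts, n_lts)

    for seed in range(n_genes):
        row = Bm[seed]
        uniq, codes = np.unique(row, return_inverse=True)
        frontier = [((seed,), codes.astype(np.int64), len(uniq))]
        for _size in range(2, d_max + 1):
            all_bj = []
            all_meta = []  # (parent_index, neighbor)
            parent_store = []
            for genes, pcodes, u in frontier:
                members = set(genes)
                nbrs = np.unique(np.concatenate([adj_idx[g] for g in genes]))
                nbrs = nbrs[~np.isin(nbrs, list(members))]
                if nbrs.size == 0:
                    continue
                ext_rows = np.ascontiguousarray(Bm[nbrs])
                mis, bjs, smis = _extension_scores(
                    pcodes, u, ext_rows, y, n_sts, n_lts
                )
                pi = len(parent_store)
                parent_store.append((genes, pcodes, u, mis, bjs, smis, nbrs))
                # guidance: best-J primary, supported MI breaks exact-J
                # ties (a module gene preserves all states, a lucky noise
                # gene only the best one)
                all_bj.append(bjs + 1e-3 * smis)
                all_meta.extend((pi, int(nb)) for nb in nbrs)
            if not all_meta:
                break
            bj_flat = np.concatenate(all_bj)
            k = min(window, len(bj_flat))
            top_idx = np.argpartition(-bj_flat, k - 1)[:k]
            # ensure every parent's best child is considered (beam
            # diversity: one lineage cannot monopolize all slots)
            per_parent_best: dict[int, int] = {}
            offset = 0
            for pi, (genes, pcodes, u, mis, bjs, smis, nbrs) in enumerate(parent_store):
                per_parent_best[pi] = offset + int(
                    np.argmax(bjs + 1e-3 * smis)
                )
                offset += len(nbrs)
            cand = []
            seen_ti: set[int] = set()
            for ti in list(top_idx) + list(per_parent_best.values()):
                ti = int(ti)
                if ti in seen_ti:
                    continue
                seen_ti.add(ti)
                pi, nb = all_meta[ti]
                genes = parent_store[pi][0]
                gtuple = tuple(sorted(genes + (nb,)))
                cand.append((-bj_flat[ti], gtuple, pi, nb, ti))
            cand.sort(key=lambda t: (t[0], t[1]))
            frontier = []
            taken: set[tuple] = set()
            parents_used: set[int] = set()
            # first pass: best child of each parent, in global J order;
            # second pass: fill remaining slots by global J order
            for restrict_to_parent_best in (True, False):
                for neg_bj, gtuple, pi, nb, ti in cand:
                    if len(frontier) >= beam_width:
                        break
                    if restrict_to_parent_best and ti != per_parent_best[pi]:
                        continue
                    if restrict_to_parent_best and pi in parents_used:
                        continue
                    if gtuple in taken:
                        continue
                    taken.add(gtuple)
                    parents_used.add(pi)
                    genes, pcodes, u, mis, bjs, smis, nbrs = parent_store[pi]
                    local = int(np.where(nbrs == nb)[0][0])
                    fs = frozenset(gtuple)
                    if fs not in scored:
                        scored[fs] = (
                            float(mis[local]),
                            float(bjs[local]),
                            float(smis[local]),
                        )
                    if fs in expanded:
                        continue
                    expanded.add(fs)
                    new_codes_raw = pcodes + u * Bm[nb]
                    nu, ncodes = np.unique(new_codes_raw, return_inverse=True)
                    frontier.append((gtuple, ncodes.astype(np.int64), len(nu)))
            if not frontier:
                break
    return scored


def compose_signature(candidates: list[Subnetwork], k: int = 5, metadata: dict | None = None) -> SignatureSet:
    """Greedy disjoint selection: scan MI-ranked candidates, skipping any
    sharing a gene with an already-selected subnetwork, until ``k`` are
    chosen.  Warns (without failing) if fewer than ``k`` disjoint
    candidates exist."""
    if len(candidates) < k:
        raise ValueError(f"need >= {k} candidates, got {len(candidates)}")
    chosen: list[Subnetwork] = []
    used: set[str] = set()
    for cand in candidates:
        if used & set(cand.genes):
            continue
        chosen.append(cand)
        used.update(cand.genes)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} pairwise-disjoint subnetworks found (requested {k})"
        )
    return SignatureSet(subnetworks=chosen, metadata=metadata or {})
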