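"""End-to-end orchestration of the three analysis arms:

1. **Discovery** — phenotype split, quartile binarization, subnetwork
   mining, signature composition on a discovery cohort.
2. **Validation** — cumulative classification of an independent cohort by
   the discovered signature, Kaplan-Meier / logrank comparison of the
   predicted survivor groups, and (optionally) centroid-subtype association
   testing.
3. **Proteomics** — mixed-model differential expression on a peptide
   table, signature/proteome intersection, yield comparison against an
   individual-marker ranking, and a CART panel over significant signature
   proteins.

Each step is a plain function over in-memory objects; passing ``out_dir``
writes the artifacts (signature JSON, report TSVs, run manifest) so any
stage can be rerun or swapped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import cumulative_evaluation, encode_features, train_classifier
from .io import (
    LTS,
    STS,
    BinarizedMatrix,
    ClinicalTable,
    ExpressionMatrix,
    PhenotypeLabels,
    PPINetwork,
    binarize_expression,
    define_survival_groups,
    intersect_with_network,
)
from .markers import proteomic_yield_analysis, rank_individual_gene_markers, signature_overlap
from .mining import SignatureSet, Subnetwork, compose_signature, mine_subnetworks
from .proteomics import PeptideTable, fit_cart_classifier, run_de_analysis
from .survival import chi_square_independence, kaplan_meier_estimate, logrank_groups_from_predictions

log = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, stage: str, params: dict) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "params": {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v)) for k, v in params.items()},
    }
    (out_dir / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass
class DiscoveryResult:
    signature: SignatureSet
    candidates: list[Subnetwork]
    labels: PhenotypeLabels
    binarized: BinarizedMatrix


def run_discovery(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    network: PPINetwork,
    lower_fraction: float = 0.25,
    upper_fraction: float = 0.25,
    top_fraction: float = 0.25,
    d_max: int = 10,
    beam_width: int = 5,
    k: int = 5,
    seed: int = 0,
    method: str = "auto",
    out_dir=None,
) -> DiscoveryResult:
    """Discovery arm: survival split -> binarization -> mining ->
    signature composition."""
    try:
        labels = define_survival_groups(clinical, lower_fraction, upper_fraction)
    except Exception as exc:
        raise RuntimeError(f"discovery failed at survival-group stage: {exc}") from exc
    expr_net = intersect_with_network(expr, network)
    binarized = binarize_expression(expr_net, top_fraction=top_fraction)
    candidates = mine_subnetworks(
        network, binarized, labels, d_max=d_max, beam_width=beam_width, seed=seed, method=method
    )
    signature = compose_signature(
        candidates,
        k=k,
        metadata={"seed": seed, "beam_width": beam_width, "d_max": d_max, "method": method},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "signature.json").write_text(json.dumps(signature.to_dict(), indent=2))
        rows = []
        for i, sub in enumerate(signature.subnetworks, 1):
            for r in sub.state_table:
                rows.append(
                    {
                        "subnetwork": i,
                        "genes": ";".join(sub.genes),
                        "state": r.state,
                        "support": r.support,
                        "confidence": r.confidence,
                        "anti_confidence": r.anti_confidence,
                        "j_value": r.j_value,
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "state_tables.tsv", sep="\t", index=False)
        _write_manifest(
            out_dir,
            "discovery",
            {
                "lower_fraction": lower_fraction,
                "upper_fraction": upper_fraction,
                "top_fraction": top_fraction,
                "d_max": d_max,
                "beam_width": beam_width,
                "k": k,
                "seed": seed,
                "method": method,
            },
        )
    return DiscoveryResult(signature=signature, candidates=candidates, labels=labels, binarized=binarized)


@dataclass
class ValidationResult:
    report: pd.DataFrame  # cumulative per-k evaluation
    best_k: int
    predictions: pd.Series  # predictions at best_k over all test samples
    logrank_statistic: float
    logrank_p: float
    km_curves: dict
    subtype_assignments: pd.DataFrame | None = None
    subtype_chi2: tuple | None = None


def run_validation(
    train_binarized: BinarizedMatrix,
    train_labels: PhenotypeLabels,
    test_expr: ExpressionMatrix,
    test_clinical: ClinicalTable,
    signature: SignatureSet,
    k_max: int = 10,
    seed: int = 0,
    model: str = "mlp",
    top_fraction: float = 0.25,
    binarize_reference: str = "self",
    train_expr: ExpressionMatrix | None = None,
    centroids: pd.DataFrame | None = None,
    out_dir=None,
) -> ValidationResult:
    """Validation arm on an independent cohort.

    By default the test cohort is binarized with its own per-gene
    quantiles (``binarize_reference="self"``, absorbing platform shift);
    ``binarize_reference="train"`` instead applies the training cohort's
    thresholds (requires ``train_expr``, same measurement scale).
    Cumulative accuracy/PPV are reported for k = 1..k_max; the k with
    maximal test accuracy defines the predicted survivor groups compared
    by Kaplan-Meier / logrank over the whole test cohort.
    """
    missing = [g for g in signature.genes if g not in test_expr.values.index]
    if missing:
        raise KeyError(f"signature genes absent from test matrix: {missing}")
    if binarize_reference == "self":
        test_binarized = binarize_expression(test_expr, top_fraction=top_fraction)
    elif binarize_reference == "train":
        if train_expr is None:
            raise ValueError("binarize_reference='train' requires train_expr")
        from .io import binarize_with_reference

        test_binarized = binarize_with_reference(test_expr, train_expr, top_fraction)
    else:
        raise ValueError(f"unknown binarize_reference: {binarize_reference!r}")
    test_labels = define_survival_groups(test_clinical)
    report = cumulative_evaluation(
        train_binarized, train_labels, test_binarized, test_labels, signature,
        k_max=k_max, seed=seed, model=model,
    )
    best_row = report.loc[report["accuracy"].idxmax()]
    best_k = int(best_row["k"])

    # predicted survivor groups over *all* test samples at best k
    feats_train = encode_features(train_binarized, signature, best_k)
    feats_test = encode_features(test_binarized, signature, best_k)
    clf = train_classifier(feats_train, train_labels, seed=seed, model=model)
    predictions = clf.predict(feats_test)

    t = test_clinical.table.set_index("sample_id")
    common = predictions.index.intersection(t.index)
    events = t.loc[common, "vital_status"] == "dead"
    if predictions.loc[common].nunique() < 2:
        log.warning("classifier predicted a single class; logrank comparison undefined")
        stat, p = float("nan"), float("nan")
    else:
        stat, p = logrank_groups_from_predictions(
            predictions.loc[common], t.loc[common, "survival_days"], events
        )
    km_curves = {}
    for cls in (STS, LTS):
        idx = [s for s in common if predictions[s] == cls]
        if idx:
            km_curves[cls] = kaplan_meier_estimate(
                t.loc[idx, "survival_days"], events.loc[idx], label=cls
            )

    subtype_assignments = None
    subtype_chi2 = None
    if centroids is not None:
        from .subtypes import assign_subtypes

        subtype_assignments = assign_subtypes(test_expr, centroids)
        joint = pd.crosstab(
            predictions.loc[common], subtype_assignments.loc[common, "subtype"]
        )
        subtype_chi2 = chi_square_independence(joint.to_numpy())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "classification_report.tsv", sep="\t", index=False)
        predictions.rename("predicted").to_csv(out_dir / "predictions.tsv", sep="\t")
        _write_manifest(out_dir, "validation", {"k_max": k_max, "seed": seed, "model": model})
    return ValidationResult(
        report=report,
        best_k=best_k,
        predictions=predictions,
        logrank_statistic=stat,
        logrank_p=p,
        km_curves=km_curves,
        subtype_assignments=subtype_assignments,
        subtype_chi2=subtype_chi2,
    )


@dataclass
class ProteomicsResult:
    de_table: pd.DataFrame
    signature_identified: set
    signature_significant: set
    signature_yield: object
    marker_yield: object | None
    cart: object | None
    cart_performance: dict | None


def run_proteomics(
    peptides: PeptideTable,
    signature: SignatureSet,
    marker_ranking: pd.DataFrame | None = None,
    alpha: float = 0.05,
    yield_step: int = 10,
    cart_max_depth: int = 2,
    seed: int = 0,
    out_dir=None,
) -> ProteomicsResult:
    """Proteomics arm: mixed-model DE, signature intersection, yield
    curves (signature prefix vs individual-marker prefix), and a CART
    panel on the significant signature proteins."""
    de = run_de_analysis(peptides, alpha=alpha)
    proteome = set(de["protein"].str.upper())
    de_set = set(de.loc[de["significant"], "protein"].str.upper())

    sig_genes = [g.upper() for g in signature.genes]
    n_ident, identified = signature_overlap(sig_genes, proteome)
    n_de, significant = signature_overlap(sig_genes, de_set)
    if n_ident == 0:
        log.warning("signature does not intersect the identified proteome")

    sizes = list(range(yield_step, len(sig_genes) + 1, yield_step)) or [len(sig_genes)]
    sig_yield = proteomic_yield_analysis(sig_genes, proteome, de_set, sizes=sizes)
    marker_yield = None
    if marker_ranking is not None:
        genes = list(marker_ranking["gene"])
        msizes = [s for s in sizes if s <= len(genes)] or [len(genes)]
        marker_yield = proteomic_yield_analysis(genes, proteome, de_set, sizes=msizes)

    cart = None
    cart_perf = None
    if significant:
        normed_de = de.set_index(de["protein"].str.upper())
        panel = sorted(significant)
        # per-sample protein features: mean normalized peptide intensity
        from .proteomics import impute_missing_by_group_median, standard_normalize_peptides

        normed = standard_normalize_peptides(impute_missing_by_group_median(peptides))
        pmap_upper = normed.protein_map.str.upper()
        feats = {}
        for prot in panel:
            rows = normed.intensities.loc[pmap_upper == prot]
            if len(rows):
                feats[prot] = rows.mean(axis=0)
        if feats:
            X = pd.DataFrame(feats)
            y = normed.groups.loc[X.index]
            cart = fit_cart_classifier(X, y, max_depth=cart_max_depth, seed=seed)
            cart_perf = cart.performance(X, y)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        de.to_csv(out_dir / "protein_de.tsv", sep="\t", index=False)
        sig_yield.table.to_csv(out_dir / "signature_yield.tsv", sep="\t", index=False)
        if marker_yield is not None:
            marker_yield.table.to_csv(out_dir / "marker_yield.tsv", sep="\t", index=False)
        _write_manifest(out_dir, "proteomics", {"alpha": alpha, "yield_step": yield_step, "seed": seed})
    return ProteomicsResult(
        de_table=de,
        signature_identified=identified,
        signature_significant=significant,
        signature_yield=sig_yield,
        marker_yield=marker_yield,
        cart=cart,
        cart_performance=cart_perf,
    )
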