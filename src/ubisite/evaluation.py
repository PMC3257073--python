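"""Evaluation protocols and metrics for imbalanced site prediction.

Protocols: leave-one-protein-out jackknife, protein-grouped stratified
k-fold cross-validation, and a single-pass independent test.  Splits are
always at the protein level so that windows of one protein never appear on
both sides.  By default the whole pipeline — discretization, FSNCMI subset
generation, forest training — is re-fit inside every fold; a ``paper_mode``
flag instead selects features once on the full dataset before looping,
which reproduces the select-then-validate protocol common in the older
site-prediction literature at the cost of feature-selection leakage (a
warning is logged).

Metrics: sensitivity, specificity and accuracy as percentages, and the
Matthews correlation coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold

from .encoders import EncodedDataset, FeatureRegistry
from .ensemble import BaseClassifierSpec, EnsembleModel, predict, train_ensemble
from .fsncmi import FeatureSubset, SelectorConfig, discretize, generate_subsets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Sn/Sp/AC in percent, MCC in [-1, 1], plus the underlying counts."""

    Sn: float
    Sp: float
    AC: float
    MCC: float
    counts: ConfusionCounts
    protocol: str = "independent"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protocol": self.protocol,
                    "Sn": self.Sn,
                    "Sp": self.Sp,
                    "AC": self.AC,
                    "MCC": self.MCC,
                    "TP": self.counts.TP,
                    "TN": self.counts.TN,
                    "FP": self.counts.FP,
                    "FN": self.counts.FN,
                }
            ]
        )


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction vector not aligned to labels")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(counts: ConfusionCounts, protocol: str = "independent") -> MetricReport:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), AC = (TP+TN)/N, and MCC.

    Sn/Sp/AC are reported as percentages.  Any zero factor in the MCC
    denominator yields MCC = 0 (the usual degenerate-case convention).
    """
    if counts.total == 0:
        raise ValueError("no evaluated sites")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    sp = 100.0 * tn / (tn + fp) if (tn + fp) else 0.0
    ac = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricReport(Sn=sn, Sp=sp, AC=ac, MCC=mcc, counts=counts, protocol=protocol)


def metrics_dict(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Convenience eval_fn for :func:`ubisite.ensemble.sweep_qbc`."""
    rep = compute_metrics(confusion_from_predictions(y_true, y_pred))
    return {"Sn": rep.Sn, "Sp": rep.Sp, "AC": rep.AC, "MCC": rep.MCC}


# ---------------------------------------------------------------------------
# pipeline configuration and fitting
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end configuration: selector, base learner, ensemble size."""

    selector: SelectorConfig = field(default_factory=SelectorConfig)
    classifier: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)
    qbc: int = 10
    master_seed: int = 0
    tie_positive: bool = True
    paper_mode: bool = False  # select features once on the full set before CV

    def __post_init__(self) -> None:
        if self.qbc < 1:
            raise ValueError("qbc must be >= 1")
        if self.qbc > self.selector.P:
            raise ValueError("qbc cannot exceed the number of generated subsets")


def fit_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    config: PipelineConfig,
    subsets: Sequence[FeatureSubset] | None = None,
) -> tuple[EnsembleModel, list[FeatureSubset]]:
    """Discretize, select qbc subsets via FSNCMI, train the voting ensemble."""
    if subsets is None:
        data = discretize(X, y, feature_ids, B=config.selector.B)
        subsets = generate_subsets(data, config.selector)
    subsets = list(subsets)[: config.qbc]
    model = train_ensemble(
        X,
        y,
        feature_ids,
        subsets,
        spec=config.classifier,
        master_seed=config.master_seed,
        tie_positive=config.tie_positive,
    )
    return model, subsets


def _grouped_rounds(
    dataset: EncodedDataset, fold_ids: list[list[str]]
) -> list[tuple[np.ndarray, np.ndarray]]:
    pid = np.array(dataset.protein_ids)
    rounds = []
    for ids in fold_ids:
        test_mask = np.isin(pid, list(ids))
        rounds.append((~test_mask, test_mask))
    return rounds


def _run_rounds(
    dataset: EncodedDataset,
    rounds: list[tuple[np.ndarray, np.ndarray]],
    config: PipelineConfig,
    protocol: str,
) -> MetricReport:
    shared_subsets: Sequence[FeatureSubset] | None = None
    if config.paper_mode:
        logger.warning(
            "paper_mode: features selected once on the full dataset before "
            "cross-validation; feature-selection leakage into the test folds"
        )
        data = discretize(
            dataset.X, dataset.y, dataset.feature_ids, B=config.selector.B
        )
        shared_subsets = generate_subsets(data, config.selector)
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for train_mask, test_mask in rounds:
        if test_mask.sum() == 0:
            continue
        model, _ = fit_pipeline(
            dataset.X[train_mask],
            dataset.y[train_mask],
            dataset.feature_ids,
            config,
            subsets=shared_subsets,
        )
        labels, _ = predict(model, dataset.X[test_mask])
        y_true_all.append(dataset.y[test_mask])
        y_pred_all.append(labels)
    counts = confusion_from_predictions(
        np.concatenate(y_true_all), np.concatenate(y_pred_all)
    )
    return compute_metrics(counts, protocol=protocol)


def jackknife_lopo(
    dataset: EncodedDataset, config: PipelineConfig | None = None
) -> MetricReport:
    """Leave-one-protein-out jackknife over the full pipeline.

    Each protein's sites are predicted by a model trained on all other
    proteins; predictions are pooled into a single confusion table.
    Proteins contributing no sites are skipped with a warning.
    """
    config = config or PipelineConfig()
    protein_ids = sorted(set(dataset.protein_ids))
    if len(protein_ids) < 2:
        raise ValueError("jackknife needs at least 2 proteins")
    rounds = _grouped_rounds(dataset, [[pid] for pid in protein_ids])
    return _run_rounds(dataset, rounds, config, protocol="jackknife_LOPO")


def kfold(
    dataset: EncodedDataset,
    k: int,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Protein-grouped, label-stratified k-fold cross-validation."""
    config = config or PipelineConfig()
    n_proteins = len(set(dataset.protein_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_proteins:
        raise ValueError(f"k={k} exceeds the number of proteins ({n_proteins})")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    rounds = [
        (np.isin(np.arange(dataset.y.size), tr), np.isin(np.arange(dataset.y.size), te))
        for tr, te in splitter.split(dataset.X, dataset.y, groups=dataset.protein_ids)
    ]
    return _run_rounds(dataset, rounds, config, protocol="kfold")


def independent_test(model: EnsembleModel, dataset: EncodedDataset) -> MetricReport:
    """Single-pass prediction on a held-out dataset."""
    if dataset.y.size == 0:
        raise ValueError("empty evaluation dataset")
    labels, _ = predict(model, dataset.X, feature_ids=dataset.feature_ids)
    counts = confusion_from_predictions(dataset.y, labels)
    return compute_metrics(counts, protocol="independent")


def check_disjoint(model_protein_ids: Sequence[str], dataset: EncodedDataset) -> bool:
    """Warn when evaluation proteins overlap the training proteins."""
    overlap = set(model_protein_ids) & set(dataset.protein_ids)
    if overlap:
        logger.warning(
            "independent test set shares %d protein(s) with training: %s",
            len(overlap),
            sorted(overlap)[:5],
        )
    return not overlap


# ---------------------------------------------------------------------------
# feature-provenance analysis
# ---------------------------------------------------------------------------

def feature_provenance(
    subsets: Sequence[FeatureSubset], registry: FeatureRegistry
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count selected features per family and per window site.

    Counting is over the multiset of selected slots (a feature picked by
    three subsets counts three times).  Composition features carry no
    window site and are excluded from the per-site table.
    """
    if not subsets:
        raise ValueError("no subsets to analyze")
    fam_counts: dict[str, int] = {f: 0 for f in ("AAC", "PSSM", "FACTOR", "DISORDER")}
    w = registry.config.w
    site_counts = {site: 0 for site in range(1, w + 1)}
    for s in subsets:
        for fid in s.feature_ids:
            d = registry.descriptor(fid)
            fam_counts[d.family] += 1
            if d.window_site is not None:
                site_counts[d.window_site] += 1
    family_table = pd.DataFrame(
        {"family": list(fam_counts), "count": list(fam_counts.values())}
    )
    site_table = pd.DataFrame(
        {"window_site": list(site_counts), "count": list(site_counts.values())}
    )
    return family_table, site_table


def summarize_reports(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Mean and standard deviation of each metric over repeated runs."""
    df = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    stats = df[["Sn", "Sp", "AC", "MCC"]].agg(["mean", "std"])
    return stats
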