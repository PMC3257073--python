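"""Majority-voting ensemble of random-forest base classifiers.

Each base classifier is a random forest trained on the columns of one
selected feature subset; all members see the same samples.  At prediction
time each member casts one vote and a site is called positive when at
least half the members vote positive (ties go to the minority positive
class).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .fsncmi import FeatureSubset

_ARCHIVE_VERSION = 1


@dataclass
class BaseClassifierSpec:
    """Hyperparameters shared by every base random forest."""

    n_trees: int = 500
    features_per_split: str | int | float = "sqrt"
    oob_score: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class EnsembleModel:
    """Qbc (subset, trained forest) pairs plus the voting rule."""

    subsets: list[FeatureSubset]
    members: list[RandomForestClassifier]
    feature_ids: list[str]
    registry_fingerprint: str
    spec: BaseClassifierSpec
    master_seed: int
    tie_positive: bool = True
    oob_scores: list[float | None] = field(default_factory=list)

    @property
    def qbc(self) -> int:
        return len(self.members)

    def member_columns(self, p: int) -> list[int]:
        return self.subsets[p].indices


def registry_fingerprint(feature_ids: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_ids).encode()).hexdigest()


def _member_seed(master_seed: int, p: int) -> int:
    digest = hashlib.sha256(f"{master_seed}:{p}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    subsets: Sequence[FeatureSubset],
    spec: BaseClassifierSpec | None = None,
    master_seed: int = 0,
    tie_positive: bool = True,
) -> EnsembleModel:
    """Train one random forest per feature subset on the same sample set.

    Member p sees only the columns of subset p; its RNG seed is derived
    deterministically from ``master_seed`` and p.
    """
    spec = spec or BaseClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_ids = list(feature_ids)
    id_index = {fid: i for i, fid in enumerate(feature_ids)}
    members: list[RandomForestClassifier] = []
    oob: list[float | None] = []
    resolved: list[FeatureSubset] = []
    for p, subset in enumerate(subsets):
        unknown = [f for f in subset.feature_ids if f not in id_index]
        if unknown:
            raise ValueError(f"subset {p} references unknown features {unknown}")
        indices = [id_index[f] for f in subset.feature_ids]
        resolved.append(
            FeatureSubset(
                feature_ids=list(subset.feature_ids),
                indices=indices,
                start=subset.start,
                trajectory=list(subset.trajectory),
                stopping_reason=subset.stopping_reason,
            )
        )
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=spec.features_per_split,
            oob_score=spec.oob_score,
            random_state=_member_seed(master_seed, p),
            n_jobs=1,
        )
        clf.fit(X[:, indices], y)
        members.append(clf)
        oob.append(float(clf.oob_score_) if spec.oob_score else None)
    return EnsembleModel(
        subsets=resolved,
        members=members,
        feature_ids=feature_ids,
        registry_fingerprint=registry_fingerprint(feature_ids),
        spec=spec,
        master_seed=master_seed,
        tie_positive=tie_positive,
        oob_scores=oob,
    )


def predict(
    model: EnsembleModel,
    X: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    q: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote prediction: (labels, vote_fractions).

    ``vote_fraction`` is the share of members voting positive; the label is
    positive iff the fraction is >= 0.5 (or > 0.5 when ties are configured
    negative).  ``q`` restricts voting to the first q members (nested
    sub-ensembles for the Qbc sweep).
    """
    if feature_ids is not None and list(feature_ids) != model.feature_ids:
        raise ValueError("feature layout does not match the model's registry")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_ids):
        raise ValueError("feature matrix not aligned to the model's registry")
    q = model.qbc if q is None else q
    if not (1 <= q <= model.qbc):
        raise ValueError(f"q must be in 1..{model.qbc}")
    votes = np.zeros((X.shape[0], q), dtype=int)
    for p in range(q):
        votes[:, p] = model.members[p].predict(X[:, model.member_columns(p)])
    fractions = votes.mean(axis=1)
    if model.tie_positive:
        labels = (fractions >= 0.5).astype(int)
    else:
        labels = (fractions > 0.5).astype(int)
    return labels, fractions


def sweep_qbc(
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_ids: Sequence[str],
    subsets: Sequence[FeatureSubset],
    q_values: Sequence[int],
    eval_fn,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    spec: BaseClassifierSpec | None = None,
    master_seed: int = 0,
) -> list[dict]:
    """Evaluate nested ensembles built from the first q subsets.

    ``eval_fn(y_true, y_pred) -> mapping`` supplies the metric columns.
    Evaluation defaults to the training set when no test set is given.
    """
    q_values = list(q_values)
    if not q_values:
        raise ValueError("q_values must be non-empty")
    if any(not (1 <= q <= len(subsets)) for q in q_values):
        raise ValueError("every q must be within 1..len(subsets)")
    model = train_ensemble(
        X_train, y_train, feature_ids, subsets, spec=spec, master_seed=master_seed
    )
    Xe = X_train if X_test is None else np.asarray(X_test, dtype=float)
    ye = y_train if y_test is None else np.asarray(y_test, dtype=int)
    rows = []
    for q in q_values:
        labels, _ = predict(model, Xe, q=q)
        row = {"Qbc": q}
        row.update(eval_fn(ye, labels))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path) -> None:
    """Write the full model archive (config, subsets, members) to one file."""
    payload = {
        "version": _ARCHIVE_VERSION,
        "registry_fingerprint": model.registry_fingerprint,
        "feature_ids": model.feature_ids,
        "spec": {
            "n_trees": model.spec.n_trees,
            "features_per_split": model.spec.features_per_split,
            "oob_score": model.spec.oob_score,
        },
        "master_seed": model.master_seed,
        "tie_positive": model.tie_positive,
        "subsets": [
            {
                "feature_ids": s.feature_ids,
                "indices": s.indices,
                "start": s.start,
                "trajectory": s.trajectory,
                "stopping_reason": s.stopping_reason,
            }
            for s in model.subsets
        ],
        "members": model.members,
        "oob_scores": model.oob_scores,
    }
    joblib.dump(payload, path)


def load_model(path, expected_fingerprint: str | None = None) -> EnsembleModel:
    """Load a model archive, validating version and registry fingerprint."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt or non-archive file
        raise ValueError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"{path} is not a version-{_ARCHIVE_VERSION} model archive")
    if (
        expected_fingerprint is not None
        and payload["registry_fingerprint"] != expected_fingerprint
    ):
        raise ValueError("model was trained under a different feature registry")
    spec = BaseClassifierSpec(**payload["spec"])
    subsets = [FeatureSubset(**s) for s in payload["subsets"]]
    return EnsembleModel(
        subsets=subsets,
        members=payload["members"],
        feature_ids=payload["feature_ids"],
        registry_fingerprint=payload["registry_fingerprint"],
        spec=spec,
        master_seed=payload["master_seed"],
        tie_positive=payload["tie_positive"],
        oob_scores=payload.get("oob_scores", []),
    )
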