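"""Information-theoretic estimators and the FSNCMI feature selector.

FSNCMI (feature selection by normalized conditional mutual information) is a
greedy forward selector.  Candidates f are scored against the selected set
FS by

    J'(f) = min_{fs in FS}  I(f; C | fs) / H(f, C)

where C is the binary class.  The min over single already-selected features
approximates conditioning on the whole set while keeping the contingency
tables dense enough to estimate; the joint-entropy normalization counters
the bias of conditional MI toward many-valued features.  Candidates whose
criterion is (numerically) zero carry no information beyond FS and are
pruned permanently.  Running the same greedy search from different seed
features (the t-th ranked feature by marginal MI with the class) yields the
multiple overlapping subsets consumed by the voting ensemble.

All entropies are plug-in estimates from empirical frequencies, in bits.
Continuous features are first discretized by per-feature equal-frequency
binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SelectorConfig:
    """Knobs of the greedy selection.

    k: maximum subset size (default 12); delta: stop when two successive
    accepted criterion values differ by less than this (0 disables the
    rule, the default: k alone stops the search, matching the protocol of
    choosing k once from the criterion plateau and then running with fixed
    k — 0.015 is the usual diagnostic threshold on that plateau); B:
    equal-frequency bins per feature (default 5); P: number of subsets /
    starting points; epsilon: numeric zero for the pruning rule.
    """

    k: int = 12
    delta: float = 0.0
    B: int = 5
    P: int = 10
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.k < 1 or self.B < 2 or self.P < 1 or self.delta < 0:
            raise ValueError("invalid selector configuration")


@dataclass
class DiscretizedMatrix:
    """Integer bin codes per feature plus the aligned binary class vector."""

    codes: np.ndarray  # (n_samples, n_features) ints in [0, B)
    y: np.ndarray  # (n_samples,) in {0, 1}
    feature_ids: list[str]
    B: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if self.codes.shape[0] != self.y.size:
            raise ValueError("class vector not aligned to rows")
        if self.codes.shape[1] != len(self.feature_ids):
            raise ValueError("feature ids not aligned to columns")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


@dataclass
class FeatureSubset:
    """Output of one greedy run: ordered ids plus the criterion trajectory.

    The seed feature's trajectory entry is its normalized marginal MI
    I(f;C)/H(f,C); subsequent entries are the J' value at acceptance.
    """

    feature_ids: list[str]
    indices: list[int]
    start: int
    trajectory: list[float]
    stopping_reason: str  # k_reached | threshold | exhausted

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.trajectory):
            raise ValueError("trajectory length must equal subset size")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate features in subset")
        if not self.feature_ids:
            raise ValueError("subset must contain at least one feature")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(len(self.feature_ids)),
                "feature_id": self.feature_ids,
                "criterion": self.trajectory,
                "start": self.start,
                "stopping_reason": self.stopping_reason,
            }
        )


def write_subsets(subsets: Sequence[FeatureSubset], path) -> None:
    frames = []
    for p, s in enumerate(subsets):
        df = s.to_frame()
        df.insert(0, "subset", p)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_subsets(path, registry=None) -> list[FeatureSubset]:
    df = pd.read_csv(path, sep="\t")
    subsets = []
    for _, grp in df.groupby("subset", sort=True):
        grp = grp.sort_values("rank")
        ids = grp["feature_id"].tolist()
        indices = [registry.index_of(f) for f in ids] if registry is not None else []
        subsets.append(
            FeatureSubset(
                feature_ids=ids,
                indices=indices,
                start=int(grp["start"].iloc[0]),
                trajectory=grp["criterion"].tolist(),
                stopping_reason=str(grp["stopping_reason"].iloc[0]),
            )
        )
    return subsets


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(
    X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str], B: int = 5
) -> DiscretizedMatrix:
    """Per-feature equal-frequency binning into at most B bins.

    Bin edges are interior quantiles; duplicate edges (heavily tied
    features) collapse, so a feature occupies at most as many bins as it
    has distinct values.  Constant features map to a single bin code 0.
    Deterministic given the input.
    """
    if B < 2:
        raise ValueError("need at least 2 bins")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("empty feature matrix")
    n, d = X.shape
    codes = np.empty((n, d), dtype=np.int64)
    qs = np.linspace(0, 1, B + 1)[1:-1]
    for j in range(d):
        col = X[:, j]
        edges = np.unique(np.quantile(col, qs))
        raw = np.searchsorted(edges, col, side="right")
        # compact to consecutive codes so bin counts are meaningful
        _, codes[:, j] = np.unique(raw, return_inverse=True)
    return DiscretizedMatrix(codes=codes, y=y, feature_ids=list(feature_ids), B=B)


# ---------------------------------------------------------------------------
# plug-in estimators (bits)
# ---------------------------------------------------------------------------

def _check_aligned(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(a).ravel() for a in arrays)
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("code vectors must have equal length")
    if n == 0:
        raise ValueError("empty code vectors")
    return arrays


def _joint_counts(*arrays: np.ndarray) -> np.ndarray:
    """Flat contingency counts of one or more aligned code vectors."""
    idx = np.zeros(arrays[0].size, dtype=np.int64)
    for a in arrays:
        idx = idx * (a.max() + 1) + a
    return np.bincount(idx)


def _entropy_of_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(x: np.ndarray) -> float:
    """Plug-in Shannon entropy H(X) in bits."""
    (x,) = _check_aligned(x)
    return _entropy_of_counts(np.bincount(x - x.min()))


def joint_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in joint entropy H(X, Y) in bits."""
    x, y = _check_aligned(x, y)
    return _entropy_of_counts(_joint_counts(x - x.min(), y - y.min()))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), plug-in, in bits (>= 0 up to fp error)."""
    x, y = _check_aligned(x, y)
    x = x - x.min()
    y = y - y.min()
    hx = _entropy_of_counts(np.bincount(x))
    hy = _entropy_of_counts(np.bincount(y))
    hxy = _entropy_of_counts(_joint_counts(x, y))
    return hx + hy - hxy


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), plug-in, in bits.

    Equals H(Y|Z) - H(Y|X,Z); non-negative up to floating-point error.
    """
    x, y, z = _check_aligned(x, y, z)
    x = x - x.min()
    y = y - y.min()
    z = z - z.min()
    hz = _entropy_of_counts(np.bincount(z))
    hxz = _entropy_of_counts(_joint_counts(x, z))
    hyz = _entropy_of_counts(_joint_counts(y, z))
    hxyz = _entropy_of_counts(_joint_counts(x, y, z))
    return hxz + hyz - hz - hxyz


def criterion_J(
    f: np.ndarray, FS: Sequence[np.ndarray], C: np.ndarray
) -> float:
    """Normalized conditional MI criterion: min_fs I(f;C|fs) / H(f,C).

    Returns 0 when H(f,C) = 0 (both constant).
    """
    if len(FS) == 0:
        raise ValueError("FS must be non-empty; seed the subset first")
    hfc = joint_entropy(f, C)
    if hfc == 0.0:
        return 0.0
    return min(conditional_mutual_information(f, C, fs) for fs in FS) / hfc


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def _mi_ranking(data: DiscretizedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Features ranked by MI with the class, descending; ties -> smaller index."""
    mi = np.array(
        [mutual_information(data.codes[:, j], data.y) for j in range(data.n_features)]
    )
    order = np.lexsort((np.arange(data.n_features), -mi))
    return order, mi


def fsncmi_select(
    data: DiscretizedMatrix,
    t: int,
    config: SelectorConfig | None = None,
    _cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FeatureSubset:
    """One greedy FSNCMI run seeded with the t-th MI-ranked feature.

    Stops when the subset reaches ``config.k`` features, when two successive
    accepted criterion values differ by less than ``config.delta`` (the
    flattening of the J' trajectory signals that further features add
    little), or when every remaining candidate has been pruned.
    """
    config = config or SelectorConfig()
    if not (0 <= t < data.n_features):
        raise ValueError(f"starting index t={t} out of range")
    if _cache is None:
        _cache = _selector_cache(data)
    order, mi, hfc = _cache
    seed = int(order[t])
    C = data.y
    selected = [seed]
    traj = [mi[seed] / hfc[seed] if hfc[seed] > 0 else 0.0]
    candidates = np.ones(data.n_features, dtype=bool)
    candidates[seed] = False
    # running min over FS members of I(f;C|fs)/H(f,C), updated incrementally
    min_J = np.full(data.n_features, np.inf)
    reason = "exhausted"
    n_greedy = 0
    while len(selected) < config.k:
        last = selected[-1]
        z = data.codes[:, last]
        for j in np.flatnonzero(candidates):
            cmi = conditional_mutual_information(data.codes[:, j], C, z)
            val = cmi / hfc[j] if hfc[j] > 0 else 0.0
            if val < min_J[j]:
                min_J[j] = val
        # prune candidates carrying no information beyond FS
        prune = candidates & (min_J <= config.epsilon)
        candidates[prune] = False
        idx = np.flatnonzero(candidates)
        if idx.size == 0:
            reason = "exhausted"
            break
        best = int(idx[np.argmax(min_J[idx])])  # argmax keeps first -> smaller index
        best_J = float(min_J[best])
        n_greedy += 1
        if n_greedy >= 2 and abs(traj[-1] - best_J) < config.delta:
            reason = "threshold"
            break
        selected.append(best)
        traj.append(best_J)
        candidates[best] = False
    else:
        reason = "k_reached"
    return FeatureSubset(
        feature_ids=[data.feature_ids[j] for j in selected],
        indices=selected,
        start=t,
        trajectory=[float(v) for v in traj],
        stopping_reason=reason,
    )


def _selector_cache(
    data: DiscretizedMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the MI ranking and per-feature H(f,C), shared across runs."""
    order, mi = _mi_ranking(data)
    hfc = np.array(
        [joint_entropy(data.codes[:, j], data.y) for j in range(data.n_features)]
    )
    return order, mi, hfc


def generate_subsets(
    data: DiscretizedMatrix, config: SelectorConfig | None = None
) -> list[FeatureSubset]:
    """P subsets from consecutive starting points t = 0 .. P-1."""
    config = config or SelectorConfig()
    if config.P > data.n_features:
        raise ValueError("more subsets requested than features available")
    cache = _selector_cache(data)
    return [fsncmi_select(data, t, config, _cache=cache) for t in range(config.P)]


def mrmr_select(
    data: DiscretizedMatrix, k: int, config: SelectorConfig | None = None
) -> FeatureSubset:
    """Greedy max-relevance min-redundancy baseline.

    Seeds with the max-MI feature, then repeatedly adds the candidate
    maximizing I(f;C) - mean_{fs in FS} I(f;fs).  Ties break toward the
    smaller feature index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order, mi = _mi_ranking(data)
    seed = int(order[0])
    selected = [seed]
    traj = [float(mi[seed])]
    candidates = np.ones(data.n_features, dtype=bool)
    candidates[seed] = False
    red_sum = np.zeros(data.n_features)
    while len(selected) < k:
        z = data.codes[:, selected[-1]]
        for j in np.flatnonzero(candidates):
            red_sum[j] += mutual_information(data.codes[:, j], z)
        idx = np.flatnonzero(candidates)
        if idx.size == 0:
            break
        score = mi[idx] - red_sum[idx] / len(selected)
        best = int(idx[np.argmax(score)])
        selected.append(best)
        traj.append(float(score[np.argmax(score)]))
        candidates[best] = False
    return FeatureSubset(
        feature_ids=[data.feature_ids[j] for j in selected],
        indices=selected,
        start=0,
        trajectory=traj,
        stopping_reason="k_reached" if len(selected) == k else "exhausted",
    )
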