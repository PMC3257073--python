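"""Independent brute-force oracles used to cross-check the estimators.

Everything here is written from the definitions using dict-based frequency
tables and explicit summation — deliberately sharing no code with the
implementation under test.
"""

from __future__ import annotations

import math
from collections import Counter


def entropy_oracle(xs) -> float:
    n = len(xs)
    return -sum((c / n) * math.log2(c / n) for c in Counter(xs).values())


def joint_entropy_oracle(xs, ys) -> float:
    return entropy_oracle(list(zip(xs, ys)))


def mi_oracle(xs, ys) -> float:
    """Direct summation of p(x,y) log2 [p(x,y) / (p(x) p(y))]."""
    n = len(xs)
    pxy = Counter(zip(xs, ys))
    px = Counter(xs)
    py = Counter(ys)
    total = 0.0
    for (x, y), c in pxy.items():
        p = c / n
        total += p * math.log2(p / ((px[x] / n) * (py[y] / n)))
    return total


def cmi_oracle(xs, ys, zs) -> float:
    """I(X;Y|Z) = sum_z p(z) * I(X;Y | Z=z), by explicit conditioning."""
    n = len(xs)
    total = 0.0
    for z, cz in Counter(zs).items():
        sub = [(x, y) for x, y, zz in zip(xs, ys, zs) if zz == z]
        total += (cz / n) * mi_oracle([a for a, _ in sub], [b for _, b in sub])
    return total


def criterion_oracle(f, FS, C) -> float:
    """min over fs in FS of I(f;C|fs) / H(f,C); 0 when H(f,C) = 0."""
    hfc = joint_entropy_oracle(f, C)
    if hfc == 0.0:
        return 0.0
    return min(cmi_oracle(f, C, fs) for fs in FS) / hfc


def fsncmi_oracle(columns, y, t, k, delta=0.0, epsilon=1e-12):
    """Exhaustive re-implementation of the greedy FSNCMI trace.

    ``columns`` is a list of code lists (one per feature).  Returns the
    list of selected feature indices.  The criterion of every candidate is
    recomputed from scratch (fresh min over the whole selected set) at
    every step, so any incremental-update bug in the implementation shows
    up as a trace mismatch.
    """
    d = len(columns)
    mi = [mi_oracle(col, y) for col in columns]
    ranking = sorted(range(d), key=lambda j: (-mi[j], j))
    seed = ranking[t]
    selected = [seed]
    remaining = [j for j in range(d) if j != seed]
    prev_j = None
    n_greedy = 0
    while len(selected) < k and remaining:
        scores = {}
        for j in list(remaining):
            val = criterion_oracle(columns[j], [columns[s] for s in selected], y)
            if val <= epsilon:
                remaining.remove(j)  # pruned for good
            else:
                scores[j] = val
        if not scores:
            break
        best = min(scores, key=lambda j: (-scores[j], j))
        n_greedy += 1
        if n_greedy >= 2 and abs(prev_j - scores[best]) < delta:
            break
        selected.append(best)
        prev_j = scores[best]
        remaining.remove(best)
    return selected


def mrmr_oracle(columns, y, k):
    """Greedy max-relevance min-redundancy trace; returns selected indices."""
    d = len(columns)
    mi = [mi_oracle(col, y) for col in columns]
    seed = min(range(d), key=lambda j: (-mi[j], j))
    selected = [seed]
    remaining = [j for j in range(d) if j != seed]
    while len(selected) < k and remaining:
        scores = {
            j: mi[j]
            - sum(mi_oracle(columns[j], columns[s]) for s in selected) / len(selected)
            for j in remaining
        }
        best = min(scores, key=lambda j: (-scores[j], j))
        selected.append(best)
        remaining.remove(best)
    return selected


def metrics_oracle(tp, tn, fp, fn):
    """Direct substitution into the confusion-table metric definitions."""
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    ac = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sn, sp, ac, mcc
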