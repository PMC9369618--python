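"""Independent brute-force oracles used only by the tests.

These deliberately re-derive the quantities from first principles (power-set
enumeration, exhaustive scans) so they share no code path with the package.
"""

from itertools import chain, combinations

import numpy as np


def _powerset(frame):
    items = list(frame)
    return [frozenset(s) for s in chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))]


def dempster_powerset(m1: dict, m2: dict) -> dict:
    """Dempster's rule over explicit focal-element sets (general, exponential)."""
    conflict = 0.0
    combined: dict[frozenset, float] = {}
    for a, wa in m1.items():
        for b, wb in m2.items():
            inter = a & b
            if inter:
                combined[inter] = combined.get(inter, 0.0) + wa * wb
            else:
                conflict += wa * wb
    if conflict >= 1.0:
        raise ZeroDivisionError("total conflict")
    return {s: w / (1.0 - conflict) for s, w in combined.items()}, conflict


def singleton_masses_to_focal(vec) -> dict:
    return {frozenset([i]): float(w) for i, w in enumerate(vec)}


def focal_to_singleton_vector(m: dict, c: int) -> np.ndarray:
    out = np.zeros(c)
    for s, w in m.items():
        assert len(s) == 1, "oracle produced a composite focal element from singleton inputs"
        out[next(iter(s))] = w
    return out


def ks_greedy_oracle(X: np.ndarray, n_train: int, start: tuple[int, int]) -> list[int]:
    """Exhaustive maximin selection: at each step scan every unselected
    candidate, compute its min distance to the selected set by brute force,
    and take the max (lowest index on ties)."""
    n = len(X)
    selected = list(start)
    while len(selected) < n_train:
        best, best_d = None, -1.0
        for cand in range(n):
            if cand in selected:
                continue
            d = min(float(np.linalg.norm(X[cand] - X[s])) for s in selected)
            if d > best_d + 1e-12:
                best, best_d = cand, d
        selected.append(best)
    return selected


def max_distance_pair(X: np.ndarray) -> tuple[int, int]:
    n = len(X)
    best, best_d = (0, 1), -1.0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(X[i] - X[j]))
            if d > best_d + 1e-12:
                best, best_d = (i, j), d
    return best
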