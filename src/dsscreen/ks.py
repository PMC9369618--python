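"""Kennard-Stone maximin train/test division with a repeated-split protocol.

The Kennard-Stone rule seeds the training set with the two mutually most
distant samples and then greedily adds the unselected sample whose minimum
Euclidean distance to the current training set is maximal, so the training
set spans the feature space and the test set probes its interior.

The rule itself is deterministic.  To obtain split-to-split variability for
the repeated statistical protocol, the ``random_start`` policy draws the seed
pair uniformly from the top decile of most-distant pairs; everything after
the seed pair is the plain deterministic greedy rule.  Distance ties are
broken by lowest row index, so any split is bit-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .featurize import FeatureMatrix


@dataclass(frozen=True)
class SplitResult:
    """One train/test partition; train ids are in selection order."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    repeat_index: int = 0
    seed: int | None = None
    seed_pair: tuple[str, str] = ("", "")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": list(self.train_ids),
                "test": list(self.test_ids),
                "train_fraction": self.train_fraction,
                "repeat_index": self.repeat_index,
                "seed": self.seed,
                "seed_pair": list(self.seed_pair),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        d = json.loads(text)
        return cls(
            train_ids=tuple(d["train"]),
            test_ids=tuple(d["test"]),
            train_fraction=d["train_fraction"],
            repeat_index=d["repeat_index"],
            seed=d["seed"],
            seed_pair=tuple(d["seed_pair"]),
        )


def _seed_pair_deterministic(dist: np.ndarray) -> tuple[int, int]:
    # first flat argmax = lexicographically smallest (i, j) among ties
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return (i, j) if i < j else (j, i)


def _seed_pair_random(dist: np.ndarray, seed: int) -> tuple[int, int]:
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    cutoff = np.quantile(d, 0.9)
    cand = np.flatnonzero(d >= cutoff)
    rng = np.random.default_rng(seed)
    k = int(cand[rng.integers(len(cand))])
    return int(iu[k]), int(ju[k])


def ks_split(
    fm: FeatureMatrix,
    fraction: float,
    policy: str = "deterministic",
    seed: int | None = None,
    repeat_index: int = 0,
) -> SplitResult:
    """Divide a standardized feature matrix by the Kennard-Stone rule.

    Parameters
    ----------
    fraction
        Training fraction in (0, 1); train size is round(fraction * n).
    policy
        ``"deterministic"`` seeds with the globally most distant pair;
        ``"random_start"`` draws the seed pair from the top-decile most
        distant pairs using `seed`.
    """
    n = fm.n
    if n < 4:
        raise ParameterError(f"Kennard-Stone division needs at least 4 samples, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"train fraction must lie in (0, 1), got {fraction}")
    n_train = int(np.floor(fraction * n + 0.5))
    if n_train < 2 or n - n_train < 1:
        raise ParameterError(
            f"fraction {fraction} on n={n} yields train={n_train}, test={n - n_train}; "
            "need train >= 2 and test >= 1"
        )

    X = fm.data.to_numpy(dtype=float)
    dist = squareform(pdist(X, metric="euclidean"))

    if policy == "deterministic":
        i, j = _seed_pair_deterministic(dist)
    elif policy == "random_start":
        if seed is None:
            raise ParameterError("random_start policy requires a seed")
        i, j = _seed_pair_random(dist, seed)
    else:
        raise ParameterError(f"unknown policy {policy!r}")

    selected = [i, j]
    in_train = np.zeros(n, dtype=bool)
    in_train[[i, j]] = True
    # min distance from every sample to the current training set
    mind = np.minimum(dist[:, i], dist[:, j])
    while len(selected) < n_train:
        mind_masked = np.where(in_train, -np.inf, mind)
        nxt = int(np.argmax(mind_masked))  # first max = lowest-index tie-break
        selected.append(nxt)
        in_train[nxt] = True
        mind = np.minimum(mind, dist[:, nxt])

    ids = fm.ids
    train_ids = tuple(ids[k] for k in selected)
    test_ids = tuple(ids[k] for k in range(n) if not in_train[k])
    return SplitResult(
        train_ids=train_ids,
        test_ids=test_ids,
        train_fraction=fraction,
        repeat_index=repeat_index,
        seed=seed,
        seed_pair=(ids[i], ids[j]),
    )


def repeat_splits(
    fm: FeatureMatrix, n_repeats: int = 100, fraction: float = 0.75, base_seed: int = 0
) -> list[SplitResult]:
    """Run `ks_split` with the random_start policy, seeding repeat i with
    base_seed + i; the whole list is reproducible from `base_seed`."""
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    return [
        ks_split(fm, fraction, policy="random_start", seed=base_seed + i, repeat_index=i)
        for i in range(n_repeats)
    ]


def write_split_manifest(splits: Sequence[SplitResult], path: str | Path) -> None:
    Path(path).write_text("[\n" + ",\n".join(s.to_json() for s in splits) + "\n]\n")
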