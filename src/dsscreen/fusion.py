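"""Dempster-Shafer evidence combination of classifier probability vectors.

Each classifier's predicted probability vector over the c therapeutic
classes is treated as a basic probability assignment (BPA) whose focal
elements are the singleton hypotheses of the discrimination frame: mass on
the empty set is identically zero and composite subsets carry no mass.  For
two such BPAs m1, m2, the conflict coefficient is the total product mass on
disjoint focal pairs,

    Kc = sum_{i != j} m1(i) m2(j) = 1 - sum_i m1(i) m2(i),

and Dempster's rule fuses them by the normalized elementwise product,

    (m1 (+) m2)(i) = m1(i) m2(i) / (1 - Kc).

Multiple evidences fold pairwise left to right; on singleton BPAs the rule
is commutative and associative, so the order does not matter unless the
high-conflict fallback fires.  When a pairwise step's Kc exceeds the
threshold (default 0.95) or equals 1, Dempster's rule is replaced for that
step by a pluggable fallback — by default the arithmetic mean of the two
masses, a conservative order-symmetric choice — and the result is flagged.
Hard zeros are floored at a tiny mass before combination so that calibrated
classifiers emitting exact 0s cannot manufacture spurious total conflict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifiers import KIND_BY_INDEX, ProbabilityMatrix
from .errors import ContractError, TotalConflictError

MASS_TOL = 1e-9


class MassVector:
    """Non-negative masses over the c singleton hypotheses, summing to 1."""

    __slots__ = ("masses",)

    def __init__(self, masses: Sequence[float] | np.ndarray):
        m = np.asarray(masses, dtype=float)
        if m.ndim != 1 or len(m) < 2:
            raise ContractError("a mass vector needs at least 2 singleton masses")
        if (m < -MASS_TOL).any():
            raise ContractError("mass vector contains negative mass")
        if abs(m.sum() - 1.0) > MASS_TOL:
            raise ContractError(f"mass vector sums to {m.sum():.12f}, not 1")
        self.masses = np.clip(m, 0.0, None)

    @property
    def c(self) -> int:
        return len(self.masses)

    def __len__(self) -> int:
        return len(self.masses)

    def __repr__(self) -> str:
        return f"MassVector({np.array2string(self.masses, precision=4)})"


@dataclass(frozen=True)
class CombinationResult:
    """A fused mass plus the largest pairwise conflict met along the fold."""

    fused: MassVector
    kc: float
    fallback_used: bool


def _mean_fallback(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    return 0.5 * (m1 + m2)


FALLBACKS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "mean": _mean_fallback,
}

_NAME_RE = re.compile(r"^DS([1-5]{2,5})$")


@dataclass(frozen=True)
class FusionSpec:
    """Which classifiers to fuse (by index) and how to handle high conflict.

    The canonical name concatenates the ascending classifier indices after
    "DS": DS12 fuses RF (1) and SVM (2), DS1235 fuses RF, SVM, LR and ABT.
    """

    indices: tuple[int, ...]
    threshold: float = 0.95
    fallback: str = "mean"
    floor: float = 1e-12

    def __post_init__(self) -> None:
        if len(self.indices) < 2:
            raise ContractError("a fusion spec needs at least 2 classifier indices")
        if len(set(self.indices)) != len(self.indices):
            raise ContractError("fusion indices must be unique")
        if list(self.indices) != sorted(self.indices):
            raise ContractError("fusion indices must be ascending")
        if not set(self.indices) <= set(KIND_BY_INDEX):
            raise ContractError(f"fusion indices must be within {sorted(KIND_BY_INDEX)}")
        if self.fallback not in FALLBACKS:
            raise ContractError(f"unknown fallback method {self.fallback!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ContractError("conflict threshold must lie in (0, 1]")

    @property
    def name(self) -> str:
        return "DS" + "".join(str(i) for i in self.indices)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(KIND_BY_INDEX[i] for i in self.indices)

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "FusionSpec":
        m = _NAME_RE.match(name)
        if m is None:
            raise ContractError(f"not a valid fusion-spec name: {name!r}")
        return cls(indices=tuple(int(d) for d in m.group(1)), **kwargs)


def conflict_coefficient(m1: MassVector, m2: MassVector) -> float:
    """Total product mass on disjoint focal-element pairs; 0 = no conflict."""
    if m1.c != m2.c:
        raise ContractError("mass vectors are over different frames")
    return float(np.clip(1.0 - float(m1.masses @ m2.masses), 0.0, 1.0))


def combine_pair(m1: MassVector, m2: MassVector) -> CombinationResult:
    """Dempster's rule for two singleton BPAs; raises on total conflict."""
    kc = conflict_coefficient(m1, m2)
    if kc >= 1.0 - 1e-15:
        raise TotalConflictError(
            "the two evidences are in total conflict (Kc = 1); use the fallback path"
        )
    fused = m1.masses * m2.masses / (1.0 - kc)
    return CombinationResult(MassVector(fused / fused.sum()), kc, fallback_used=False)


def _floored(m: MassVector, floor: float) -> np.ndarray:
    if floor <= 0:
        return m.masses
    v = np.maximum(m.masses, floor)
    return v / v.sum()


def combine_evidences(masses: Sequence[MassVector], spec: FusionSpec) -> CombinationResult:
    """Left-fold of Dempster's rule over the evidence list, with the
    high-conflict fallback applied at any pairwise step whose Kc exceeds
    the spec threshold; the reported kc is the largest step conflict."""
    if len(masses) != len(spec.indices):
        raise ContractError(
            f"{spec.name} expects {len(spec.indices)} evidences, got {len(masses)}"
        )
    fallback = FALLBACKS[spec.fallback]
    acc = _floored(masses[0], spec.floor)
    max_kc = 0.0
    used_fallback = False
    for m in masses[1:]:
        nxt = _floored(m, spec.floor)
        kc = float(np.clip(1.0 - float(acc @ nxt), 0.0, 1.0))
        max_kc = max(max_kc, kc)
        if kc > spec.threshold or kc >= 1.0 - 1e-15:
            acc = fallback(acc, nxt)
            acc = acc / acc.sum()
            used_fallback = True
        else:
            acc = acc * nxt / (1.0 - kc)
            acc = acc / acc.sum()
    return CombinationResult(MassVector(acc), max_kc, used_fallback)


def fuse_predictions(
    spec: FusionSpec, per_classifier: Sequence[ProbabilityMatrix]
) -> ProbabilityMatrix:
    """Row-wise evidence combination of aligned probability matrices.

    The matrices must share ids in the same order, one matrix per fusion
    index.  The returned matrix carries a per-row companion report (kc and
    fallback flag) in its ``report`` attribute.
    """
    if len(per_classifier) != len(spec.indices):
        raise ContractError(f"{spec.name} needs {len(spec.indices)} probability matrices")
    ids = per_classifier[0].ids
    cols = list(per_classifier[0].data.columns)
    for pm in per_classifier[1:]:
        if pm.ids != ids or list(pm.data.columns) != cols:
            raise ContractError("probability matrices are not row/column aligned")

    arrays = [pm.data.to_numpy(dtype=float) for pm in per_classifier]
    fused_rows = np.empty_like(arrays[0])
    kcs = np.empty(len(ids))
    flags = np.empty(len(ids), dtype=bool)
    for r in range(len(ids)):
        res = combine_evidences([MassVector(a[r]) for a in arrays], spec)
        fused_rows[r] = res.fused.masses
        kcs[r] = res.kc
        flags[r] = res.fallback_used
    report = pd.DataFrame({"kc": kcs, "fallback_used": flags}, index=ids)
    df = pd.DataFrame(fused_rows, index=ids, columns=cols)
    return ProbabilityMatrix(df, classifier_index=0, report=report)
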