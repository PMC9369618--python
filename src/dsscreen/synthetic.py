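"""Synthetic datasets with the statistical structure the pipeline assumes.

Real drug-category data has three properties the method must cope with:
uneven class sizes (the default sizes 228/211/296/108/64/70/42 mirror the
shape of a curated seven-class drug collection), real-valued descriptor
blocks with class-dependent location shifts, and binary fingerprint blocks
with class-dependent bit rates.  The generators here reproduce exactly
those properties — and nothing else of real chemistry — so every pipeline
stage can be exercised without a download and with a known ground truth.

`make_complementary_predictors` skips featurization entirely: it emits two
synthetic classifier probability matrices with controlled argmax accuracies
and a controlled overlap between their error sets, the minimal scenario in
which evidence fusion of two complementary classifiers should beat either
one alone.

`make_toy_smiles_set` returns a small packaged fixture of well-known,
license-free drug SMILES with synthetic class labels and curation flags
(synthetic in the sense that flags and some role assignments are assigned
for testing, not curated from literature), for end-to-end smoke tests; it
includes multi-role records, a two-fragment salt and a deliberately
oversized molecule so the curation rules all fire.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ProbabilityMatrix
from .errors import ParameterError
from .featurize import FeatureMatrix
from .molecules import DEFAULT_CLASSES, ClassFrame, MoleculeRecord

#: Class-size shape of the full curated seven-class drug collection.
DEFAULT_CLASS_SIZES = (228, 211, 296, 108, 64, 70, 42)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generators; defaults are the study conditions.

    separation is the between-class mean shift in within-class-sd units on
    a class's own coordinates; bit_contrast is the Bernoulli-rate offset on
    a class's informative bits over the background rate p_base.
    """

    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    n_real_features: int = 50
    n_binary_features: int = 512
    separation: float = 3.0
    bit_contrast: float = 0.25
    p_base: float = 0.2
    informative_bits_per_class: int = 64
    multi_role_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.class_sizes):
            raise ParameterError("class sizes must be non-negative")
        if self.separation < 0:
            raise ParameterError("separation must be non-negative")
        if not 0.0 < self.p_base < 1.0:
            raise ParameterError("p_base must lie in (0, 1)")

    def scaled(self, factor: float) -> "SyntheticConfig":
        """Shrink/grow every class size by `factor` (rounded, floor 2)."""
        sizes = tuple(max(2, int(round(s * factor))) for s in self.class_sizes)
        return replace(self, class_sizes=sizes)

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    def frame(self) -> ClassFrame:
        if self.n_classes <= len(DEFAULT_CLASSES):
            return ClassFrame(DEFAULT_CLASSES[: self.n_classes])
        return ClassFrame(tuple(f"class{i+1}" for i in range(self.n_classes)))


def _ids_and_labels(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    labels: list[str] = []
    frame = cfg.frame()
    for k, size in enumerate(cfg.class_sizes):
        labels.extend([frame.labels[k]] * size)
    ids = [f"mol{i:05d}" for i in range(len(labels))]
    return ids, labels


def make_gaussian_dataset(cfg: SyntheticConfig) -> tuple[FeatureMatrix, list[str]]:
    """Spherical-Gaussian classes emulating a real-valued descriptor block.

    Class k's mean puts `separation` on the coordinates congruent to k
    modulo the class count and 0 elsewhere; within-class variance is 1.
    """
    if cfg.n_real_features < 1:
        raise ParameterError("need at least one real feature")
    if sum(cfg.class_sizes) == 0:
        raise ParameterError("all class sizes are zero")
    rng = np.random.default_rng(cfg.seed)
    ids, labels = _ids_and_labels(cfg)
    c = cfg.n_classes
    X = rng.standard_normal((len(ids), cfg.n_real_features))
    row = 0
    for k, size in enumerate(cfg.class_sizes):
        mu = np.zeros(cfg.n_real_features)
        mu[np.arange(cfg.n_real_features) % c == k] = cfg.separation
        X[row : row + size] += mu
        row += size
    df = pd.DataFrame(X, index=ids, columns=[f"desc_{j}" for j in range(cfg.n_real_features)])
    return FeatureMatrix(df, "F2_descriptors"), labels


def make_fingerprint_dataset(cfg: SyntheticConfig) -> tuple[FeatureMatrix, list[str]]:
    """Bernoulli bit matrix emulating a binary fingerprint family.

    Each class owns a contiguous block of `informative_bits_per_class` bits
    whose on-rate is p_base + bit_contrast; every other bit fires at p_base.
    """
    if cfg.n_binary_features < 1:
        raise ParameterError("need at least one binary feature")
    if sum(cfg.class_sizes) == 0:
        raise ParameterError("all class sizes are zero")
    if cfg.informative_bits_per_class * cfg.n_classes > cfg.n_binary_features:
        raise ParameterError("informative bit blocks exceed the fingerprint width")
    rng = np.random.default_rng(cfg.seed)
    ids, labels = _ids_and_labels(cfg)
    p_hi = float(np.clip(cfg.p_base + cfg.bit_contrast, 0.01, 0.99))
    P = np.full((len(ids), cfg.n_binary_features), cfg.p_base)
    row = 0
    for k, size in enumerate(cfg.class_sizes):
        lo = k * cfg.informative_bits_per_class
        P[row : row + size, lo : lo + cfg.informative_bits_per_class] = p_hi
        row += size
    X = (rng.random(P.shape) < P).astype(np.int8)
    df = pd.DataFrame(X, index=ids, columns=[f"bit_{j}" for j in range(cfg.n_binary_features)])
    return FeatureMatrix(df, "F5_morgan"), labels


def make_complementary_predictors(
    labels: Sequence[str],
    acc_a: float,
    acc_b: float,
    error_overlap: float,
    sharpness: float = 6.0,
    seed: int = 0,
    frame: ClassFrame | None = None,
) -> tuple[ProbabilityMatrix, ProbabilityMatrix]:
    """Two synthetic probability matrices with controlled complementarity.

    error_overlap is P(B errs | A errs); B's unconditional error rate stays
    1 - acc_b, so the pair (acc, overlap) must be jointly feasible.  Rows
    are softmax-sharpened one-hot-plus-noise vectors; an erring predictor
    keeps the true class as a strong runner-up, the behaviour that lets
    product-style fusion recover the truth when the other predictor is
    confidently right.
    """
    if frame is None:
        frame = ClassFrame(tuple(dict.fromkeys(labels)))
    c = frame.c
    for acc in (acc_a, acc_b):
        if not 1.0 / c < acc < 1.0:
            raise ParameterError(f"accuracy {acc} must lie in (1/c, 1)")
    if not 0.0 <= error_overlap <= 1.0:
        raise ParameterError("error_overlap must lie in [0, 1]")
    p_b_err_given_a_ok = ((1 - acc_b) - (1 - acc_a) * error_overlap) / acc_a
    if not -1e-12 <= p_b_err_given_a_ok <= 1.0:
        raise ParameterError(
            f"(acc_a={acc_a}, acc_b={acc_b}, overlap={error_overlap}) is infeasible"
        )
    p_b_err_given_a_ok = max(0.0, p_b_err_given_a_ok)

    rng = np.random.default_rng(seed)
    ids = [f"s{i:05d}" for i in range(len(labels))]

    def _row(true_idx: int, errs: bool) -> np.ndarray:
        if errs:
            target = int(rng.integers(c - 1))
            target += target >= true_idx  # uniform over wrong classes
        else:
            target = true_idx
        v = rng.normal(0.0, 0.25, size=c)
        v[target] += 1.0
        if target != true_idx:
            v[true_idx] += 0.5  # truth stays the runner-up
        e = np.exp(sharpness * (v - v.max()))
        return e / e.sum()

    rows_a, rows_b = [], []
    for lab in labels:
        t = frame.index_of(lab)
        a_errs = rng.random() < (1 - acc_a)
        b_errs = rng.random() < (error_overlap if a_errs else p_b_err_given_a_ok)
        rows_a.append(_row(t, a_errs))
        rows_b.append(_row(t, b_errs))
    cols = list(frame.labels)
    pa = ProbabilityMatrix(pd.DataFrame(rows_a, index=ids, columns=cols), classifier_index=1)
    pb = ProbabilityMatrix(pd.DataFrame(rows_b, index=ids, columns=cols), classifier_index=2)
    return pa, pb


# ---------------------------------------------------------------------------
# Toy SMILES fixture.  Well-known small-molecule drugs with valid SMILES;
# class labels are their textbook primary uses, while curation flags and the
# synthetic extras (oversized chain, salt) are assigned purely for testing.

_TOY_SINGLE: dict[str, list[tuple[str, str, str]]] = {
    # class -> [(id, name, smiles), ...]; within-class order = fixture order
    "analgesic": [
        ("an01", "aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
        ("an02", "paracetamol", "CC(=O)Nc1ccc(O)cc1"),
        ("an03", "ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
        ("an04", "naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ],
    "antineoplastic": [
        ("np01", "fluorouracil", "O=c1[nH]cc(F)c(=O)[nH]1"),
        ("np02", "chlorambucil", "O=C(O)CCCc1ccc(N(CCCl)CCCl)cc1"),
        ("np03", "cyclophosphamide", "O=P1(N(CCCl)CCCl)NCCCO1"),
        ("np04", "hydroxyurea", "NC(=O)NO"),
    ],
    "antibacterial": [
        ("ab01", "trimethoprim", "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC"),
        ("ab02", "metronidazole", "Cc1ncc([N+](=O)[O-])n1CCO"),
        ("ab03", "sulfanilamide", "Nc1ccc(S(N)(=O)=O)cc1"),
        ("ab04", "isoniazid", "NNC(=O)c1ccncc1"),
    ],
    "antiviral": [
        ("av01", "aciclovir", "Nc1nc2c(ncn2COCCO)c(=O)[nH]1"),
        ("av02", "amantadine", "NC12CC3CC(CC(C3)C1)C2"),
        ("av03", "zidovudine", "Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O"),
        ("av04", "rimantadine", "CC(N)C12CC3CC(CC(C3)C1)C2"),
    ],
    "antifungal": [
        ("af01", "fluconazole", "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F"),
        ("af02", "flucytosine", "Nc1nc(=O)[nH]cc1F"),
        ("af03", "clotrimazole", "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1"),
        ("af04", "terbinafine", "CC(C)(C)C#CC=CCN(C)Cc1cccc2ccccc12"),
    ],
    "antidiabetic": [
        ("ad01", "metformin", "CN(C)C(=N)NC(=N)N"),
        ("ad02", "tolbutamide", "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1"),
        ("ad03", "phenformin", "N=C(N)NC(=N)NCCc1ccccc1"),
        ("ad04", "chlorpropamide", "CCCNC(=O)NS(=O)(=O)c1ccc(Cl)cc1"),
    ],
    "antiarrhythmic": [
        ("ar01", "lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
        ("ar02", "procainamide", "CCN(CC)CCNC(=O)c1ccc(N)cc1"),
        ("ar03", "mexiletine", "CC(N)COc1c(C)cccc1C"),
        ("ar04", "tocainide", "CC(N)C(=O)Nc1c(C)cccc1C"),
    ],
}

#: flags assigned for tier testing only (not literature curation)
_TOY_FLAGS: dict[str, str] = {
    "an04": "adjuvant_or_healthcare",
    "np04": "adjuvant_or_healthcare",
    "ab04": "potential_other_use",
    "av04": "potential_other_use",
    "af04": "no_mechanism_or_veterinary_or_trial",
}

_TOY_EXTRAS: list[MoleculeRecord] = [
    MoleculeRecord(
        id="mr01",
        name="celecoxib",
        smiles="Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
        roles=("analgesic", "antineoplastic", "antiviral"),
        source="toy fixture (multi-role)",
    ),
    MoleculeRecord(
        id="mr02",
        name="thalidomide",
        smiles="O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1",
        roles=("antineoplastic", "analgesic"),
        source="toy fixture (multi-role)",
    ),
    MoleculeRecord(
        id="xx01",
        name="synthetic-macro-chain",  # synthetic: C130 alkane, mass > 1800, trips the mass rule
        smiles="C" * 130,
        roles=("analgesic",),
        source="toy fixture (synthetic oversized)",
    ),
    MoleculeRecord(
        id="xx02",
        name="aspirin sodium salt",  # two fragments, trips the multi-fragment rule
        smiles="CC(=O)Oc1ccccc1C(=O)[O-].[Na+]",
        roles=("analgesic",),
        source="toy fixture (salt)",
    ),
]


def make_toy_smiles_set(n_per_class: int = 4) -> list[MoleculeRecord]:
    """The packaged toy fixture: `n_per_class` single-role drugs per class
    (max 4) plus the fixed extras (two multi-role drugs, one oversized
    synthetic chain, one salt)."""
    max_n = min(len(v) for v in _TOY_SINGLE.values())
    if not 1 <= n_per_class <= max_n:
        raise ParameterError(f"n_per_class must lie in [1, {max_n}]")
    records: list[MoleculeRecord] = []
    for cls, entries in _TOY_SINGLE.items():
        for mid, name, smi in entries[:n_per_class]:
            flags = frozenset({_TOY_FLAGS[mid]}) if mid in _TOY_FLAGS else frozenset()
            records.append(
                MoleculeRecord(
                    id=mid, name=name, smiles=smi, roles=(cls,), flags=flags, source="toy fixture"
                )
            )
    records.extend(_TOY_EXTRAS)
    return records
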