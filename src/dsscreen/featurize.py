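"""Five descriptor/fingerprint families computed from SMILES.

Two families are real-valued descriptor blocks and three are binary
fingerprints:

* ``F1_combinatorial`` — RDKit's scalar 2-D descriptor block merged with the
  42 molecular quantum numbers (MQN) and the 192 2-D autocorrelation
  descriptors, de-duplicated by name; a combinatorial block mixing counts,
  constitutional, topological and autocorrelation information.
* ``F2_descriptors`` — RDKit's scalar 2-D descriptor block alone, the large
  automatically generated descriptor set; columns with missing values are
  dropped later by `clean_features`, so the surviving count is data-dependent.
* ``F3_maccs`` — the 167 MACCS structural keys.
* ``F4_topological`` — the RDKit path-based (Daylight-like) topological
  fingerprint, hashed to ``n_bits`` (default 2048).
* ``F5_morgan`` — circular Morgan fingerprints with radius 4 hashed to
  ``n_bits`` (default 1024).

All families flow through the same cleaning (drop any column with a missing
value, drop zero-variance columns) and z-score standardization, so binary
fingerprints enter distance computations on the same footing as real
descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from .errors import (
    ContractError,
    DegenerateMatrixError,
    FeaturizationError,
    SchemaError,
)
from .molecules import MoleculeRecord

log = logging.getLogger(__name__)

FAMILY_KEYS = ("F1_combinatorial", "F2_descriptors", "F3_maccs", "F4_topological", "F5_morgan")
BINARY_FAMILIES = frozenset({"F3_maccs", "F4_topological", "F5_morgan"})

_DEFAULT_BITS = {"F4_topological": 2048, "F5_morgan": 1024}


@dataclass(frozen=True)
class DescriptorFamily:
    """One of the five families, with its hashing parameters fixed per run."""

    key: str
    radius: int = 4          # Morgan circle radius
    n_bits: int | None = None  # hashed-fingerprint width; family default if None

    def __post_init__(self) -> None:
        if self.key not in FAMILY_KEYS:
            raise ContractError(f"unknown descriptor family {self.key!r}")
        if self.n_bits is None:
            object.__setattr__(self, "n_bits", _DEFAULT_BITS.get(self.key))

    @property
    def is_binary(self) -> bool:
        return self.key in BINARY_FAMILIES


@dataclass
class FeatureMatrix:
    """Molecules × named features for one family; index is the molecule id."""

    data: pd.DataFrame
    family: str

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ContractError("feature matrix row ids must be unique")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(ids)], self.family)


@dataclass(frozen=True)
class ScalingStats:
    """Per-column mean/sd fitted on one set of rows, reusable on another."""

    mean: pd.Series
    sd: pd.Series
    fitted_on: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            raise ContractError("scaling stats contain a non-positive standard deviation")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"mean": self.mean.to_dict(), "sd": self.sd.to_dict(), "fitted_on": list(self.fitted_on)}
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingStats":
        import json

        d = json.loads(text)
        return cls(
            mean=pd.Series(d["mean"]), sd=pd.Series(d["sd"]), fitted_on=tuple(d["fitted_on"])
        )


def _parse_all(records: Sequence[MoleculeRecord]) -> list[Chem.Mol]:
    mols, bad = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            bad.append(rec.id)
        mols.append(mol)
    if bad:
        raise FeaturizationError(bad)
    return mols


def _scalar_block(mol: Chem.Mol) -> dict[str, float]:
    return Descriptors.CalcMolDescriptors(mol)


def _combinatorial_block(mol: Chem.Mol) -> dict[str, float]:
    block = _scalar_block(mol)
    extra: dict[str, float] = {}
    for i, v in enumerate(rdMolDescriptors.MQNs_(mol), start=1):
        extra[f"MQN{i:02d}"] = float(v)
    for i, v in enumerate(rdMolDescriptors.CalcAUTOCORR2D(mol), start=1):
        extra[f"AUTOCORR2D_{i}"] = float(v)
    # name-based de-duplication: the scalar block wins on a collision
    for k, v in extra.items():
        block.setdefault(k, v)
    return block


def featurize(records: Sequence[MoleculeRecord], family: DescriptorFamily) -> FeatureMatrix:
    """Compute one family's feature matrix, one row per record.

    Raises `FeaturizationError` naming every unparseable record; it never
    silently drops a molecule (curation is the place where molecules vanish).
    """
    mols = _parse_all(records)
    ids = [r.id for r in records]

    if family.key in ("F1_combinatorial", "F2_descriptors"):
        fn = _combinatorial_block if family.key == "F1_combinatorial" else _scalar_block
        rows = [fn(m) for m in mols]
        df = pd.DataFrame(rows, index=ids, dtype=float)
    elif family.key == "F3_maccs":
        arrs = [np.array(MACCSkeys.GenMACCSKeys(m), dtype=np.int8) for m in mols]
        df = pd.DataFrame(arrs, index=ids, columns=[f"MACCS_{i}" for i in range(167)])
    elif family.key == "F4_topological":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=family.n_bits)
        arrs = [np.array(gen.GetFingerprint(m), dtype=np.int8) for m in mols]
        df = pd.DataFrame(arrs, index=ids, columns=[f"TOPO_{i}" for i in range(family.n_bits)])
    elif family.key == "F5_morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=family.radius, fpSize=family.n_bits)
        arrs = [np.array(gen.GetFingerprint(m), dtype=np.int8) for m in mols]
        df = pd.DataFrame(arrs, index=ids, columns=[f"MORGAN_{i}" for i in range(family.n_bits)])
    else:  # pragma: no cover - guarded by DescriptorFamily
        raise ContractError(family.key)

    return FeatureMatrix(df, family.key)


def clean_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Drop columns with any missing/non-finite value, then zero-variance columns."""
    df = fm.data
    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=0)
    dropped_missing = list(df.columns[~finite])
    df = df.loc[:, finite]
    variable = df.nunique(axis=0) > 1
    dropped_constant = list(df.columns[~variable])
    df = df.loc[:, variable.to_numpy()]
    if dropped_missing:
        log.info("clean_features[%s]: dropped %d column(s) with missing values: %s",
                 fm.family, len(dropped_missing), dropped_missing[:10])
    if dropped_constant:
        log.info("clean_features[%s]: dropped %d constant column(s)", fm.family, len(dropped_constant))
    if df.shape[1] == 0:
        raise DegenerateMatrixError(f"all columns of family {fm.family} were dropped")
    return FeatureMatrix(df, fm.family)


def standardize(
    fm: FeatureMatrix, stats: ScalingStats | None = None
) -> tuple[FeatureMatrix, ScalingStats]:
    """Z-score the matrix; fit on `fm` when `stats` is None, else apply as-is.

    Applying train-fitted stats to a test matrix deliberately does not refit,
    so test columns need not come out centred.
    """
    df = fm.data.astype(float)
    if stats is None:
        if len(df) < 2:
            raise ContractError("cannot fit scaling statistics on fewer than 2 rows")
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=0)
        if (sd <= 0).any():
            bad = list(sd.index[sd <= 0])
            raise ContractError(f"zero-variance column(s) reached standardize: {bad[:5]} (run clean_features first)")
        stats = ScalingStats(mean=mean, sd=sd, fitted_on=tuple(fm.ids))
    else:
        missing = [c for c in stats.mean.index if c not in df.columns]
        if missing:
            raise SchemaError(f"matrix lacks column(s) required by scaling stats: {missing[:5]}")
        df = df[list(stats.mean.index)]
    out = (df - stats.mean) / stats.sd
    return FeatureMatrix(out, fm.family), stats
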