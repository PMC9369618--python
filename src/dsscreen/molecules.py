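"""Molecule tables, curation rules and tiered molecular sets.

A drug molecule enters the pipeline as a row of a CSV/TSV table (id, name,
SMILES, one-to-three therapeutic roles, optional curation flags).  Curation
removes structures a descriptor pipeline cannot use — unparseable SMILES,
multi-fragment entries (salts, mixtures), molecules above a molar-mass limit,
structural duplicates and, optionally, stereoisomer pairs.  The surviving
single-role molecules are organised into four nested tiers S1 ⊇ S2 ⊇ S3 ⊇ S4
of increasing curation strictness, driven by per-record annotation flags;
multi-role molecules are set aside for external validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import Descriptors

from .errors import ContractError, SchemaError, ValidationError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Default therapeutic classes, indexed C1..C7 in this fixed order.
DEFAULT_CLASSES: tuple[str, ...] = (
    "analgesic",
    "antineoplastic",
    "antibacterial",
    "antiviral",
    "antifungal",
    "antidiabetic",
    "antiarrhythmic",
)

#: Curation-annotation flags used to peel tiers S2..S4 off S1.
KNOWN_FLAGS: frozenset[str] = frozenset(
    {"adjuvant_or_healthcare", "potential_other_use", "no_mechanism_or_veterinary_or_trial"}
)

TIER_NAMES = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class ClassFrame:
    """The discrimination frame: the exhaustive, ordered set of class labels.

    Every probability vector and mass vector in the pipeline is indexed in
    this order, so the frame is created once per run and threaded through.
    """

    labels: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("class labels must be unique")
        if len(self.labels) < 2:
            raise ValidationError("a discrimination frame needs at least 2 classes")

    @property
    def c(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown class label {label!r}") from None


@dataclass(frozen=True)
class MoleculeRecord:
    """One drug molecule: identifier, structure, therapeutic role(s), flags."""

    id: str
    name: str
    smiles: str
    roles: tuple[str, ...]
    flags: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValidationError(f"record {self.id!r} has an empty SMILES")
        if not self.roles:
            raise ValidationError(f"record {self.id!r} has no therapeutic role")

    @property
    def is_multi_role(self) -> bool:
        return len(self.roles) >= 2


@dataclass(frozen=True)
class CurationReport:
    """Per-rule removal tallies; kept + removals always sums to the input size."""

    input_count: int
    kept: int
    parse_failure: int = 0
    multi_fragment: int = 0
    mass_over_limit: int = 0
    duplicate_structure: int = 0
    isomer_pair: int = 0

    @property
    def removals(self) -> dict[str, int]:
        return {
            "parse_failure": self.parse_failure,
            "multi_fragment": self.multi_fragment,
            "mass_over_limit": self.mass_over_limit,
            "duplicate_structure": self.duplicate_structure,
            "isomer_pair": self.isomer_pair,
        }

    def __post_init__(self) -> None:
        if self.kept + sum(self.removals.values()) != self.input_count:
            raise ContractError("curation report counts do not sum to the input size")

    def to_json(self) -> str:
        return json.dumps({"input": self.input_count, "kept": self.kept, **self.removals})


@dataclass(frozen=True)
class CurationConfig:
    """Knobs for `curate`; the mass limit defaults to 1800 g/mol."""

    mass_limit: float = 1800.0
    remove_isomer_pairs: bool = False


@dataclass(frozen=True)
class TieredSets:
    """The four nested molecular tiers, S4 ⊆ S3 ⊆ S2 ⊆ S1, all single-role."""

    tiers: Mapping[str, tuple[MoleculeRecord, ...]]

    def __post_init__(self) -> None:
        ids = {t: {r.id for r in self.tiers[t]} for t in TIER_NAMES}
        for inner, outer in zip(TIER_NAMES[1:], TIER_NAMES[:-1]):
            if not ids[inner] <= ids[outer]:
                raise ContractError(f"tier {inner} is not a subset of {outer}")

    def __getitem__(self, tier: str) -> tuple[MoleculeRecord, ...]:
        return self.tiers[tier]

    def sizes(self) -> dict[str, int]:
        return {t: len(self.tiers[t]) for t in TIER_NAMES}


# ---------------------------------------------------------------------------
# Reading

_REQUIRED_COLUMNS = ("id", "name", "smiles", "roles")


def read_molecule_table(path: str | Path, frame: ClassFrame) -> list[MoleculeRecord]:
    """Read a CSV/TSV molecule table into records, validating roles and flags.

    The delimiter is inferred from the extension (``.tsv``/``.tab`` → tab,
    anything else → comma).  `roles` and `flags` cells hold semicolon-separated
    lists; unknown class labels or flags raise with the offending row number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"molecule table {path} is missing column(s): {', '.join(missing)}")

    records: list[MoleculeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        roles = tuple(r.strip() for r in str(getattr(row, "roles")).split(";") if r.strip())
        for role in roles:
            if role not in frame.labels:
                raise ValidationError(f"row {i}: unknown class label {role!r}")
        raw_flags = str(getattr(row, "flags", "")) if "flags" in df.columns else ""
        flags = frozenset(f.strip() for f in raw_flags.split(";") if f.strip())
        unknown = flags - KNOWN_FLAGS
        if unknown:
            raise ValidationError(f"row {i}: unknown flag(s) {sorted(unknown)}")
        records.append(
            MoleculeRecord(
                id=str(getattr(row, "id")),
                name=str(getattr(row, "name")),
                smiles=str(getattr(row, "smiles")),
                roles=roles,
                flags=flags,
                source=str(getattr(row, "source", "")) if "source" in df.columns else "",
            )
        )
    return records


def read_sdf_structures(path: str | Path) -> dict[str, str]:
    """Read an SDF file into a {title: canonical SMILES} map.

    The molecule title (first line of each block) is used as the record id;
    therapeutic roles and flags still come from the molecule table, so this
    is a structure supplement, not a standalone input.  Unparseable blocks
    are skipped with a log entry; untitled blocks get a positional id.
    """
    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.info("read_sdf_structures: skipping unparseable block %d", i)
            continue
        title = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip() or f"sdf{i}"
        out[title] = Chem.MolToSmiles(mol)
    return out


def write_molecule_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records back out in the same CSV schema `read_molecule_table` reads."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles for r in records],
            "roles": [";".join(r.roles) for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Curation


def _canonical(mol: Chem.Mol, stereo: bool = True) -> str:
    return Chem.MolToSmiles(mol, isomericSmiles=stereo)


def curate(
    records: Sequence[MoleculeRecord], config: CurationConfig | None = None
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the structural curation rules in order; problem molecules are
    removed and counted, never raised.

    Order: unparseable SMILES → multi-fragment structures (salts/mixtures)
    → molar mass above ``config.mass_limit`` → duplicate canonical structures
    (first occurrence kept) → optionally stereoisomer pairs (records whose
    stereo-stripped canonical form collides while their stereo forms differ;
    the whole colliding group is removed).
    """
    config = config or CurationConfig()
    counts = {k: 0 for k in ("parse_failure", "multi_fragment", "mass_over_limit", "duplicate_structure", "isomer_pair")}

    stage: list[tuple[MoleculeRecord, Chem.Mol]] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            counts["parse_failure"] += 1
            log.info("curate: %s removed (unparseable SMILES)", rec.id)
            continue
        stage.append((rec, mol))

    stage2 = []
    for rec, mol in stage:
        if len(Chem.GetMolFrags(mol)) > 1:
            counts["multi_fragment"] += 1
            log.info("curate: %s removed (multi-fragment structure)", rec.id)
            continue
        stage2.append((rec, mol))

    stage3 = []
    for rec, mol in stage2:
        if Descriptors.MolWt(mol) > config.mass_limit:
            counts["mass_over_limit"] += 1
            log.info("curate: %s removed (molar mass > %g)", rec.id, config.mass_limit)
            continue
        stage3.append((rec, mol))

    seen: set[str] = set()
    stage4 = []
    for rec, mol in stage3:
        canon = _canonical(mol)
        if canon in seen:
            counts["duplicate_structure"] += 1
            log.info("curate: %s removed (duplicate structure)", rec.id)
            continue
        seen.add(canon)
        stage4.append((rec, mol, canon))

    if config.remove_isomer_pairs:
        groups: dict[str, list[int]] = {}
        for idx, (_, mol, _) in enumerate(stage4):
            groups.setdefault(_canonical(mol, stereo=False), []).append(idx)
        drop = set()
        for members in groups.values():
            if len(members) >= 2:  # same skeleton, different stereo forms
                drop.update(members)
        counts["isomer_pair"] = len(drop)
        stage4 = [t for i, t in enumerate(stage4) if i not in drop]

    kept = [rec for rec, _, _ in stage4]
    report = CurationReport(input_count=len(records), kept=len(kept), **counts)
    return kept, report


# ---------------------------------------------------------------------------
# Tiers and validation split


def assemble_tiers(records: Sequence[MoleculeRecord]) -> TieredSets:
    """Build the nested tiers by peeling off flagged records.

    S1 is everything; S2 drops adjuvant/healthcare-only entries; S3 further
    drops drugs whose class may be a side use; S4 further drops drugs without
    a known mechanism, veterinary-only drugs and trial-phase drugs.
    """
    for rec in records:
        if rec.is_multi_role:
            raise ContractError(f"multi-role record {rec.id!r} cannot enter the tiered sets")
    s1 = tuple(records)
    s2 = tuple(r for r in s1 if "adjuvant_or_healthcare" not in r.flags)
    s3 = tuple(r for r in s2 if "potential_other_use" not in r.flags)
    s4 = tuple(r for r in s3 if "no_mechanism_or_veterinary_or_trial" not in r.flags)
    return TieredSets(tiers={"S1": s1, "S2": s2, "S3": s3, "S4": s4})


def split_validation(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Partition curated records into (single-role, multi-role), order preserved.

    Multi-role drugs — molecules with two or three recognised therapeutic
    uses — are never trained on; they form the external validation pool.
    """
    single = [r for r in records if not r.is_multi_role]
    multi = [r for r in records if r.is_multi_role]
    return single, multi
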