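"""Compound parsing and molecular descriptor calculation.

The QEA model scores molecules on six physicochemical descriptors:
molecular weight (MW), Wildman-Crippen logP, hydrogen-bond acceptor and
donor counts (HBA/HBD, N/O topological rules), rotatable bond count
(nRotB, non-ring single bonds between non-terminal heavy atoms, amide
C-N excluded) and aromatic ring count (nArR).  All six come from RDKit
and the exact rule-set identifiers are recorded so a fitted profile is
never applied with mismatched descriptor conventions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: Identifiers of the descriptor rule sets in use.  Stored inside every
#: fitted profile; scoring refuses a profile fitted under different rules.
DESCRIPTOR_CONVENTIONS = {
    "mw": "rdkit-average-molwt",
    "logp": "wildman-crippen",
    "hba": "lipinski-n-o-acceptors",
    "hbd": "lipinski-nh-oh-donors",
    "nrotb": "rdkit-strict-no-amide",
    "narr": "rdkit-aromatic-rings",
    "fragment": "largest-heavy-atom-fragment",
}

DESCRIPTOR_NAMES = ("mw", "logp", "hba", "hbd", "nrotb", "narr")


@dataclass
class CompoundRecord:
    """One input molecule with its parse status."""

    id: str
    smiles: str
    valid: bool = True
    failure_reason: str | None = None
    fragment_smiles: str | None = None  # largest fragment actually scored


@dataclass(frozen=True)
class DescriptorVector:
    """The six per-molecule property values of the QEA model."""

    mw: float
    logp: float
    hba: int
    hbd: int
    nrotb: int
    narr: int

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


class SchemaError(ValueError):
    """Input file exists but lacks the required structure."""


def _dedupe_ids(records: list[CompoundRecord]) -> None:
    """Suffix duplicate ids deterministically: x, x_2, x_3, ..."""
    seen: dict[str, int] = {}
    for rec in records:
        n = seen.get(rec.id, 0) + 1
        seen[rec.id] = n
        if n > 1:
            rec.id = f"{rec.id}_{n}"


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def _make_record(id_: str, smiles: str) -> CompoundRecord:
    smiles = smiles.strip()
    if not smiles:
        return CompoundRecord(id_, smiles, valid=False, failure_reason="empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return CompoundRecord(id_, smiles, valid=False, failure_reason="RDKit failed to parse SMILES")
    if mol.GetNumHeavyAtoms() < 1:
        return CompoundRecord(id_, smiles, valid=False, failure_reason="no heavy atoms")
    frag = _largest_fragment(mol)
    return CompoundRecord(id_, smiles, valid=True, fragment_smiles=Chem.MolToSmiles(frag))


def parse_compounds(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read compounds from a .smi, .csv or .sdf file.

    One :class:`CompoundRecord` per input entry, in input order; entries
    that fail to parse yield ``valid=False`` records rather than raising.

    Parameters
    ----------
    path:
        Input file.  Must exist.
    format:
        ``"smi"``, ``"csv"`` or ``"sdf"``; inferred from the suffix when
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "smi":
        records = _parse_smi(path)
    elif fmt == "csv":
        records = _parse_csv(path)
    elif fmt == "sdf":
        records = _parse_sdf(path)
    else:
        raise ValueError(f"unsupported compound format: {fmt!r} (expected smi, csv or sdf)")
    _dedupe_ids(records)
    return records


def _parse_smi(path: Path) -> list[CompoundRecord]:
    records = []
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            id_ = parts[1].strip() if len(parts) > 1 else f"line{i}"
            records.append(_make_record(id_, smiles))
    return records


def _parse_csv(path: Path) -> list[CompoundRecord]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty CSV")
        cols = {c.lower(): c for c in reader.fieldnames}
        if "smiles" not in cols:
            raise SchemaError(f"{path}: no 'smiles' column (found: {reader.fieldnames})")
        smi_col = cols["smiles"]
        id_col = cols.get("id")
        records = []
        for i, row in enumerate(reader, start=1):
            id_ = (row.get(id_col) or "").strip() if id_col else ""
            records.append(_make_record(id_ or f"row{i}", row.get(smi_col) or ""))
    return records


def _parse_sdf(path: Path) -> list[CompoundRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            records.append(
                CompoundRecord(f"sdf{i}", "", valid=False, failure_reason="unreadable SDF record")
            )
            continue
        id_ = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        records.append(_make_record(id_ or f"sdf{i}", Chem.MolToSmiles(mol)))
    return records


def compute_descriptors(record: CompoundRecord) -> DescriptorVector:
    """Compute the six QEA descriptors for one valid compound.

    Descriptors are evaluated on the largest covalent fragment, so salts
    and formulation mixtures are scored on their main component.  Raises
    ``ValueError`` for records with ``valid=False`` — never silent zeros.
    """
    if not record.valid:
        raise ValueError(f"cannot compute descriptors for invalid record {record.id!r}: "
                         f"{record.failure_reason}")
    mol = Chem.MolFromSmiles(record.fragment_smiles or record.smiles)
    if mol is None:  # pragma: no cover - valid records always reparse
        raise ValueError(f"record {record.id!r} marked valid but SMILES no longer parses")
    # reparse from canonical SMILES: atom order then no longer depends on how
    # the input was written, so additive descriptors are bit-identical
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        nrotb=Descriptors.NumRotatableBonds(mol),
        narr=rdMolDescriptors.CalcNumAromaticRings(mol),
    )


def canonical_smiles(record: CompoundRecord) -> str | None:
    """Canonical SMILES of the scored fragment, or None for invalid records."""
    if not record.valid:
        return None
    return record.fragment_smiles


def deduplicate(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Drop repeated structures (by canonical fragment SMILES), keeping the
    first occurrence.  Invalid records are kept as-is."""
    out, seen = [], set()
    for rec in records:
        key = canonical_smiles(rec)
        if key is not None:
            if key in seen:
                continue
            seen.add(key)
        out.append(rec)
    return out


def descriptor_table(records: Sequence[CompoundRecord]):
    """Descriptor table as a pandas DataFrame (invalid rows carry NaN)."""
    import pandas as pd

    rows = []
    for rec in records:
        row: dict = {"id": rec.id, "smiles": rec.smiles, "valid": rec.valid}
        if rec.valid:
            row.update(compute_descriptors(rec).as_dict())
        rows.append(row)
    cols = ["id", "smiles", *DESCRIPTOR_NAMES, "valid"]
    return pd.DataFrame(rows).reindex(columns=cols)


def write_descriptor_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    descriptor_table(records).to_csv(path, index=False)
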