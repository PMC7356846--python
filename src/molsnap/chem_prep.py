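"""Compound curation and 3D embedding.

Raw screening libraries arrive as (id, SMILES, activity score) rows. Before
any image can be rendered the structures are standardized: the largest
organic fragment is kept (desalting), simple protonation states are
neutralized, and the structure is canonicalized. Records that cannot be
standardized — unparseable SMILES, carbon-free species — are excluded with a
machine-readable reason rather than dropped silently, and duplicate
structures whose activity labels disagree are excluded as indefinite.

Kept records are embedded as a single explicit-hydrogen 3D conformer using
seeded distance-geometry embedding followed by force-field cleanup, and can
be round-tripped through V2000 SDF.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

ACTIVE_THRESHOLD = 40  # activity score >= 40 means active

# exclusion reasons (machine readable)
REASON_INACCURATE_SMILES = "inaccurate_smiles"
REASON_NONORGANIC = "nonorganic"
REASON_INDEFINITE = "indefinite_activity"
REASON_EMBED_FAILED = "embedding_failed"
REASON_MISSING_SCORE = "missing_score"


@dataclass
class CompoundRecord:
    """One library entry: identifier, structure, and activity annotation."""

    compound_id: str
    smiles: str
    activity_score: Optional[int] = None
    label: str = "excluded"  # active | inactive | excluded
    exclusion_reason: Optional[str] = None
    canonical_smiles: Optional[str] = None

    @property
    def kept(self) -> bool:
        return self.label in ("active", "inactive")


@dataclass
class Conformer3D:
    """Elements, Cartesian coordinates (Å) and bonds of one conformer."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float
    bonds: list[tuple[int, int]] = field(default_factory=list)
    source: str = "embedded"  # embedded | sdf
    compound_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for i, j in self.bonds:
            if i == j:
                raise ValueError("self-bond")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


class ParseFailure:
    """Value-level SMILES parse failure (never an exception)."""

    __slots__ = ("reason",)

    def __init__(self, reason: str = REASON_INACCURATE_SMILES):
        self.reason = reason

    def __repr__(self) -> str:
        return f"ParseFailure({self.reason!r})"

    def __bool__(self) -> bool:
        return False


def parse_smiles(smiles: str) -> Chem.Mol | ParseFailure:
    """Parse a SMILES string; syntactic failure is returned as a value."""
    if not smiles or not smiles.strip():
        return ParseFailure()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ParseFailure()
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    # prefer fragments containing carbon, then most heavy atoms
    def key(frag: Chem.Mol):
        has_c = any(a.GetSymbol() == "C" for a in frag.GetAtoms())
        return (has_c, frag.GetNumHeavyAtoms())

    return max(frags, key=key)


_UNCHARGER = rdMolStandardize.Uncharger()


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize simple protonation states (carboxylates, ammoniums...).

    Quaternary centers and true zwitterions are left as the uncharger finds
    them; no pKa model is applied.
    """
    return _UNCHARGER.uncharge(mol)


def _is_organic(mol: Chem.Mol) -> bool:
    return any(atom.GetSymbol() == "C" for atom in mol.GetAtoms())


def classify_score(score: int) -> str:
    if not (0 <= score <= 100):
        raise ValueError(f"activity score must be in [0, 100], got {score}")
    return "active" if score >= ACTIVE_THRESHOLD else "inactive"


def curate_record(record: CompoundRecord) -> CompoundRecord:
    """Standardize one record: desalt, neutralize, canonicalize, label.

    Exclusion (bad SMILES, carbon-free largest fragment, missing score) is
    expressed in the label and reason fields; this function never raises for
    bad structures.
    """
    mol = parse_smiles(record.smiles)
    if isinstance(mol, ParseFailure):
        return replace(record, label="excluded", exclusion_reason=mol.reason,
                       canonical_smiles=None)
    mol = _largest_fragment(mol)
    if not _is_organic(mol):
        return replace(record, label="excluded", exclusion_reason=REASON_NONORGANIC,
                       canonical_smiles=None)
    mol = _neutralize(mol)
    canonical = Chem.MolToSmiles(mol)
    if record.activity_score is None:
        return replace(record, label="excluded", exclusion_reason=REASON_MISSING_SCORE,
                       canonical_smiles=canonical)
    label = classify_score(record.activity_score)
    return replace(record, label=label, exclusion_reason=None,
                   canonical_smiles=canonical)


def resolve_duplicates(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse records sharing one canonical structure.

    Groups that agree on the active/inactive label collapse to their first
    member; groups with conflicting labels are excluded entirely as
    ``indefinite_activity``. Already-excluded records pass through untouched.
    """
    out: list[CompoundRecord] = []
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        if not rec.kept or rec.canonical_smiles is None:
            out.append(rec)
            continue
        if rec.canonical_smiles not in groups:
            groups[rec.canonical_smiles] = []
            order.append(rec.canonical_smiles)
        groups[rec.canonical_smiles].append(rec)
    for smi in order:
        members = groups[smi]
        labels = {m.label for m in members}
        if len(labels) == 1:
            out.append(members[0])
        else:
            for m in members:
                out.append(replace(m, label="excluded",
                                   exclusion_reason=REASON_INDEFINITE))
    return out


def curate_library(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """curate_record on every record, then resolve duplicates."""
    return resolve_duplicates([curate_record(r) for r in records])


def embed_3d(record: CompoundRecord, seed: int = 1) -> Conformer3D | CompoundRecord:
    """Embed one explicit-hydrogen 3D conformer, deterministically per seed.

    Distance-geometry (ETKDG) embedding followed by MMFF94 cleanup (UFF
    fallback). On embedding failure the record is returned marked excluded
    with reason ``embedding_failed``.
    """
    if not record.kept:
        raise ValueError(f"cannot embed excluded record {record.compound_id}")
    smiles = record.canonical_smiles or record.smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return replace(record, label="excluded", exclusion_reason=REASON_EMBED_FAILED)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(mol, params) != 0:
        return replace(record, label="excluded", exclusion_reason=REASON_EMBED_FAILED)
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # unoptimized geometry is still usable
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x,
                        conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return Conformer3D(elements=elements, coords=coords, bonds=bonds,
                       source="embedded", compound_id=record.compound_id)


# ---------------------------------------------------------------------------
# SDF round-trip


def write_sdf(conformers: Sequence[Conformer3D], path: str | Path) -> None:
    """Write conformers as a V2000 SDF (one record per conformer)."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for c in conformers:
            mol = Chem.RWMol()
            rd_conf = Chem.Conformer(c.n_atoms)
            for i, (el, xyz) in enumerate(zip(c.elements, c.coords)):
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
                rd_conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
            for i, j in c.bonds:
                mol.AddBond(i, j, Chem.BondType.SINGLE)
            m = mol.GetMol()
            m.SetProp("_Name", c.compound_id)
            Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
            m.AddConformer(rd_conf)
            writer.write(m)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Conformer3D]:
    """Read conformers back from an SDF written by :func:`write_sdf`."""
    out: list[Conformer3D] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        out.append(Conformer3D(
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            coords=coords,
            bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
            source="sdf",
            compound_id=mol.GetProp("_Name") if mol.HasProp("_Name") else "",
        ))
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def read_library_csv(path: str | Path) -> list[CompoundRecord]:
    """Read a compound library CSV: compound_id, smiles, activity_score."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row.get("activity_score", "")
            score = int(raw) if raw not in ("", None, "NA") else None
            records.append(CompoundRecord(
                compound_id=row["compound_id"], smiles=row["smiles"],
                activity_score=score))
    return records


def write_exclusion_log(records: Sequence[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "reason"])
        for rec in records:
            if not rec.kept:
                w.writerow([rec.compound_id, rec.exclusion_reason or ""])
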