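"""Docking post-processing: affinity filtering, pose RMSD, contacts, H-bonds.

Docking itself is never run here; its outputs (score tables, pose files)
are consumed.  The hit filter keeps ligands whose predicted binding
affinity is at or below a kcal/mol threshold (more negative = stronger;
the default -8.0 is inclusive).  Pose agreement is measured as heavy- or
all-atom RMSD, optionally after optimal least-squares (Kabsch)
superimposition.  Binding-site analysis is geometric: residues with any
heavy-atom pair within a cutoff, and hydrogen bonds from donor/acceptor
distance and D-H...A angle criteria — no interaction-subtype typing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import SchemaError
from .structures import Molecule

__all__ = [
    "AffinityRecord",
    "DOCKING_BOX",
    "AFFINITY_THRESHOLD",
    "load_affinity_table",
    "normalize_ligand_name",
    "filter_hits",
    "pose_rmsd",
    "contact_residues",
    "hydrogen_bonds",
]

# Grid-box metadata of the ER-alpha (3ERT) docking setup, carried for
# provenance only; nothing in this package executes a docking run.
DOCKING_BOX = {
    "center": (29.944, -1.861, 24.611),
    "size": (18.0, 14.0, 18.0),
}

AFFINITY_THRESHOLD = -8.0  # kcal/mol, inclusive

# Misspellings that appear in published score tables, mapped back to the
# GC-MS constituent names.  Matches are flagged, never silent.
_NAME_ALIASES = {
    "copaane": "Copaene",
    "limonenel": "Limonene",
    "cryophyllene": "Caryophyllene",
    "cryophyllene oxide": "Caryophyllene oxide",
}


@dataclass(frozen=True)
class AffinityRecord:
    ligand_name: str
    affinity: float  # kcal/mol

    def __post_init__(self):
        if not np.isfinite(self.affinity):
            raise ValueError(f"non-finite affinity for {self.ligand_name!r}")


def normalize_ligand_name(name: str) -> tuple[str, bool]:
    """Return (canonical name, was_aliased)."""
    key = name.strip().lower()
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key], True
    return name.strip(), False


def load_affinity_table(path: str | Path, normalize_names: bool = True) -> list[AffinityRecord]:
    """Read a TSV/CSV with ``ligand`` and ``affinity_kcal_mol`` columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    name_col = next((cols[k] for k in ("ligand", "name", "ligand_name") if k in cols), None)
    aff_col = next(
        (cols[k] for k in ("affinity_kcal_mol", "affinity", "affinity (kcal/mol)") if k in cols),
        None,
    )
    if name_col is None or aff_col is None:
        raise SchemaError(f"{path.name}: need ligand and affinity columns, found {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        name = str(row[name_col])
        if normalize_names:
            name, _ = normalize_ligand_name(name)
        records.append(AffinityRecord(ligand_name=name, affinity=float(row[aff_col])))
    return records


def filter_hits(
    records: list[AffinityRecord],
    threshold: float = AFFINITY_THRESHOLD,
    exclude: list[str] | None = None,
) -> list[AffinityRecord]:
    """Keep records with affinity <= threshold (inclusive), preserving
    input order; names in ``exclude`` are removed first (case-insensitive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    excluded = {e.strip().lower() for e in (exclude or [])}
    return [
        r
        for r in records
        if r.ligand_name.strip().lower() not in excluded and r.affinity <= threshold
    ]


def _check_matched(mol_a: Molecule, mol_b: Molecule) -> None:
    if len(mol_a) != len(mol_b):
        raise ValueError(f"atom count mismatch: {len(mol_a)} vs {len(mol_b)}")
    if mol_a.elements != mol_b.elements:
        raise ValueError("element sequences differ; atoms are matched by file order")


def pose_rmsd(mol_a: Molecule, mol_b: Molecule, superimpose: bool = False) -> float:
    """RMSD between two conformations with atoms matched by order.

    With ``superimpose`` the optimal rigid rotation+translation (Kabsch)
    is applied first, so the value reflects shape difference only.  No
    graph-symmetry correction is attempted.
    """
    _check_matched(mol_a, mol_b)
    P, Q = mol_a.coords, mol_b.coords
    if superimpose:
        Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
        _, rssd = Rotation.align_vectors(Pc, Qc)
        return float(rssd / np.sqrt(len(P)))
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def contact_residues(
    protein: Molecule, ligand: Molecule, cutoff: float = 4.5
) -> list[tuple[str, float]]:
    """Residues with any heavy-atom pair within ``cutoff`` angstrom of the
    ligand, as (label, min distance) sorted by min distance.

    Labels are ``RESNAME+number`` (e.g. ``LEU346``), chain-qualified when
    chains are present.
    """
    if not protein.has_residue_labels:
        raise ValueError("protein has no residue labels; cannot report contacts")
    prot = protein.heavy()
    lig = ligand.heavy()
    d = cdist(prot.coords, lig.coords)
    per_res: dict[str, float] = {}
    for atom, dmin in zip(prot.atoms, d.min(axis=1)):
        chain = atom.chain or ""
        label = f"{atom.residue_name}{atom.residue_number}"
        if chain:
            label = f"{chain}:{label}"
        per_res[label] = min(per_res.get(label, np.inf), float(dmin))
    hits = [(lab, dm) for lab, dm in per_res.items() if dm <= cutoff]
    hits.sort(key=lambda t: t[1])
    return hits


@dataclass(frozen=True)
class HydrogenBond:
    donor: str  # label of donor heavy atom (with molecule tag)
    acceptor: str
    distance: float  # donor-acceptor, angstrom
    angle: float  # D-H...A, degrees


def _atom_label(mol_tag: str, mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    res = f"{a.residue_name}{a.residue_number}." if a.residue_name else ""
    return f"{mol_tag}:{res}{a.name or a.element}{idx}"


def _donors_with_h(mol: Molecule, bond_cutoff: float = 1.25):
    """(heavy index, H index) pairs for N/O atoms with an attached H."""
    h_idx = [i for i, a in enumerate(mol.atoms) if a.element == "H"]
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element not in ("N", "O"):
            continue
        for j in h_idx:
            if np.linalg.norm(mol.atoms[j].coords - a.coords) <= bond_cutoff:
                out.append((i, j))
    return out


def _acceptors(mol: Molecule):
    return [i for i, a in enumerate(mol.atoms) if a.element in ("N", "O")]


def hydrogen_bonds(
    protein: Molecule,
    ligand: Molecule,
    max_da_dist: float = 3.5,
    min_dha_angle: float = 120.0,
) -> list[HydrogenBond]:
    """Geometric hydrogen bonds between the two molecules, both directions.

    Criteria: donor is N/O with an attached hydrogen; acceptor is N/O of
    the other molecule; donor-acceptor distance <= ``max_da_dist`` and
    D-H...A angle >= ``min_dha_angle`` degrees.
    """
    bonds: list[HydrogenBond] = []
    pairs = [("protein", protein, "ligand", ligand), ("ligand", ligand, "protein", protein)]
    for dtag, dmol, atag, amol in pairs:
        for d_idx, h_idx in _donors_with_h(dmol):
            d_xyz = dmol.atoms[d_idx].coords
            h_xyz = dmol.atoms[h_idx].coords
            for a_idx in _acceptors(amol):
                a_xyz = amol.atoms[a_idx].coords
                dist = float(np.linalg.norm(a_xyz - d_xyz))
                if dist > max_da_dist:
                    continue
                v1 = d_xyz - h_xyz
                v2 = a_xyz - h_xyz
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
                angle = float(np.degrees(np.arccos(cosang)))
                if angle >= min_dha_angle:
                    bonds.append(
                        HydrogenBond(
                            donor=_atom_label(dtag, dmol, d_idx),
                            acceptor=_atom_label(atag, amol, a_idx),
                            distance=dist,
                            angle=angle,
                        )
                    )
    bonds.sort(key=lambda b: b.distance)
    return bonds
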