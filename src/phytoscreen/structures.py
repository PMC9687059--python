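"""3D structure containers and PDB/PDBQT/XYZ input/output.

PDB files are read through gemmi.  PDBQT (AutoDock's PDB dialect with
partial charges and AD atom types) and plain XYZ are handled by compact
fixed-column readers here, including element recovery from AD atom types
and Vina result REMARKs.  Coordinates are angstroms in the source frame;
nothing is re-centered on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import StructureParseError

__all__ = ["Atom", "Molecule", "load_structure", "write_xyz", "write_pdb",
           "mark_polar_hydrogens", "parse_vina_affinities"]

_KNOWN_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "K", "CA", "BR", "I", "FE", "ZN", "MN", "CU", "SE",
}

# AutoDock atom type -> element
_AD_TYPES = {
    "A": "C", "C": "C", "CA": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "H": "H", "HD": "H", "HS": "H",
    "S": "S", "SA": "S", "P": "P", "F": "F", "CL": "Cl", "BR": "Br",
    "I": "I", "ZN": "Zn", "MG": "Mg", "MN": "Mn", "CA+": "Ca", "FE": "Fe",
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP"}


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) angstrom
    name: str = ""
    residue_name: str | None = None
    residue_number: int | None = None
    chain: str | None = None
    is_polar_h: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"bad coordinates for atom {self.name!r}: {self.coords}")
        if self.element.upper() not in _KNOWN_ELEMENTS:
            raise StructureParseError(f"unknown element symbol {self.element!r}")


@dataclass
class Molecule:
    atoms: list[Atom]
    label: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def has_residue_labels(self) -> bool:
        return any(a.residue_name for a in self.atoms)

    def heavy(self) -> "Molecule":
        """Copy without hydrogens."""
        kept = [a for a in self.atoms if a.element != "H"]
        return Molecule(atoms=kept, label=self.label)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "Molecule":
        """Rigidly transformed copy: x -> R x + t."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return Molecule(atoms=atoms, label=self.label)


def mark_polar_hydrogens(mol: Molecule, bond_cutoff: float = 1.25) -> None:
    """Flag hydrogens within ``bond_cutoff`` angstrom of an N/O as polar."""
    heavies = [(a.coords) for a in mol.atoms if a.element in ("N", "O")]
    if not heavies:
        return
    heavies = np.array(heavies)
    for a in mol.atoms:
        if a.element == "H":
            d = np.linalg.norm(heavies - a.coords, axis=1).min()
            a.is_polar_h = bool(d <= bond_cutoff)


def _element_from_pdbqt(line: str, lineno: int) -> str:
    ad_type = line[77:79].strip().upper() if len(line) > 77 else ""
    if ad_type in _AD_TYPES:
        return _AD_TYPES[ad_type]
    # fall back on the atom-name convention
    name = line[12:16].strip()
    guess = "".join(c for c in name if c.isalpha())[:2].capitalize()
    for cand in (guess, guess[:1]):
        if cand.upper() in _KNOWN_ELEMENTS:
            return cand
    raise StructureParseError(f"cannot infer element from {line!r}", line=lineno)


def _load_pdbqt(path: Path, strip_waters: bool, model: int) -> Molecule:
    atoms: list[Atom] = []
    current_model = 0  # 0 while no MODEL record has been seen
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current_model += 1
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        if current_model and current_model != model:
            continue
        resname = line[17:20].strip()
        if strip_waters and resname in _WATER_NAMES:
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError:
            raise StructureParseError(
                f"malformed coordinate field in {path.name}", line=lineno
            ) from None
        element = _element_from_pdbqt(line, lineno)
        resseq = line[22:26].strip()
        atoms.append(
            Atom(
                element=element,
                coords=xyz,
                name=line[12:16].strip(),
                residue_name=resname or None,
                residue_number=int(resseq) if resseq else None,
                chain=line[21].strip() or None,
            )
        )
    if not atoms:
        raise StructureParseError(f"{path.name}: no atoms found")
    mol = Molecule(atoms=atoms, label=path.stem)
    mark_polar_hydrogens(mol)
    return mol


def _load_pdb_gemmi(path: Path, strip_waters: bool, model: int) -> Molecule:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from None
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no models")
    if strip_waters:
        st.remove_waters()
    gm = st[min(model, len(st)) - 1]
    atoms: list[Atom] = []
    for chain in gm:
        for res in chain:
            for at in res:
                el = at.element.name
                if el.upper() not in _KNOWN_ELEMENTS:
                    raise StructureParseError(
                        f"{path.name}: unknown element {el!r} in {res.name}"
                    )
                atoms.append(
                    Atom(
                        element=el,
                        coords=[at.pos.x, at.pos.y, at.pos.z],
                        name=at.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain=chain.name,
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path.name}: no atoms found")
    mol = Molecule(atoms=atoms, label=path.stem)
    mark_polar_hydrogens(mol)
    return mol


def _load_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise StructureParseError(f"{path.name}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path.name}: bad atom count line", line=1) from None
    atoms: list[Atom] = []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path.name}: short XYZ row", line=lineno)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise StructureParseError(
                f"{path.name}: malformed coordinate field", line=lineno
            ) from None
        atoms.append(Atom(element=parts[0].capitalize(), coords=xyz, name=parts[0]))
    if len(atoms) != n:
        raise StructureParseError(f"{path.name}: expected {n} atoms, found {len(atoms)}")
    mol = Molecule(atoms=atoms, label=path.stem)
    mark_polar_hydrogens(mol)
    return mol


def load_structure(path: str | Path, strip_waters: bool = True, model: int = 1) -> Molecule:
    """Read a PDB, PDBQT, or XYZ file into a :class:`Molecule`.

    For multi-model files the first model is read unless ``model`` selects
    another.  Waters (HOH and friends) are stripped by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".pdbqt":
        return _load_pdbqt(path, strip_waters, model)
    if suffix in (".pdb", ".ent"):
        return _load_pdb_gemmi(path, strip_waters, model)
    if suffix == ".xyz":
        return _load_xyz(path)
    raise StructureParseError(f"unsupported structure format: {path.name}")


def write_xyz(mol: Molecule, path: str | Path, comment: str = "") -> None:
    path = Path(path)
    lines = [str(len(mol)), comment or mol.label]
    for a in mol.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element} {x:.4f} {y:.4f} {z:.4f}")
    path.write_text("\n".join(lines) + "\n")


def write_pdb(mol: Molecule, path: str | Path) -> None:
    """Write minimal ATOM records (readable back through gemmi)."""
    path = Path(path)
    lines = []
    for i, a in enumerate(mol.atoms, start=1):
        x, y, z = a.coords
        name = (a.name or a.element)[:4]
        resname = (a.residue_name or "LIG")[:3]
        chain = (a.chain or "A")[:1]
        resnum = a.residue_number or 1
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{resname:>4s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def parse_vina_affinities(path: str | Path) -> list[float]:
    """Extract the kcal/mol scores from ``REMARK VINA RESULT`` lines of an
    AutoDock-Vina output PDBQT, in model order."""
    path = Path(path)
    scores = []
    for line in path.read_text().splitlines():
        if line.startswith("REMARK VINA RESULT"):
            parts = line.split()
            try:
                scores.append(float(parts[3]))
            except (IndexError, ValueError):
                raise StructureParseError(f"malformed Vina result line: {line!r}") from None
    return scores
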