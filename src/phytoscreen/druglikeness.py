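"""Lipinski rule-of-five evaluation with a local Moriguchi MLOGP.

The rule-of-five screen used here flags violations of

    MW > 500 g/mol,  MLOGP > 4.15,  HBA > 10,  HBD > 5

and calls a compound druglike when at most one rule is violated.
Hydrogen-bond acceptors follow the Lipinski convention (count of N and O
atoms) and donors are heteroatoms bearing at least one hydrogen.

MLOGP is the Moriguchi 13-descriptor regression on topological counts,
implemented locally on RDKit molecule graphs:

    MLOGP = 1.244*CX^0.6 - 1.069*NO^0.9 + 0.406*PRX - 0.145*UB^0.8
            + 0.511*HB + 0.268*POL - 2.215*AMP + 0.912*ALK - 0.392*RNG
            - 3.684*QN + 0.474*NO2 + 1.582*NCS + 0.773*BLM - 1.041

Descriptor conventions (documented in docs/methods.md): CX weights
carbons 1.0 and halogens F/Cl/Br/I as 0.5/1.0/1.5/2.0; UB counts Kekule
double/triple bonds outside nitro groups (a triple bond counts twice);
ALK marks pure hydrocarbons with at most one aliphatic multiple bond
(aromatic bonds do not count against it); RNG marks any ring that is not
a pure-carbon aromatic ring.  Molecular weights use 2005-vintage standard
atomic weights.  Molar refractivity (Wildman-Crippen, via RDKit) is
reported for information only and never enters the verdict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Crippen

from .errors import UnknownElementError

__all__ = [
    "ATOMIC_WEIGHTS",
    "CompoundRecord",
    "parse_formula",
    "molecular_weight",
    "count_hb_acceptors",
    "count_hb_donors",
    "mlogp",
    "molar_refractivity",
    "lipinski_assess",
    "evaluate_compound",
]

# 2005 IUPAC standard atomic weights (g/mol)
ATOMIC_WEIGHTS = {
    "H": 1.00794, "C": 12.0107, "N": 14.0067, "O": 15.9994, "S": 32.065,
    "P": 30.973762, "F": 18.9984032, "Cl": 35.453, "Br": 79.904,
    "I": 126.90447, "Na": 22.98977, "K": 39.0983, "Ca": 40.078,
}

MLOGP_THRESHOLD = 4.15
RULE_NAMES = ("MW>500", "MLOGP>4.15", "HBA>10", "HBD>5")

_HALOGEN_CX = {"C": 1.0, "F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}
_MLOGP_COVERED = {"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """'C15H24O' -> {'C': 15, 'H': 24, 'O': 1}."""
    if isinstance(formula, dict):
        return dict(formula)
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula.strip()) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molecular_weight(formula: str | dict[str, int]) -> float:
    """Sum of count * standard atomic weight over the formula."""
    counts = parse_formula(formula)
    unknown = set(counts) - set(ATOMIC_WEIGHTS)
    if unknown:
        raise UnknownElementError(f"no atomic weight for {sorted(unknown)}")
    return sum(n * ATOMIC_WEIGHTS[el] for el, n in counts.items())


def _as_mol(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(str(structure))
    if mol is None:
        raise ValueError(f"cannot interpret structure {structure!r}")
    return mol


def count_hb_acceptors(structure_or_formula) -> int:
    """Lipinski acceptors: number of N and O atoms."""
    if isinstance(structure_or_formula, (str, dict)):
        try:
            counts = parse_formula(structure_or_formula)  # type: ignore[arg-type]
            return counts.get("N", 0) + counts.get("O", 0)
        except ValueError:
            pass  # not a formula; fall through to SMILES
    mol = _as_mol(structure_or_formula)
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))


def count_hb_donors(structure) -> int:
    """Lipinski donors: N/O atoms carrying at least one hydrogen.

    Needs a structure; a bare formula cannot place the hydrogens.
    """
    if isinstance(structure, dict) or (
        isinstance(structure, str) and _looks_like_formula(structure)
    ):
        counts = parse_formula(structure)
        if counts.get("N", 0) or counts.get("O", 0):
            raise ValueError(
                "donor counting needs a structure: a formula cannot say "
                "which N/O atoms carry hydrogens"
            )
        return 0
    mol = _as_mol(structure)
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) > 0
    )


def _looks_like_formula(text: str) -> bool:
    try:
        parse_formula(text)
    except ValueError:
        return False
    # formulas that are also valid SMILES (e.g. "CO") are treated as formulas
    return True


# --- Moriguchi descriptors -------------------------------------------------

_NITRO = Chem.MolFromSmarts("[N+](=O)[O-]")
_NITRO_NEUTRAL = Chem.MolFromSmarts("N(=O)=O")
_QUAT_N = Chem.MolFromSmarts("[NX4+,NX4]")
_N_OXIDE = Chem.MolFromSmarts("[#7+][O-]")
_NCS_ITC = Chem.MolFromSmarts("N=C=S")
_NCS_TC = Chem.MolFromSmarts("[SX2]C#N")
_BETA_LACTAM = Chem.MolFromSmarts("[NX3R]1[CX3R](=O)[CX4R][CX4R]1")
_ALPHA_AMINO_ACID = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O)][CX4H]C(=O)[OX2H1,OX1-]")
_ORTHO_HB = Chem.MolFromSmarts("[OX2H,NX3H]c1ccccc1[$([OX1]),$([OX2H]),$([NX3]),$([OX2])]")


def _nitro_bond_ids(mol: Chem.Mol) -> set[int]:
    ids: set[int] = set()
    for patt in (_NITRO, _NITRO_NEUTRAL):
        for match in mol.GetSubstructMatches(patt):
            atoms = set(match)
            for b in mol.GetBonds():
                if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms:
                    ids.add(b.GetIdx())
    return ids


def mlogp_descriptors(structure) -> dict[str, float]:
    """The 13 Moriguchi descriptor values for a molecule."""
    mol = _as_mol(structure)
    uncovered = {a.GetSymbol() for a in mol.GetAtoms()} - _MLOGP_COVERED
    if uncovered:
        raise UnknownElementError(f"MLOGP does not cover element(s) {sorted(uncovered)}")

    cx = sum(_HALOGEN_CX.get(a.GetSymbol(), 0.0) for a in mol.GetAtoms())
    no = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))

    # proximity of N/O: bonded pair -> 2, 1,3 through C/S/P -> 1
    prx = 0.0
    hetero = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")]
    for i, ai in enumerate(hetero):
        for aj in hetero[i + 1 :]:
            bond = mol.GetBondBetweenAtoms(ai, aj)
            if bond is not None:
                prx += 2.0
                continue
            shared = set(
                n.GetIdx() for n in mol.GetAtomWithIdx(ai).GetNeighbors()
            ) & set(n.GetIdx() for n in mol.GetAtomWithIdx(aj).GetNeighbors())
            if any(
                mol.GetAtomWithIdx(s).GetSymbol() in ("C", "S", "P") for s in shared
            ):
                prx += 1.0

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro_bonds = _nitro_bond_ids(mol)
    ub = 0
    aliphatic_multiple = 0
    for b in kek.GetBonds():
        if b.GetIdx() in nitro_bonds:
            continue
        if b.GetBondType() == Chem.BondType.DOUBLE:
            ub += 1
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            ub += 2
    for b in mol.GetBonds():
        if b.GetIsAromatic() or b.GetIdx() in nitro_bonds:
            continue
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            aliphatic_multiple += 1

    hb = 1.0 if mol.HasSubstructMatch(_ORTHO_HB) else 0.0

    # polar substituents attached to an aromatic ring
    pol = 0
    for a in mol.GetAtoms():
        if not a.GetIsAromatic():
            continue
        for n in a.GetNeighbors():
            if n.GetIsAromatic():
                continue
            group = {n.GetSymbol()} | {m.GetSymbol() for m in n.GetNeighbors()}
            if {"N", "O"} & group:
                pol += 1
                break

    amp = 1.0 if mol.HasSubstructMatch(_ALPHA_AMINO_ACID) else 0.0

    is_hydrocarbon = all(a.GetSymbol() in ("C", "H") for a in mol.GetAtoms())
    alk = 1.0 if is_hydrocarbon and aliphatic_multiple <= 1 else 0.0

    rng = 0.0
    for ring in mol.GetRingInfo().AtomRings():
        if not all(
            mol.GetAtomWithIdx(i).GetIsAromatic()
            and mol.GetAtomWithIdx(i).GetSymbol() == "C"
            for i in ring
        ):
            rng = 1.0
            break

    qn = 0.0
    if mol.HasSubstructMatch(_QUAT_N):
        qn = 1.0
    elif mol.HasSubstructMatch(_N_OXIDE):
        qn = 0.5

    no2 = float(len(mol.GetSubstructMatches(_NITRO)) or len(mol.GetSubstructMatches(_NITRO_NEUTRAL)))
    ncs = 1.0 * len(mol.GetSubstructMatches(_NCS_ITC)) + 0.5 * len(
        mol.GetSubstructMatches(_NCS_TC)
    )
    blm = 1.0 if mol.HasSubstructMatch(_BETA_LACTAM) else 0.0

    return {
        "CX": cx, "NO": float(no), "PRX": prx, "UB": float(ub), "HB": hb,
        "POL": float(pol), "AMP": amp, "ALK": alk, "RNG": rng, "QN": qn,
        "NO2": no2, "NCS": ncs, "BLM": blm,
    }


def mlogp(structure) -> float:
    """Moriguchi MLOGP of an RDKit molecule or SMILES string."""
    d = mlogp_descriptors(structure)
    return (
        1.244 * d["CX"] ** 0.6
        - 1.069 * d["NO"] ** 0.9
        + 0.406 * d["PRX"]
        - 0.145 * d["UB"] ** 0.8
        + 0.511 * d["HB"]
        + 0.268 * d["POL"]
        - 2.215 * d["AMP"]
        + 0.912 * d["ALK"]
        - 0.392 * d["RNG"]
        - 3.684 * d["QN"]
        + 0.474 * d["NO2"]
        + 1.582 * d["NCS"]
        + 0.773 * d["BLM"]
        - 1.041
    )


def molar_refractivity(structure) -> float:
    """Wildman-Crippen molar refractivity (cm^3/mol), informational."""
    return float(Crippen.MolMR(_as_mol(structure)))


@dataclass
class CompoundRecord:
    """Druglikeness summary of one compound."""

    name: str
    formula: dict[str, int]
    mw: float
    mlogp: float
    hba: int
    hbd: int
    molar_refractivity: float | None = None
    violations: list[str] = field(default_factory=list)
    druglike: bool = True

    @property
    def verdict(self) -> str:
        """Verdict string in the conventional 'Yes; N violation(s)' style."""
        n = len(self.violations)
        word = "Yes" if self.druglike else "No"
        if n == 0:
            return f"{word}; 0 violation"
        suffix = "violation" if n == 1 else "violations"
        return f"{word}; {n} {suffix}: {', '.join(self.violations)}"

    def to_row(self) -> dict:
        return {
            "name": self.name,
            "mw": round(self.mw, 2),
            "mlogp": round(self.mlogp, 2),
            "hba": self.hba,
            "hbd": self.hbd,
            "molar_refractivity": (
                round(self.molar_refractivity, 2)
                if self.molar_refractivity is not None
                else None
            ),
            "druglike": self.verdict,
        }


def lipinski_assess(
    mw: float, mlogp_value: float, hba: int, hbd: int
) -> tuple[list[str], bool]:
    """Violations among MW>500, MLOGP>4.15, HBA>10, HBD>5; druglike when
    at most one rule is violated."""
    violations = []
    if mw > 500:
        violations.append("MW > 500")
    if mlogp_value > MLOGP_THRESHOLD:
        violations.append(f"MLOGP > {MLOGP_THRESHOLD}")
    if hba > 10:
        violations.append("HBA > 10")
    if hbd > 5:
        violations.append("HBD > 5")
    return violations, len(violations) <= 1


def evaluate_compound(name: str, structure) -> CompoundRecord:
    """Full rule-of-five evaluation of one structure (RDKit mol or SMILES)."""
    mol = _as_mol(structure)
    molh = Chem.AddHs(mol)
    formula: dict[str, int] = {}
    for a in molh.GetAtoms():
        formula[a.GetSymbol()] = formula.get(a.GetSymbol(), 0) + 1
    mw = molecular_weight(formula)
    logp = mlogp(mol)
    hba = count_hb_acceptors(mol)
    hbd = count_hb_donors(mol)
    violations, ok = lipinski_assess(mw, logp, hba, hbd)
    return CompoundRecord(
        name=name, formula=formula, mw=mw, mlogp=logp, hba=hba, hbd=hbd,
        molar_refractivity=molar_refractivity(mol),
        violations=violations, druglike=ok,
    )


def load_sdf(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read an SDF into (name, molecule) pairs; the _Name field keys each."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out = []
    for mol in supplier:
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{len(out)+1}"
        out.append((name, mol))
    return out
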