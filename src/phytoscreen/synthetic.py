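"""Seeded synthetic-data generators for every pipeline stage.

Each generator returns both the data table/structures and a machine-
readable truth record, so tests can compare pipeline output against the
known ground truth.  All randomness flows through one
``numpy.random.default_rng(seed)`` per call; the same seed reproduces the
output bit-for-bit, and file-writing helpers record the seed in a header
comment.

Defaults mirror the study conditions the pipeline was built around: the
dose-response truth (a=11.08 %/ln(ug/mL), b=12.68%, the six printed assay
concentrations, 2% Gaussian noise), seventeen-peak chromatograms with
log-normally dispersed areas, and docking-score tables spanning the
-10..-5 kcal/mol range around the -8 hit threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .complementarity import DensityParams, default_density_params
from .structures import Atom, Molecule, write_pdb, write_xyz

__all__ = [
    "gen_dose_response",
    "gen_toy_complex",
    "gen_affinity_table",
    "gen_peak_table",
    "gen_cf1_cloud",
    "DoseResponseTruth",
    "ToyComplex",
    "AffinityTruth",
    "PeakTruth",
    "Cf1CloudTruth",
]

#: concentrations (ug/mL) of the packaged radical-scavenging assay
ASSAY_CONCENTRATIONS = (3.1, 6.3, 12.5, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class DoseResponseTruth:
    a: float
    b: float
    noise_sd: float
    ic50: float
    seed: int


def gen_dose_response(
    a: float = 11.08,
    b: float = 12.68,
    noise_sd: float = 2.0,
    concentrations=ASSAY_CONCENTRATIONS,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, DoseResponseTruth]:
    """Log-linear dose-response table with Gaussian noise per replicate.

    Columns: ``concentration_ug_ml, rep1..repK, response_pct`` (mean).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = a * np.log(conc) + b
    reps = clean[:, None] + rng.normal(0.0, noise_sd, size=(conc.size, n_replicates))
    df = pd.DataFrame({"concentration_ug_ml": conc})
    for j in range(n_replicates):
        df[f"rep{j+1}"] = reps[:, j]
    df["response_pct"] = reps.mean(axis=1)
    truth = DoseResponseTruth(a=a, b=b, noise_sd=noise_sd,
                              ic50=math.exp((50.0 - b) / a), seed=seed)
    return df, truth


@dataclass
class ToyComplex:
    protein: Molecule
    ligand: Molecule
    separation: float
    seed: int
    protein_path: Path | None = None
    ligand_path: Path | None = None


_PROTEIN_ELEMENTS = ("C", "N", "O", "S")
_PROTEIN_WEIGHTS = (0.62, 0.17, 0.17, 0.04)


def _random_cluster(rng: np.random.Generator, n: int, spread: float,
                    elements, weights) -> np.ndarray:
    coords = rng.normal(0.0, spread, size=(n, 3))
    els = rng.choice(elements, size=n, p=weights)
    return coords, els


def _min_dist(p_coords: np.ndarray, l_coords: np.ndarray, shift_x: float) -> float:
    shifted = l_coords + np.array([shift_x, 0.0, 0.0])
    d = np.linalg.norm(p_coords[:, None, :] - shifted[None, :, :], axis=-1)
    return float(d.min())


def _solve_shift(p_coords: np.ndarray, l_coords: np.ndarray, separation: float) -> float:
    """Bisect the +x shift so the closest inter-cluster atom pair sits at
    exactly ``separation`` angstrom."""
    span = (
        float(np.abs(p_coords[:, 0]).max(initial=0.0))
        + float(np.abs(l_coords[:, 0]).max(initial=0.0))
    )
    lo, hi = 0.0, span + separation + 1.0
    # min distance grows monotonically with the shift once clusters separate
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _min_dist(p_coords, l_coords, mid) < separation:
            lo = mid
        else:
            hi = mid
    return hi


def gen_toy_complex(
    n_protein_atoms: int = 50,
    n_ligand_atoms: int = 10,
    separation: float = 3.0,
    params: DensityParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    single_atoms: bool = False,
) -> ToyComplex:
    """Two random atom clusters posed as an enzyme-ligand complex.

    ``separation`` is the closest inter-atomic distance between the two
    clusters: the ligand cluster is shifted along +x until its nearest
    atom sits exactly ``separation`` angstrom from the nearest protein
    atom, so an intermolecular shell of that width always exists.
    ``single_atoms=True`` gives the one-atom/one-atom configuration used
    by the closed-form complementarity checks.  When ``out_dir`` is given
    the protein is written as PDB and the ligand as XYZ (the same
    dialects the readers accept).
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    if single_atoms:
        p_coords, p_els = np.zeros((1, 3)), np.array(["C"])
        l_coords, l_els = np.zeros((1, 3)), np.array(["C"])
    else:
        p_coords, p_els = _random_cluster(
            rng, n_protein_atoms, 2.0, _PROTEIN_ELEMENTS, _PROTEIN_WEIGHTS
        )
        l_coords, l_els = _random_cluster(
            rng, n_ligand_atoms, 1.2, ("C", "O"), (0.85, 0.15)
        )
    shift = np.array([_solve_shift(p_coords, l_coords, separation), 0.0, 0.0])

    protein_atoms = [
        Atom(element=el, coords=xyz, name=f"{el}{i+1}",
             residue_name="GLY", residue_number=i + 1, chain="A")
        for i, (el, xyz) in enumerate(zip(p_els, p_coords))
    ]
    ligand_atoms = [
        Atom(element=el, coords=xyz + shift, name=f"{el}{i+1}")
        for i, (el, xyz) in enumerate(zip(l_els, l_coords))
    ]
    complex_ = ToyComplex(
        protein=Molecule(protein_atoms, label="toy_protein"),
        ligand=Molecule(ligand_atoms, label="toy_ligand"),
        separation=separation,
        seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        complex_.protein_path = out_dir / "toy_protein.pdb"
        complex_.ligand_path = out_dir / "toy_ligand.xyz"
        write_pdb(complex_.protein, complex_.protein_path)
        write_xyz(complex_.ligand, complex_.ligand_path, comment=f"seed={seed}")
    return complex_


@dataclass(frozen=True)
class AffinityTruth:
    n_below_threshold: int
    threshold: float
    seed: int


def gen_affinity_table(
    n: int = 17,
    affinity_range: tuple[float, float] = (-10.0, -5.0),
    threshold: float = -8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, AffinityTruth]:
    """Uniform docking scores with the true count at/below the threshold."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = min(affinity_range), max(affinity_range)
    aff = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame(
        {"ligand": [f"ligand{i+1}" for i in range(n)],
         "affinity_kcal_mol": np.round(aff, 2)}
    )
    truth = AffinityTruth(
        n_below_threshold=int((df["affinity_kcal_mol"] <= threshold).sum()),
        threshold=threshold, seed=seed,
    )
    return df, truth


@dataclass(frozen=True)
class PeakTruth:
    areas: tuple[float, ...]
    percentages: tuple[float, ...]
    seed: int


def gen_peak_table(
    n: int = 17,
    mean_log_area: float = 12.0,
    sd_log_area: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PeakTruth]:
    """Log-normal peak areas with analytically derived truth percentages."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    areas = np.exp(rng.normal(mean_log_area, sd_log_area, size=n))
    pct = 100.0 * areas / areas.sum()
    df = pd.DataFrame(
        {
            "peak": np.arange(1, n + 1),
            "rt_min": np.round(np.sort(rng.uniform(5.0, 45.0, size=n)), 2),
            "compound": [f"constituent{i+1}" for i in range(n)],
            "area": areas,
        }
    )
    return df, PeakTruth(areas=tuple(areas), percentages=tuple(pct), seed=seed)


@dataclass(frozen=True)
class Cf1CloudTruth:
    a: float
    b: float
    noise_sd: float
    seed: int


def gen_cf1_cloud(
    a: float = 6.4,
    b: float = -4.0,
    noise_sd: float = 0.3,
    n: int = 100,
    sumrlre_range: tuple[float, float] = (2.4, 4.5),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, Cf1CloudTruth]:
    """Synthetic (SUMRLRE, CF1) cloud with known linear coefficients."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(*sumrlre_range, size=n)
    cf1 = a + b * s + rng.normal(0.0, noise_sd, size=n)
    return s, cf1, Cf1CloudTruth(a=a, b=b, noise_sd=noise_sd, seed=seed)


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a generated table as TSV with the seed recorded in a header."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
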