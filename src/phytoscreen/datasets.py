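"""Loaders for the small fixture tables and structures shipped with the
package: the 17-peak guava-leaf chromatogram, the DPPH dose-response
points, the MTT viability table, the ER-alpha docking score table, the
default density-parameter table, and minimal SDF structures of the five
docking hits."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .bioassay import DoseResponsePoint
from .composition import ChromatographicPeak, load_peak_table
from .docking import AffinityRecord, load_affinity_table
from .druglikeness import load_sdf

__all__ = [
    "data_path",
    "load_guava_peaks",
    "load_dpph_points",
    "load_mtt_table",
    "load_er_affinities",
    "load_hit_compounds",
]

_HIT_COMPOUND_FILES = {
    "Caryophyllene": "caryophyllene.sdf",
    "Caryophyllene oxide": "caryophyllene_oxide.sdf",
    "Humulene": "humulene.sdf",
    "14-Hydroxy-9-epi-(E)-caryophyllene": "14_hydroxy_9_epi_e_caryophyllene.sdf",
    "Calamenene": "calamenene.sdf",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(files("phytoscreen") / "data" / name))


def load_guava_peaks() -> list[ChromatographicPeak]:
    """The packaged 17-peak guava-leaf GC-MS table."""
    return load_peak_table(data_path("guava_leaf_peaks.tsv"))


def load_dpph_points() -> list[DoseResponsePoint]:
    """The six packaged DPPH (concentration, % inhibition) observations."""
    df = pd.read_csv(data_path("dpph_inhibition.tsv"), sep="\t")
    return [
        DoseResponsePoint(concentration=float(r.concentration_ug_ml),
                          response=float(r.response_pct))
        for r in df.itertuples()
    ]


def load_mtt_table() -> pd.DataFrame:
    """Packaged MTT viability fixture (mean +/- SEM per cell line)."""
    return pd.read_csv(data_path("mtt_viability.tsv"), sep="\t")


def load_er_affinities(normalize_names: bool = True) -> list[AffinityRecord]:
    """Packaged ER-alpha docking score table (17 ligands + reference)."""
    return load_affinity_table(data_path("er_alpha_affinities.tsv"),
                               normalize_names=normalize_names)


def load_hit_compounds() -> dict[str, object]:
    """Structures of the five docking hits, keyed by compound name."""
    out = {}
    for name, fname in _HIT_COMPOUND_FILES.items():
        pairs = load_sdf(data_path(f"compounds/{fname}"))
        out[name] = pairs[0][1]
    return out
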