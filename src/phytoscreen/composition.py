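"""GC-MS composition profiling.

A gas chromatogram of an essential oil is reduced to a peak table
(retention time, identified compound, integrated raw area).  The relative
concentration of each constituent is taken directly as its share of the
total integrated area ("area percentage"), the standard semi-quantitative
convention for essential-oil work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SchemaError, TableParseError

__all__ = [
    "ChromatographicPeak",
    "CompositionProfile",
    "load_peak_table",
    "compute_area_percentages",
    "major_components",
]


@dataclass(frozen=True)
class ChromatographicPeak:
    """One integrated GC-MS peak."""

    index: int
    retention_time: float  # minutes
    compound_name: str
    area: float  # raw detector counts

    def __post_init__(self):
        if self.area < 0:
            raise ValueError(f"peak {self.index}: negative area {self.area}")


@dataclass
class CompositionProfile:
    """Peak table with derived area percentages.

    ``area_pct`` holds the unrounded percentages used for all arithmetic;
    ``area_pct_rounded`` is the 1-decimal presentation used in reports.
    """

    peaks: list[ChromatographicPeak]
    total_area: float
    area_pct: np.ndarray
    area_pct_rounded: np.ndarray = field(init=False)

    def __post_init__(self):
        self.area_pct = np.asarray(self.area_pct, dtype=float)
        self.area_pct_rounded = np.round(self.area_pct, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak": [p.index for p in self.peaks],
                "rt_min": [p.retention_time for p in self.peaks],
                "compound": [p.compound_name for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "area_pct": self.area_pct_rounded,
            }
        )


# accepted header spellings, all matched case-insensitively
_COLUMN_ALIASES = {
    "peak": {"peak", "index", "peak_number", "s.n.", "sn"},
    "rt_min": {"rt_min", "retention_time", "retention time (min)", "rt"},
    "compound": {"compound", "name", "compound_name"},
    "area": {"area", "raw_area"},
}


def _resolve_columns(columns) -> dict[str, str]:
    lowered = {str(c).strip().lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
    return resolved


def load_peak_table(path: str | Path) -> list[ChromatographicPeak]:
    """Read a TSV/CSV peak table into :class:`ChromatographicPeak` rows.

    Column order is free and headers are case-insensitive; a ``peak``
    index column is optional (row order is used when absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    cols = _resolve_columns(df.columns)
    missing = {"rt_min", "compound", "area"} - cols.keys()
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )

    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        raw_area = str(rec[cols["area"]]).replace(",", "")
        try:
            area = float(raw_area)
        except ValueError:
            raise TableParseError(
                f"{path.name}: non-numeric area {rec[cols['area']]!r}", row=i
            ) from None
        try:
            rt = float(rec[cols["rt_min"]])
        except ValueError:
            raise TableParseError(
                f"{path.name}: non-numeric retention time "
                f"{rec[cols['rt_min']]!r}", row=i
            ) from None
        idx = int(rec[cols["peak"]]) if "peak" in cols else i
        peaks.append(
            ChromatographicPeak(
                index=idx,
                retention_time=rt,
                compound_name=str(rec[cols["compound"]]).strip(),
                area=area,
            )
        )
    return peaks


def compute_area_percentages(peaks: list[ChromatographicPeak]) -> CompositionProfile:
    """Derive area percentages: ``100 * area / total_area`` per peak."""
    if not peaks:
        raise DegenerateInputError("no peaks given")
    areas = np.array([p.area for p in peaks], dtype=float)
    total = float(areas.sum())
    if total <= 0:
        raise DegenerateInputError("total peak area is zero")
    return CompositionProfile(peaks=list(peaks), total_area=total,
                              area_pct=100.0 * areas / total)


def major_components(profile: CompositionProfile, min_pct: float) -> list[tuple[str, float]]:
    """Constituents whose unrounded area percentage is >= ``min_pct``,
    sorted by decreasing share."""
    if not 0.0 <= min_pct <= 100.0:
        raise ValueError(f"min_pct must be in [0, 100], got {min_pct}")
    pairs = [
        (p.compound_name, float(pct))
        for p, pct in zip(profile.peaks, profile.area_pct)
        if pct >= min_pct
    ]
    pairs.sort(key=lambda t: -t[1])
    return pairs
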