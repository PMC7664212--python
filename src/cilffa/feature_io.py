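"""Readers/writers for feature tables, pair tables, the standards library and
result matrices.

The canonical interchange format is comma-delimited UTF-8 text with a header
row and dot decimals; lines starting with ``#`` are comments (the CLI writes a
provenance comment carrying the config hash and seed).  A feature table has
columns ``mz, rt, intensity, sample_id`` and optionally ``region`` and ``ri``.

Peak tables are held as :class:`pandas.DataFrame` throughout the pipeline;
:class:`Peak`, :class:`PeakPair` and :class:`LibraryEntry` give the validated
record-level view.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import Formula, LabelTag, derivative_mz

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakPair",
    "LibraryEntry",
    "DEFAULT_REGIONS",
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_library",
    "packaged_library_path",
    "write_pair_table",
    "read_pair_table",
    "write_matrix",
    "read_matrix",
    "read_mzml_features",
]

#: The 13 dissected rat-brain regions used as the default region vocabulary:
#: olfactory bulb, frontal/parietal/occipital/temporal cortex, hippocampus,
#: striatum, midbrain, thalamus, hypothalamus, cerebellum, medulla-pons,
#: brainstem.  Region labels remain free strings everywhere.
DEFAULT_REGIONS: tuple[str, ...] = (
    "OB", "FC", "PC", "OC", "TC", "HP", "STR", "MID", "THA", "HYP", "CE", "MEA", "BS",
)

FEATURE_COLUMNS = ("mz", "rt", "intensity", "sample_id")
OPTIONAL_COLUMNS = ("region", "ri")


@dataclass
class Peak:
    """One centroided LC-MS feature within a sample run."""

    mz: float
    rt: float
    intensity: float
    sample_id: str
    region: str | None = None
    ri: float | None = None

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")
        if not self.intensity > 0:
            raise ValueError(f"intensity must be > 0, got {self.intensity}")
        if self.ri is not None and self.ri < 0:
            raise ValueError(f"ri must be >= 0 once set, got {self.ri}")


@dataclass
class PeakPair:
    """A matched light/heavy feature pair: evidence for one potential FFA."""

    light: Peak
    heavy: Peak
    mass_error_mda: float   # signed: (heavy.mz - light.mz - 4.0251...) in mDa
    ri_gap: float
    intensity_ratio: float  # light / heavy

    def __post_init__(self):
        if not self.heavy.mz > self.light.mz:
            raise ValueError("heavy.mz must exceed light.mz")


@dataclass
class LibraryEntry:
    """A packaged standards-library record: a known labeled compound."""

    name: str
    neutral_formula: Formula
    reference_ri: float
    compound_class: str
    light_mz: float = field(init=False)

    def __post_init__(self):
        if not self.reference_ri > 0:
            raise ValueError(f"reference_ri must be > 0 for {self.name!r}")
        self.light_mz = derivative_mz(self.neutral_formula, LabelTag.LIGHT)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Rows violating the Peak invariants (non-positive mz/intensity, negative rt,
    non-numeric fields) are rejected; the rejected count is logged and recorded
    in ``df.attrs["n_rejected"]``.  Missing required columns raise ValueError
    naming the column.
    """
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "region": str})
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature table {path} is missing required column {col!r}")

    n_in = len(df)
    for col in ("mz", "rt", "intensity") + (("ri",) if "ri" in df.columns else ()):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["mz"].gt(0) & df["rt"].ge(0) & df["intensity"].gt(0)
        & df["sample_id"].notna()
    )
    if "ri" in df.columns:
        ok &= df["ri"].isna() | df["ri"].ge(0)
    bad = df.index[~ok]
    if len(bad):
        for i in bad[:10]:
            logger.warning("rejected row %d of %s: violates peak invariants", i + 2, path)
        logger.warning("%d of %d rows rejected from %s", len(bad), n_in, path)
    out = df.loc[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = int(len(bad))
    return out


def write_feature_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    _write_csv(df, path, header_comment)


# ---------------------------------------------------------------------------
# Standards library
# ---------------------------------------------------------------------------

def packaged_library_path() -> Path:
    """Path of the packaged (synthetic-RI) standards library CSV."""
    return Path(str(importlib.resources.files("cilffa").joinpath("data/ffa_library.csv")))


def read_library(path: str | Path | None = None) -> list[LibraryEntry]:
    """Load a standards library CSV (columns name, formula, reference_ri, class).

    Falls back to the packaged fixture library when ``path`` is None.
    Duplicate names and unparseable formulas raise ValueError naming the entry.
    """
    if path is None:
        path = packaged_library_path()
    df = pd.read_csv(path, comment="#")
    required = {"name", "formula", "reference_ri", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library {path} missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"duplicate library entry name: {dup!r}")
    entries = []
    for _, row in df.iterrows():
        try:
            formula = Formula.parse(str(row["formula"]))
        except ValueError as exc:
            raise ValueError(f"library entry {row['name']!r}: {exc}") from exc
        entries.append(
            LibraryEntry(
                name=str(row["name"]),
                neutral_formula=formula,
                reference_ri=float(row["reference_ri"]),
                compound_class=str(row["class"]),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Pair tables and matrices
# ---------------------------------------------------------------------------

PAIR_COLUMNS = (
    "light_mz", "heavy_mz", "mass_error_mda", "light_ri", "heavy_ri", "ri_gap",
    "light_rt", "heavy_rt", "light_intensity", "heavy_intensity",
    "intensity_ratio", "sample_id", "region",
)


def write_pair_table(pairs: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a pair table CSV (one matched light/heavy pair per row)."""
    _write_csv(pairs, path, header_comment)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"sample_id": str, "region": str})


def write_matrix(matrix: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a labeled (regions x regions or samples x FFAs) matrix CSV."""
    _write_csv(matrix, path, header_comment, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


# ---------------------------------------------------------------------------
# Optional mzML adapter
# ---------------------------------------------------------------------------

def read_mzml_features(path: str | Path, sample_id: str, region: str | None = None,
                       min_intensity: float = 0.0) -> pd.DataFrame:
    """Flatten centroided MS1 spectra of an mzML file into a feature table.

    Every centroid becomes one row (mz, rt, intensity); no peak picking or
    chromatographic integration is attempted — upstream feature detection is
    out of scope and this adapter exists only for already-centroided data.
    Requires :mod:`pyteomics`.
    """
    from pyteomics import mzml  # local import: optional dependency

    rows: list[tuple[float, float, float]] = []
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = float(spec["scanList"]["scan"][0]["scan start time"])
            mzs = np.asarray(spec["m/z array"], dtype=float)
            ints = np.asarray(spec["intensity array"], dtype=float)
            keep = ints > min_intensity
            rows.extend(zip(mzs[keep], np.full(keep.sum(), rt), ints[keep]))
    df = pd.DataFrame(rows, columns=["mz", "rt", "intensity"])
    df["sample_id"] = sample_id
    if region is not None:
        df["region"] = region
    return df
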