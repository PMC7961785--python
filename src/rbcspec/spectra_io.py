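"""Reading and writing spectral tables, cohort manifests and result tables.

Axis convention: wavenumbers are stored strictly increasing (cm^-1).  Files
written with a descending axis are reversed on load so that every downstream
operation can assume an ascending grid.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rbcspec.errors import InputError, ParseError

__all__ = [
    "Modality",
    "Stage",
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "write_spectrum_table",
    "write_table",
    "read_table",
    "read_manifest",
    "load_spectrum_set",
]

# Numeric formatting used for every table we emit; 12 significant digits keep
# round-trip relative error well under 1e-9 and make reruns byte-identical.
FLOAT_FORMAT = "%.12g"


class Modality(str, enum.Enum):
    FTIR = "FTIR"
    RAMAN = "RAMAN"


class Stage(str, enum.Enum):
    RAW = "RAW"
    PREPROCESSED = "PREPROCESSED"
    SECOND_DERIVATIVE = "SECOND_DERIVATIVE"


@dataclass
class Spectrum:
    """A single vibrational spectrum on an ascending wavenumber axis.

    Attributes
    ----------
    wavenumbers : ndarray
        Strictly increasing axis in cm^-1.
    intensities : ndarray
        Same length as ``wavenumbers``; absorbance (FTIR) or counts (Raman).
    modality : Modality
    sample_id : str
    group : str
        Cohort group label, e.g. ``"control"`` or ``"treated"``.
    stage : Stage
        Where in the processing chain this spectrum sits.
    meta : dict
        Free-form provenance; preprocessing appends one record per operation.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    modality: Modality
    sample_id: str = ""
    group: str = ""
    stage: Stage = Stage.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.modality = Modality(self.modality)
        self.stage = Stage(self.stage)
        self.validate()

    def validate(self) -> None:
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise InputError("wavenumbers and intensities must be 1-D arrays")
        if len(self.wavenumbers) != len(self.intensities):
            raise InputError(
                f"axis/intensity length mismatch: {len(self.wavenumbers)} vs "
                f"{len(self.intensities)}"
            )
        if len(self.wavenumbers) < 2:
            raise InputError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise InputError("non-finite wavenumber values")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("non-finite intensity values")
        dx = np.diff(self.wavenumbers)
        if np.any(dx <= 0):
            raise InputError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(
        self, intensities: np.ndarray, stage: Stage | None = None, op: dict | None = None
    ) -> "Spectrum":
        """Copy of this spectrum with new intensities on the identical axis."""
        new = replace(
            self,
            wavenumbers=self.wavenumbers,  # bit-exact axis preservation
            intensities=np.asarray(intensities, dtype=float),
            stage=self.stage if stage is None else stage,
            meta=dict(self.meta),
        )
        if op is not None:
            new.meta.setdefault("ops", [])
            new.meta["ops"] = list(new.meta["ops"]) + [op]
        return new

    def crop(self, low: float, high: float) -> "Spectrum":
        mask = (self.wavenumbers >= low) & (self.wavenumbers <= high)
        if mask.sum() < 2:
            raise InputError(f"crop window [{low}, {high}] covers <2 points")
        return replace(
            self,
            wavenumbers=self.wavenumbers[mask],
            intensities=self.intensities[mask],
            meta=dict(self.meta),
        )


@dataclass
class SpectrumSet:
    """A collection of spectra with group structure."""

    spectra: list[Spectrum]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            groups: dict[str, list[str]] = {}
            for s in self.spectra:
                groups.setdefault(s.group, [])
                if s.sample_id not in groups[s.group]:
                    groups[s.group].append(s.sample_id)
            self.groups = groups
        self.validate()

    def validate(self) -> None:
        seen: dict[Modality, set[str]] = {}
        for s in self.spectra:
            ids = seen.setdefault(s.modality, set())
            if s.sample_id in ids:
                raise InputError(
                    f"duplicate sample_id {s.sample_id!r} for modality {s.modality.value}"
                )
            ids.add(s.sample_id)
        for g, members in self.groups.items():
            if not members:
                raise InputError(f"group {g!r} is empty")

    def by_modality(self, modality: Modality) -> list[Spectrum]:
        modality = Modality(modality)
        return [s for s in self.spectra if s.modality == modality]

    def get(self, sample_id: str, modality: Modality) -> Spectrum | None:
        modality = Modality(modality)
        for s in self.spectra:
            if s.sample_id == sample_id and s.modality == modality:
                return s
        return None

    def group_labels(self) -> list[str]:
        return list(self.groups.keys())


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    """Autodetect comma/tab/whitespace delimiter for one row."""
    if "," in line:
        return [f.strip() for f in line.split(",")]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return line.split()


def _parse_two_column(lines: Iterable[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    first_data_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_row(line)
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        numeric = all(_NUMERIC_RE.match(f) for f in fields[:2])
        if not numeric:
            if not first_data_seen:
                # one optional header row is tolerated
                first_data_seen = True
                continue
            raise ParseError(f"{path}: line {lineno}: non-numeric value in {fields[:2]}")
        first_data_seen = True
        xs.append(float(fields[0]))
        ys.append(float(fields[1]))
    return np.asarray(xs), np.asarray(ys)


def _parse_jcampdx_like(lines: Sequence[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX dialect: ##KEY=VALUE records and an (XY..XY) data block.

    Honors ##XFACTOR / ##YFACTOR multipliers and requires, if present,
    ##XUNITS to be 1/CM.
    """
    xfactor = 1.0
    yfactor = 1.0
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            body = line[2:]
            key, _, value = body.partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XUNITS" and value and value.upper() not in {"1/CM", "CM-1", "CM^-1"}:
                raise ParseError(f"{path}: line {lineno}: unsupported XUNITS {value!r}")
            elif key == "XFACTOR" and value:
                xfactor = float(value)
            elif key == "YFACTOR" and value:
                yfactor = float(value)
            elif key in {"XYDATA", "PEAKTABLE", "XYPOINTS"}:
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if not in_data:
            continue
        # data rows: "x,y" pairs, possibly several per line separated by ';'
        for pair in line.replace(";", " ").split():
            fields = pair.split(",") if "," in pair else [pair]
            if len(fields) == 1:
                fields = pair.split()
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: malformed XY pair {pair!r}")
            if not all(_NUMERIC_RE.match(f.strip()) for f in fields):
                raise ParseError(f"{path}: line {lineno}: non-numeric value in {fields}")
            xs.append(float(fields[0]) * xfactor)
            ys.append(float(fields[1]) * yfactor)
    return np.asarray(xs), np.asarray(ys)


def read_spectrum_table(
    path: str | Path,
    modality: Modality | str,
    dialect: str = "two_column",
    sample_id: str = "",
    group: str = "",
) -> Spectrum:
    """Read one spectrum from a text file.

    Parameters
    ----------
    path : str or Path
    modality : Modality
    dialect : {"two_column", "jcampdx_like"}
        ``two_column``: delimited x/y rows (comma, tab or whitespace; one
        optional header row).  ``jcampdx_like``: ``##KEY=`` records with an
        (XY..XY) data block and ``##XUNITS=1/CM``.

    Returns
    -------
    Spectrum
        stage=RAW, axis ascending (descending files are reversed).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"spectrum file not found: {path}")
    lines = path.read_text().splitlines()
    if dialect == "two_column":
        x, y = _parse_two_column(lines, str(path))
    elif dialect == "jcampdx_like":
        x, y = _parse_jcampdx_like(lines, str(path))
    else:
        raise InputError(f"unknown dialect {dialect!r}")
    if len(x) < 2:
        raise InputError(f"{path}: fewer than 2 data points")
    if len(np.unique(x)) != len(x):
        raise InputError(f"{path}: duplicate wavenumbers")
    if x[0] > x[-1]:
        x = x[::-1]
        y = y[::-1]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError(f"{path}: non-finite values")  # NaN is rejected, never imputed
    return Spectrum(
        wavenumbers=x,
        intensities=y,
        modality=Modality(modality),
        sample_id=sample_id or path.stem,
        group=group,
        stage=Stage.RAW,
    )


def write_spectrum_table(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV (wavenumber_cm1, intensity)."""
    df = pd.DataFrame({"wavenumber_cm1": s.wavenumbers, "intensity": s.intensities})
    write_table(df, path)


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write tabular results as CSV with deterministic float formatting.

    Round-trip guarantee: :func:`read_table` reproduces every numeric value
    to <=1e-9 relative error.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if df.empty:
        raise InputError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    return pd.read_csv(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest: columns sample_id, group, modality, path."""
    df = read_table(path)
    required = {"sample_id", "group", "modality", "path"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_spectrum_set(manifest_path: str | Path) -> SpectrumSet:
    """Load every spectrum referenced by a manifest into one SpectrumSet.

    Relative paths in the manifest resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise InputError(f"manifest entry {row['sample_id']!r}: file not found: {p}")
        spectra.append(
            read_spectrum_table(
                p,
                modality=row["modality"],
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
            )
        )
    return SpectrumSet(spectra=spectra)
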