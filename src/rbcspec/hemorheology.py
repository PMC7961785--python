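"""Ektacytometry elongation index and derived red-cell indices.

EI = (L - W) / (L + W) from the length and width of the laser diffraction
pattern; EImax is EI at the top of the shear-stress sweep (20 Pa).  CBC
records derive MCV, MCH and MCHC from HGB, HCT and RBC count via the
standard hematology identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rbcspec.errors import InputError
from rbcspec.spectra_io import read_table

__all__ = [
    "DeformabilityRecord",
    "CBCRecord",
    "elongation_index",
    "ei_max",
    "derive_cbc",
    "read_deformability_table",
]

logger = logging.getLogger(__name__)

# instruments may end the sweep at 19.8-20.0 Pa; anything below this is an
# incomplete sweep
MIN_TOP_SHEAR_PA = 19.5
SHEAR_RANGE_PA = (0.5, 20.0)


def elongation_index(L: float, W: float) -> float:
    """EI = (L - W) / (L + W).

    L and W are the diffraction-pattern length and width (same units).
    W > L is physically unexpected (axes can swap at low shear) and yields a
    negative EI with a logged warning rather than an error.
    """
    if L <= 0 or W <= 0:
        raise InputError(f"L and W must be positive, got L={L}, W={W}")
    if W > L:
        logger.warning("W (%g) > L (%g): negative elongation index", W, L)
    return (L - W) / (L + W)


@dataclass
class DeformabilityRecord:
    """One ektacytometry sweep: EI as a function of shear stress."""

    sample_id: str
    curve: list[tuple[float, float, float, float]]  # (shear_Pa, L, W, EI)
    group: str = ""

    def __post_init__(self) -> None:
        if not self.curve:
            raise InputError(f"{self.sample_id}: empty deformability curve")
        shear = np.array([p[0] for p in self.curve])
        if np.any(np.diff(shear) <= 0):
            raise InputError(f"{self.sample_id}: shear stresses must be strictly increasing")
        lo, hi = SHEAR_RANGE_PA
        if shear[0] < lo or shear[-1] > hi:
            raise InputError(
                f"{self.sample_id}: shear stresses outside [{lo}, {hi}] Pa"
            )
        for sigma, L, W, ei in self.curve:
            if L <= 0 or W <= 0:
                raise InputError(f"{self.sample_id}: non-positive L or W at {sigma} Pa")
            if not -1 < ei < 1:
                raise InputError(f"{self.sample_id}: EI {ei} outside (-1, 1)")

    @property
    def shear(self) -> np.ndarray:
        return np.array([p[0] for p in self.curve])

    @property
    def ei(self) -> np.ndarray:
        return np.array([p[3] for p in self.curve])


def ei_max(rec: DeformabilityRecord) -> float:
    """EI at the highest shear stress of the sweep.

    Errors if the sweep tops out below 19.5 Pa (incomplete sweep).
    """
    top_shear, _, _, top_ei = rec.curve[-1]
    if top_shear < MIN_TOP_SHEAR_PA:
        raise InputError(
            f"{rec.sample_id}: incomplete sweep; highest shear {top_shear} Pa "
            f"< {MIN_TOP_SHEAR_PA} Pa"
        )
    return top_ei


@dataclass(frozen=True)
class CBCRecord:
    """Complete blood count with derived red-cell indices.

    Units: HGB g/dL, HCT %, RBC 10^6/uL, MCV fL, MCH pg, MCHC g/dL, RDW %.
    """

    HGB: float
    HCT: float
    RBC: float
    MCV: float
    MCH: float
    MCHC: float
    RDW: float = float("nan")
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("HGB", "HCT", "RBC", "MCV", "MCH", "MCHC"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if abs(self.MCHC - 100.0 * self.HGB / self.HCT) > 1e-9 * self.MCHC:
            raise InputError("MCHC inconsistent with 100*HGB/HCT")
        if abs(self.MCV - 10.0 * self.HCT / self.RBC) > 1e-9 * self.MCV:
            raise InputError("MCV inconsistent with 10*HCT/RBC")
        if abs(self.MCH - 10.0 * self.HGB / self.RBC) > 1e-9 * self.MCH:
            raise InputError("MCH inconsistent with 10*HGB/RBC")


def derive_cbc(
    HGB: float, HCT: float, RBC: float, RDW: float = float("nan"),
    sample_id: str = "", group: str = "",
) -> CBCRecord:
    """Derive MCV, MCH, MCHC from HGB (g/dL), HCT (%), RBC (10^6/uL).

    MCV = 10*HCT/RBC (fL); MCH = 10*HGB/RBC (pg); MCHC = 100*HGB/HCT (g/dL).
    """
    if HGB <= 0 or HCT <= 0 or RBC <= 0:
        raise InputError(
            f"HGB, HCT, RBC must be positive, got {HGB}, {HCT}, {RBC}"
        )
    return CBCRecord(
        HGB=HGB, HCT=HCT, RBC=RBC,
        MCV=10.0 * HCT / RBC, MCH=10.0 * HGB / RBC, MCHC=100.0 * HGB / HCT,
        RDW=RDW, sample_id=sample_id, group=group,
    )


def read_deformability_table(path: str | Path) -> list[DeformabilityRecord]:
    """Read a deformability table.

    Accepted columns: (sample_id, shear_Pa, L, W) or (sample_id, shear_Pa,
    EI); when L and W are present EI is recomputed and cross-checked against
    any provided EI column (mismatch > 1e-6 is an error).  An optional
    ``group`` column is carried through.
    """
    df = read_table(path)
    cols = set(df.columns)
    if "sample_id" not in cols or "shear_Pa" not in cols:
        raise InputError(f"{path}: need columns sample_id and shear_Pa")
    has_lw = {"L", "W"} <= cols
    if not has_lw and "EI" not in cols:
        raise InputError(f"{path}: need either L,W columns or an EI column")
    records = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("shear_Pa")
        group = str(sub["group"].iloc[0]) if "group" in cols else ""
        curve = []
        for _, row in sub.iterrows():
            if has_lw:
                L, W = float(row["L"]), float(row["W"])
                ei = elongation_index(L, W)
                if "EI" in cols and np.isfinite(row["EI"]):
                    if abs(ei - float(row["EI"])) > 1e-6:
                        raise InputError(
                            f"{path}: sample {sample_id} at {row['shear_Pa']} Pa: "
                            f"EI column {row['EI']} inconsistent with (L-W)/(L+W)={ei:.6f}"
                        )
            else:
                ei = float(row["EI"])
                # synthesize L, W consistent with EI on a unit scale
                L, W = 1.0 + ei, 1.0 - ei
            curve.append((float(row["shear_Pa"]), L, W, ei))
        records.append(DeformabilityRecord(sample_id=str(sample_id), curve=curve, group=group))
    return records
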