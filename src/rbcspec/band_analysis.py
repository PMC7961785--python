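"""Marker-band integration and the biomarker ratio panel.

The default band library carries the published integration windows for the
FTIR and Raman marker bands of red-blood-cell membranes; windows printed as
(high-low) pairs are stored normalized as [low, high].  The ratio panel maps
band areas onto semi-quantitative biochemical indices (phospholipid content,
lipid unsaturation, acyl chain shortening, ...), each with its expected
direction of change under aging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rbcspec.errors import InputError, UsageError
from rbcspec.group_stats import GroupComparison, box_summary, mann_whitney_u
from rbcspec.spectra_io import Modality, Spectrum, SpectrumSet, Stage, write_table

__all__ = [
    "BandDefinition",
    "RatioDefinition",
    "default_band_library",
    "default_ratio_panel",
    "secondary_structure_panel",
    "integrate_band",
    "second_derivative_band_intensity",
    "compute_band_table",
    "compute_panel",
    "BiomarkerPanelResult",
    "write_band_library",
    "read_band_library",
]

logger = logging.getLogger(__name__)

UP, DOWN, NONE = "UP", "DOWN", "NONE"


@dataclass(frozen=True)
class BandDefinition:
    """A marker band and its integration window [low, high] in cm^-1."""

    name: str
    modality: Modality
    nominal_position: float
    window: tuple[float, float]
    assignment: str = ""

    def __post_init__(self) -> None:
        low, high = self.window
        if low >= high:
            object.__setattr__(self, "window", (high, low))
            low, high = self.window
        if high - low < 5:
            raise InputError(f"band {self.name!r}: window narrower than 5 cm^-1")
        object.__setattr__(self, "modality", Modality(self.modality))


@dataclass(frozen=True)
class RatioDefinition:
    """A named ratio (or sum) of band areas.

    ``numerator`` band areas are summed; likewise ``denominator``.  An empty
    denominator means the quantity is reported as a plain (summed) area —
    used for area-style indices such as total protein, the sum of the
    amide I and II areas.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()
    interpretation: str = ""
    expected_aging_direction: str = NONE

    def __post_init__(self) -> None:
        if not self.numerator:
            raise InputError(f"ratio {self.name!r}: empty numerator")
        if set(self.numerator) & set(self.denominator):
            raise InputError(f"ratio {self.name!r}: numerator and denominator overlap")
        if self.expected_aging_direction not in {UP, DOWN, NONE}:
            raise InputError(
                f"ratio {self.name!r}: bad direction {self.expected_aging_direction!r}"
            )


def default_band_library() -> list[BandDefinition]:
    """The built-in marker-band library.

    FTIR windows come from the published integration regions; bands in the
    CH-stretch region are named by their (self-consistent) windows because
    the printed peak labels conflict with them.  The 1738 cm^-1 ester C=O
    band has no printed window; a symmetric +-25 cm^-1 default is used and
    flagged in the assignment text.
    """
    F, R = Modality.FTIR, Modality.RAMAN
    return [
        BandDefinition("amide_I", F, 1651, (1605, 1687), "protein amide I"),
        BandDefinition("amide_II", F, 1544, (1502, 1560), "protein amide II"),
        BandDefinition("ch_window_A", F, 2855, (2847, 2863), "CH2 symmetric stretch region"),
        BandDefinition("ch_window_B", F, 2950, (2936, 2965), "CH3 asymmetric stretch region"),
        BandDefinition("po2_asym", F, 1236, (1214, 1261), "PO2- asymmetric stretch (phospholipids)"),
        BandDefinition("co_o_c", F, 1167, (1144, 1191), "-CO-O-C- stretch (cholesterol esters)"),
        BandDefinition(
            "ester_co_1738", F, 1738, (1713, 1763),
            "ester C=O stretch; default +-25 cm^-1 window (no published window)",
        ),
        BandDefinition("raman_ester_co", R, 1743, (1715, 1764), "C=O symmetric stretch (esters)"),
        BandDefinition("raman_cc", R, 1661, (1655, 1670), "C=C symmetric stretch (unsaturation)"),
        BandDefinition("raman_ch_def", R, 1447, (1420, 1480), "CH2/CH3 scissoring/bending"),
        BandDefinition("raman_phe", R, 1007, (990, 1015), "phenylalanine ring breathing"),
    ]


def default_ratio_panel(scenario: str = "dgal") -> list[RatioDefinition]:
    """The built-in biomarker panel.

    ``scenario`` selects the expected aging directions for the indices whose
    direction differs between D-galactose-induced and natural aging
    (cholesterol esters and total esterified lipids: DOWN in the D-gal
    model, UP in natural aging).
    """
    if scenario not in {"dgal", "natural"}:
        raise InputError(f"unknown scenario {scenario!r}")
    ester_dir = DOWN if scenario == "dgal" else UP
    return [
        RatioDefinition(
            "total_protein", ("amide_I", "amide_II"), (),
            "total protein as the sum of amide I and II areas", NONE,
        ),
        RatioDefinition(
            "amideII_over_amideI", ("amide_II",), ("amide_I",),
            "amide II to amide I ratio", NONE,
        ),
        RatioDefinition(
            "phospholipid", ("po2_asym",), (),
            "phospholipid content from the PO2- asymmetric stretch", DOWN,
        ),
        RatioDefinition(
            "acyl_shortening", ("ch_window_B",), ("ch_window_A",),
            "CH3/CH2 stretch ratio; rises with acyl chain shortening", UP,
        ),
        RatioDefinition(
            "cholesterol_esters", ("co_o_c",), (),
            "cholesterol esters from the -CO-O-C- stretch", ester_dir,
        ),
        RatioDefinition(
            "unsaturation", ("raman_cc",), ("raman_ch_def",),
            "lipid unsaturation: C=C 1661 over CH def 1447", DOWN,
        ),
        RatioDefinition(
            "esterified_lipids", ("raman_ester_co",), ("raman_phe",),
            "total esterified lipids: 1743 over 1007", ester_dir,
        ),
    ]


def secondary_structure_panel() -> list[tuple[str, float, float, str]]:
    """Second-derivative ratio definitions: (name, numerator position,
    denominator position, expected direction).  Positions in cm^-1 on the
    amide I region: 1650 alpha-helix, 1660 turns, 1640 unordered."""
    return [
        ("turns_over_helix", 1660.0, 1650.0, DOWN),
        ("unordered_over_helix", 1640.0, 1650.0, NONE),
    ]


def band_map(bands: Iterable[BandDefinition]) -> dict[str, BandDefinition]:
    out: dict[str, BandDefinition] = {}
    for b in bands:
        if b.name in out:
            raise InputError(f"duplicate band name {b.name!r}")
        out[b.name] = b
    return out


def integrate_band(
    s: Spectrum, b: BandDefinition, baseline: str = "none"
) -> float:
    """Trapezoidal band area over the band window (AU * cm^-1).

    ``baseline="local_linear"`` subtracts the chord between the window
    endpoints before integrating, removing any constant or linear local
    offset exactly.
    """
    if s.modality != b.modality:
        raise InputError(
            f"band {b.name!r} is {b.modality.value} but spectrum is {s.modality.value}"
        )
    low, high = b.window
    x, y = s.wavenumbers, s.intensities
    if x[0] > low or x[-1] < high:
        raise InputError(
            f"band {b.name!r}: window [{low}, {high}] not fully covered by "
            f"spectrum [{x[0]:.1f}, {x[-1]:.1f}]"
        )
    mask = (x >= low) & (x <= high)
    xw, yw = x[mask], y[mask]
    if baseline == "local_linear":
        chord = yw[0] + (yw[-1] - yw[0]) * (xw - xw[0]) / (xw[-1] - xw[0])
        yw = yw - chord
    elif baseline != "none":
        raise InputError(f"unknown band baseline {baseline!r}")
    return float(np.trapezoid(yw, xw))


def second_derivative_band_intensity(
    s2: Spectrum, position: float, halfwidth: float = 5.0
) -> float:
    """Magnitude of the negative second-derivative lobe around ``position``.

    Absorbance bands point downward in the second derivative; the integral
    of max(0, -d2A/dnu2) over [position-halfwidth, position+halfwidth] is
    returned, so a band at the query position yields a positive value.
    """
    if s2.stage != Stage.SECOND_DERIVATIVE:
        raise UsageError(
            f"expected a SECOND_DERIVATIVE spectrum, got stage {s2.stage.value}"
        )
    low, high = position - halfwidth, position + halfwidth
    x = s2.wavenumbers
    if x[0] > low or x[-1] < high:
        raise InputError(f"window [{low}, {high}] not covered by spectrum")
    mask = (x >= low) & (x <= high)
    lobe = np.maximum(0.0, -s2.intensities[mask])
    return float(np.trapezoid(lobe, x[mask]))


def compute_band_table(
    spectra: SpectrumSet,
    bands: Sequence[BandDefinition],
    baseline_ftir: str = "none",
    baseline_raman: str = "local_linear",
) -> pd.DataFrame:
    """Integrate every band over every matching-modality spectrum.

    Returns a long table (sample_id, group, modality, band, area).  Default
    local baselines: none for normalized FTIR absorbance, local_linear for
    Raman (residual offsets after rubberband correction).
    """
    rows = []
    for s in spectra.spectra:
        for b in bands:
            if b.modality != s.modality:
                continue
            baseline = baseline_ftir if b.modality == Modality.FTIR else baseline_raman
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "modality": s.modality.value,
                    "band": b.name,
                    "area": integrate_band(s, b, baseline=baseline),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BiomarkerPanelResult:
    """Panel output: per-sample values, group summaries, and tests."""

    values: pd.DataFrame  # columns: sample_id, group, ratio, value
    summaries: pd.DataFrame  # columns: ratio, group, n, median, q1, q3, min, max
    comparisons: pd.DataFrame  # ratio, n1, n2, U, p, stars, method, direction
    directions: dict[str, str] = field(default_factory=dict)

    def value_matrix(self) -> pd.DataFrame:
        return self.values.pivot(index="sample_id", columns="ratio", values="value")


def _ratio_values(
    band_table: pd.DataFrame, ratio: RatioDefinition
) -> pd.DataFrame | None:
    """Per-sample value of one ratio from the long band table."""
    wide = band_table.pivot_table(
        index=["sample_id", "group"], columns="band", values="area"
    )
    needed = set(ratio.numerator) | set(ratio.denominator)
    missing = needed - set(wide.columns)
    if missing:
        logger.warning("ratio %s: missing bands %s; skipped", ratio.name, sorted(missing))
        return None
    num = wide[list(ratio.numerator)].sum(axis=1)
    if ratio.denominator:
        den = wide[list(ratio.denominator)].sum(axis=1)
        vals = num / den
    else:
        vals = num
    out = vals.reset_index()
    out.columns = ["sample_id", "group", "value"]
    out = out.dropna(subset=["value"])
    out.insert(2, "ratio", ratio.name)
    return out


def compute_panel(
    spectra: SpectrumSet,
    spectra_2d: SpectrumSet | None = None,
    bands: Sequence[BandDefinition] | None = None,
    ratios: Sequence[RatioDefinition] | None = None,
    control_group: str = "control",
    treated_group: str = "treated",
    sd_halfwidth: float = 5.0,
) -> BiomarkerPanelResult:
    """Compute the full biomarker panel for a two-group cohort.

    Marker-band ratios are computed from ``spectra`` (PREPROCESSED); the
    secondary-structure ratios from ``spectra_2d`` (SECOND_DERIVATIVE FTIR)
    when given.  Group summaries are box-plot statistics (median, IQR,
    min-max); two-group comparison is the exact Mann-Whitney test where
    feasible.
    """
    bands = list(bands) if bands is not None else default_band_library()
    ratios = list(ratios) if ratios is not None else default_ratio_panel()
    bmap = band_map(bands)
    for r in ratios:
        unresolved = (set(r.numerator) | set(r.denominator)) - set(bmap)
        if unresolved:
            raise InputError(f"ratio {r.name!r} references unknown bands {sorted(unresolved)}")

    band_table = compute_band_table(spectra, bands)
    value_frames: list[pd.DataFrame] = []
    directions: dict[str, str] = {}
    for r in ratios:
        vals = _ratio_values(band_table, r)
        if vals is not None and not vals.empty:
            value_frames.append(vals)
            directions[r.name] = r.expected_aging_direction

    if spectra_2d is not None:
        sd_rows = []
        for s2 in spectra_2d.by_modality(Modality.FTIR):
            mags = {
                pos: second_derivative_band_intensity(s2, pos, sd_halfwidth)
                for pos in (1640.0, 1650.0, 1660.0)
            }
            for name, num_pos, den_pos, _direction in secondary_structure_panel():
                den = mags[den_pos]
                if den == 0:
                    logger.warning("%s: zero denominator lobe for %s", name, s2.sample_id)
                    continue
                sd_rows.append(
                    {
                        "sample_id": s2.sample_id,
                        "group": s2.group,
                        "ratio": name,
                        "value": mags[num_pos] / den,
                    }
                )
        if sd_rows:
            value_frames.append(pd.DataFrame(sd_rows))
            for name, _n, _d, direction in secondary_structure_panel():
                directions[name] = direction

    if not value_frames:
        raise InputError("no ratio could be computed from the provided spectra")
    values = pd.concat(value_frames, ignore_index=True)

    summaries = []
    comparisons = []
    for ratio_name, sub in values.groupby("ratio", sort=False):
        for grp, gsub in sub.groupby("group", sort=True):
            bs = box_summary(gsub["value"].to_numpy())
            summaries.append(
                {
                    "ratio": ratio_name, "group": grp, "n": bs.n,
                    "median": bs.median, "q1": bs.q1, "q3": bs.q3,
                    "min": bs.min, "max": bs.max,
                }
            )
        x = sub.loc[sub["group"] == control_group, "value"].to_numpy()
        y = sub.loc[sub["group"] == treated_group, "value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            logger.warning("ratio %s: a group has n<2; test skipped", ratio_name)
            continue
        cmp: GroupComparison = mann_whitney_u(x, y)
        med_diff = float(np.median(y) - np.median(x))
        comparisons.append(
            {
                "ratio": ratio_name,
                "n1": cmp.n1, "n2": cmp.n2,
                "median_control": float(np.median(x)),
                "median_treated": float(np.median(y)),
                "direction": "UP" if med_diff > 0 else ("DOWN" if med_diff < 0 else "NONE"),
                "U": cmp.U, "p": cmp.p_two_sided,
                "stars": cmp.stars, "method": cmp.method,
            }
        )
    return BiomarkerPanelResult(
        values=values.sort_values(["ratio", "group", "sample_id"]).reset_index(drop=True),
        summaries=pd.DataFrame(summaries),
        comparisons=pd.DataFrame(comparisons),
        directions=directions,
    )


def write_band_library(bands: Sequence[BandDefinition], path: str | Path) -> None:
    """Serialize a band library as an editable table."""
    rows = [
        {
            "name": b.name,
            "modality": b.modality.value,
            "low": b.window[0],
            "high": b.window[1],
            "nominal_position": b.nominal_position,
            "assignment": b.assignment,
        }
        for b in bands
    ]
    write_table(rows, path)


def read_band_library(path: str | Path) -> list[BandDefinition]:
    df = pd.read_csv(path)
    required = {"name", "modality", "low", "high"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"band library {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            BandDefinition(
                name=str(row["name"]),
                modality=Modality(row["modality"]),
                nominal_position=float(row.get("nominal_position", (row["low"] + row["high"]) / 2)),
                window=(float(row["low"]), float(row["high"])),
                assignment=str(row.get("assignment", "")),
            )
        )
    return out
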