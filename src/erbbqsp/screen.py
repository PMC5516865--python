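"""Ligand-screen plate normalization and viability AUC fold-changes.

The ligand screen asks which growth factors activate Akt in a cell line:
each plate carries replicate p-Akt measurements per ligand plus a human
serum albumin (HSA) vehicle control.  Normalization is
median-over-replicates, HSA-median subtraction, then division by the
largest background-subtracted signal in the cell line, so the most potent
ligand scores exactly 1 and ligands below background go negative (kept:
they carry suppression information).

Viability dose-response curves (relative to media control) are compared
through the trapezoidal area under the curve over log10-dose; the AUC
fold-change of a curve against a reference quantifies how a ligand or
drug shifts overall drug sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenPlate",
    "ViabilityCurve",
    "ScreenError",
    "normalize_ligand_screen",
    "screen_heatmap_matrix",
    "viability_auc_foldchange",
]

HSA_CONTROL = "HSA"


class ScreenError(ValueError):
    pass


@dataclass
class ScreenPlate:
    """One cell line's plate: replicate p-Akt values per ligand.

    ``measurements`` columns: ligand, replicate, value (assay units >= 0);
    the HSA control ligand must be present.
    """

    cell_line: str
    measurements: pd.DataFrame
    control_ligand: str = HSA_CONTROL

    def __post_init__(self):
        df = self.measurements
        missing = {"ligand", "replicate", "value"} - set(df.columns)
        if missing:
            raise ScreenError(f"missing columns: {sorted(missing)}")
        if (df["value"] < 0).any():
            raise ScreenError("assay values must be >= 0")
        if self.control_ligand not in set(df["ligand"]):
            raise ScreenError(f"control ligand {self.control_ligand!r} absent")
        if (df.groupby("ligand")["value"].count() < 1).any():
            raise ScreenError("every ligand needs >= 1 replicate")


def normalize_ligand_screen(plate: ScreenPlate) -> pd.Series:
    """Per-ligand normalized activation in (-inf, 1].

    Replicates are aggregated by median, the median HSA signal subtracted,
    and the result divided by the maximum background-subtracted signal in
    the plate.  An unresponsive plate (no ligand above background) raises,
    flagging the cell line rather than emitting noise.
    """
    medians = plate.measurements.groupby("ligand")["value"].median()
    background = medians[plate.control_ligand]
    centered = medians - background
    top = centered.max()
    if top <= 0:
        raise ScreenError(
            f"cell line {plate.cell_line!r} unresponsive: no ligand above the HSA control"
        )
    return centered / top


def screen_heatmap_matrix(plates) -> pd.DataFrame:
    """Cell-line x ligand matrix of normalized screen values."""
    rows = {}
    for plate in plates:
        rows[plate.cell_line] = normalize_ligand_screen(plate)
    return pd.DataFrame(rows).T


@dataclass
class ViabilityCurve:
    """Relative viability (media-control normalized) along a dose grid."""

    drug: str
    condition: str  # e.g. "alone", "+HRG", "+HRG+blocker"
    doses: np.ndarray  # nmol/l, increasing
    relative_viability: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.relative_viability = np.asarray(self.relative_viability, float)
        if np.any(np.diff(self.doses) <= 0):
            raise ScreenError("doses must be strictly increasing")
        if np.any(self.relative_viability < 0):
            raise ScreenError("relative viability must be >= 0")
        if len(self.doses) != len(self.relative_viability):
            raise ScreenError("doses and viabilities must have equal length")


def viability_auc_foldchange(curve: ViabilityCurve, reference: ViabilityCurve) -> float:
    """AUC(curve) / AUC(reference), trapezoidal over log10-dose.

    Both curves must share the dose grid; the ratio is invariant to any
    common rescaling of the two curves.
    """
    if not np.array_equal(curve.doses, reference.doses):
        raise ScreenError("curves measured on different dose grids")
    x = np.log10(curve.doses)
    auc = np.trapezoid(curve.relative_viability, x)
    auc_ref = np.trapezoid(reference.relative_viability, x)
    if auc_ref == 0:
        raise ScreenError("reference curve has zero AUC")
    return float(auc / auc_ref)
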