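"""Synthetic datasets with the statistical structure the analyses assume.

Every generator is a pure, seeded function, and every dataset it emits is
paired with the generating truth, so each pipeline stage can be tested as
a closed loop (generate -> analyze -> recover the truth):

* dose-time phospho matrices: simulated network output with relative
  (multiplicative Gaussian or lognormal) noise — assay CVs are relative;
* serum PK profiles: simulated concentrations with lognormal noise and
  left-censoring at an assay quantification limit (censored records are
  dropped, not imputed, before fitting);
* caliper tumor studies: per-mouse lognormal starting volumes around
  200 mm³, exponential group growth, additive log-scale residual noise,
  with widths/lengths back-derived through the caliper formula;
* ligand-screen plates: HSA baseline plus designed ligand effects with
  three technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import READOUTS, DoseTimeMatrix, simulate_matrix
from .network_model import ReactionNetwork, ValidationError
from .pkpd import DoseSchedule, PKParams, SerumProfile, simulate_pk
from .screen import HSA_CONTROL, ScreenPlate
from .tumor_growth import CALIPER_FACTOR, TumorStudy

__all__ = [
    "NoiseSpec",
    "gen_dose_time_matrix",
    "gen_pk_dataset",
    "gen_tumor_study",
    "gen_screen_plate",
    "PK_SAMPLING_TIMES_H",
    "PK_DOSE_GROUPS_UG",
]

#: serum sampling schedule (hours post-dose) of the single-dose PK study
PK_SAMPLING_TIMES_H = (1.0, 4.0, 8.0, 24.0, 48.0, 72.0, 96.0, 168.0)
#: single-dose groups (µg/mouse)
PK_DOSE_GROUPS_UG = (150.0, 300.0, 600.0)


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "gaussian-relative"  # or "lognormal"
    scale: float = 0.05  # relative SD
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian-relative", "lognormal"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return np.asarray(values, float).copy()
        if self.kind == "gaussian-relative":
            noisy = values * (1.0 + self.scale * rng.standard_normal(np.shape(values)))
            return np.maximum(noisy, 0.0)
        return values * rng.lognormal(0.0, self.scale, np.shape(values))


def gen_dose_time_matrix(
    network: ReactionNetwork,
    params_true: dict,
    grid: dict,
    noise: NoiseSpec,
    readouts=READOUTS,
):
    """Noisy dose-time matrices for each ligand plus the generating truth.

    ``grid`` maps ligand -> (doses, times); each ligand needs at least 3
    doses and 4 times.  Returns ``(matrices, truth)`` where ``matrices``
    maps ligand -> noisy DoseTimeMatrix and ``truth`` carries the true
    parameter overrides and the noise-free matrices.
    """
    rng = np.random.default_rng(noise.seed)
    net = network.with_parameters(params_true) if params_true else network
    clean, noisy = {}, {}
    for ligand, (doses, times) in sorted(grid.items()):
        if len(doses) < 3 or len(times) < 4:
            raise ValidationError("grid needs >= 3 doses and >= 4 times per ligand")
        m = simulate_matrix(net, ligand, doses, times, readouts)
        clean[ligand] = m
        noisy[ligand] = DoseTimeMatrix(
            m.readouts, m.ligand, m.doses, m.times, noise.apply(m.values, rng)
        )
    truth = {"params_true": dict(params_true), "clean_matrices": clean}
    return noisy, truth


def gen_pk_dataset(
    pk_true: PKParams,
    dose_groups=PK_DOSE_GROUPS_UG,
    times=PK_SAMPLING_TIMES_H,
    noise: NoiseSpec = NoiseSpec("lognormal", 0.10, 0),
    *,
    lloq_ug_ml: float = 0.1,
):
    """Noisy single-dose serum profiles with assay-limit censoring.

    Concentrations below ``lloq_ug_ml`` (lower limit of quantification)
    are dropped from the profile, mimicking dose groups falling under
    assay sensitivity.  Raises when censoring removes everything.
    """
    if len(dose_groups) < 2:
        raise ValidationError("need >= 2 dose groups")
    rng = np.random.default_rng(noise.seed)
    profiles = []
    for dose in dose_groups:
        clean = simulate_pk(pk_true, DoseSchedule.single(dose, max(times)), times)
        conc = noise.apply(clean.concentrations, rng)
        keep = conc >= lloq_ug_ml
        profiles.append(SerumProfile(np.asarray(times)[keep], conc[keep], dose))
    if all(len(p.times) == 0 for p in profiles):
        raise ValidationError("censoring limit removed every record")
    return profiles


def gen_tumor_study(
    k_by_group: dict,
    intercept_sd: float = 0.3,
    residual_sd: float = 0.1,
    n_mice: int = 8,
    days=tuple(np.arange(0.0, 22.0, 3.5)),
    seed: int = 0,
    *,
    control_group: str = "PBS",
    baseline_mm3: float = 200.0,
    aspect_ratio: float = 1.25,
) -> TumorStudy:
    """Exponential-growth caliper study with mouse-level random intercepts.

    Per-mouse log initial volume ~ Normal(log 200 mm³, intercept_sd);
    log-volume then grows linearly at the group rate with Gaussian
    residuals (residual_sd) per measurement — twice-weekly caliper days by
    default.  Width and length are back-derived so that
    width² x length x 0.52 reproduces the volume exactly, with a fixed
    length/width aspect ratio.
    """
    if control_group not in k_by_group:
        raise ValidationError(f"control group {control_group!r} missing from k_by_group")
    if n_mice < 2:
        raise ValidationError("need >= 2 mice per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group, k in sorted(k_by_group.items()):
        for m in range(n_mice):
            mouse = f"{group}-{m + 1:02d}"
            log_v0 = np.log(baseline_mm3) + intercept_sd * rng.standard_normal()
            for day in days:
                log_v = log_v0 + k * day + residual_sd * rng.standard_normal()
                volume = float(np.exp(log_v))
                width = (volume / (CALIPER_FACTOR * aspect_ratio)) ** (1.0 / 3.0)
                length = aspect_ratio * width
                rows.append((mouse, group, float(day), width, length, volume))
    records = pd.DataFrame(
        rows, columns=["mouse_id", "group", "day", "width_mm", "length_mm", "volume_mm3"]
    )
    return TumorStudy(records, control_group=control_group)


def gen_screen_plate(
    cell_profiles: dict,
    noise: NoiseSpec = NoiseSpec("gaussian-relative", 0.05, 0),
    seed: int | None = None,
    *,
    ligands=None,
    baseline: float = 10.0,
    replicates: int = 3,
):
    """Screen plates from designed responsiveness profiles.

    ``cell_profiles`` maps cell line -> {ligand: effect size in baseline
    units}; every plate carries the HSA control at baseline and
    ``replicates`` technical replicates per ligand.  ``ligands`` fixes the
    full ligand panel (defaults to the union of profiled ligands).
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    if ligands is None:
        panel = set()
        for effects in cell_profiles.values():
            panel |= set(effects)
        ligands = sorted(panel)
    plates = []
    for cell_line, effects in sorted(cell_profiles.items()):
        rows = []
        for ligand in [HSA_CONTROL] + [l for l in ligands if l != HSA_CONTROL]:
            level = baseline + float(effects.get(ligand, 0.0))
            values = noise.apply(np.full(replicates, level), rng)
            for rep, v in enumerate(values, start=1):
                rows.append((ligand, rep, float(v)))
        plates.append(ScreenPlate(
            cell_line, pd.DataFrame(rows, columns=["ligand", "replicate", "value"])
        ))
    return plates
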