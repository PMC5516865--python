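"""Xenograft growth-rate estimation, %TGI and Bliss-independence calls.

Tumor volumes from caliper measurements (volume = width² x length x 0.52)
grow exponentially in these models, so log-volume is linear in time.  The
group growth rate k (1/day) is estimated by a linear mixed-effects model —
log V ~ group-specific slope over time, with a random intercept per mouse —
which pools mice without letting big or small starters bias the slope.
Treatment effect is summarized as percent tumor growth-rate inhibition,

    %TGI_i = (k_PBS - k_i) / k_PBS x 100,

which exceeds 100% for regressing tumors, and combinations are judged
against the Bliss-independence expectation f_AB = f_A + f_B - f_A f_B on
the fractional inhibitions f = TGI/100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CALIPER_FACTOR",
    "TumorStudy",
    "GrowthRates",
    "SynergyResult",
    "TumorInputError",
    "caliper_volume",
    "fit_growth_rates",
    "tgi_percent",
    "bliss_expected_tgi",
]

CALIPER_FACTOR = 0.52
#: floor applied to volumes before log-transform (mm^3)
VOLUME_FLOOR_MM3 = 1.0


class TumorInputError(ValueError):
    pass


def caliper_volume(width_mm: float, length_mm: float) -> float:
    """Ellipsoid-approximation tumor volume: width² x length x 0.52 (mm³).

    By convention ``width`` is the smaller caliper dimension.
    """
    if width_mm <= 0 or length_mm <= 0:
        raise TumorInputError("caliper dimensions must be positive")
    if width_mm > length_mm:
        raise TumorInputError("width must not exceed length (convention)")
    return width_mm ** 2 * length_mm * CALIPER_FACTOR


@dataclass
class TumorStudy:
    """Longitudinal caliper records; one row per mouse per measurement day.

    ``records`` columns: mouse_id, group, day, width_mm, length_mm and/or
    volume_mm3 (derived through the caliper formula when absent).
    """

    records: pd.DataFrame
    control_group: str = "PBS"

    def __post_init__(self):
        df = self.records.copy()
        if "volume_mm3" not in df.columns:
            df["volume_mm3"] = [
                caliper_volume(w, l) for w, l in zip(df["width_mm"], df["length_mm"])
            ]
        required = {"mouse_id", "group", "day", "volume_mm3"}
        missing = required - set(df.columns)
        if missing:
            raise TumorInputError(f"missing columns: {sorted(missing)}")
        if (df["day"] < 0).any():
            raise TumorInputError("days must be >= 0")
        if self.control_group not in set(df["group"]):
            raise TumorInputError(f"control group {self.control_group!r} absent")
        counts = df.groupby("mouse_id")["day"].count()
        if (counts < 2).any():
            raise TumorInputError("every mouse needs >= 2 observations")
        self.records = df

    @property
    def groups(self):
        return sorted(set(self.records["group"]))


@dataclass
class GrowthRates:
    rates: dict  # group -> k (1/day)
    standard_errors: dict
    random_effects: dict  # mouse_id -> intercept deviation (mixed model only)
    model: str  # "mixed" | "per-mouse-OLS"
    control_group: str

    def tgi(self, group: str) -> float:
        return tgi_percent(self.rates[self.control_group], self.rates[group])


def _log_volumes(study: TumorStudy) -> pd.DataFrame:
    df = study.records.copy()
    floored = df["volume_mm3"] < VOLUME_FLOOR_MM3
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} volume(s) below {VOLUME_FLOOR_MM3} mm^3 floored before log",
            stacklevel=3,
        )
    df["log_volume"] = np.log(df["volume_mm3"].clip(lower=VOLUME_FLOOR_MM3))
    return df


def _per_mouse_ols(df: pd.DataFrame, groups) -> tuple[dict, dict]:
    rates, ses = {}, {}
    for group in groups:
        slopes = []
        for _, sub in df[df["group"] == group].groupby("mouse_id"):
            slope = np.polyfit(sub["day"], sub["log_volume"], 1)[0]
            slopes.append(slope)
        slopes = np.asarray(slopes)
        rates[group] = float(np.mean(slopes))
        ses[group] = float(np.std(slopes, ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else float("nan")
    return rates, ses


def fit_growth_rates(study: TumorStudy, method: str = "mixed", *, random_slope: bool = False) -> GrowthRates:
    """Estimate per-group exponential growth rates k (1/day).

    ``method="mixed"`` (default): restricted-likelihood linear mixed model
    on log-volume with group-specific fixed slopes and a random intercept
    per mouse (optionally a random slope).  A singular or non-converging
    fit falls back to the per-mouse OLS average with a warning, never
    silently.  ``method="per-mouse"`` uses the fallback estimator directly.
    """
    df = _log_volumes(study)
    groups = study.groups
    if method == "per-mouse":
        rates, ses = _per_mouse_ols(df, groups)
        return GrowthRates(rates, ses, {}, "per-mouse-OLS", study.control_group)
    if method != "mixed":
        raise TumorInputError(f"unknown method {method!r}")

    import statsmodels.formula.api as smf

    re_formula = "~day" if random_slope else "1"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "log_volume ~ 0 + C(group) + C(group):day",
                df, groups=df["mouse_id"], re_formula=re_formula,
            )
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite mixed-model parameters")
    except Exception as err:  # singular fits surface in several guises
        warnings.warn(f"mixed model failed ({err}); falling back to per-mouse OLS", stacklevel=2)
        rates, ses = _per_mouse_ols(df, groups)
        return GrowthRates(rates, ses, {}, "per-mouse-OLS", study.control_group)

    rates, ses = {}, {}
    for group in groups:
        key = f"C(group)[{group}]:day"
        rates[group] = float(fit.params[key])
        ses[group] = float(fit.bse[key])
    random_effects = {
        mouse: float(np.asarray(re).ravel()[0]) for mouse, re in fit.random_effects.items()
    }
    return GrowthRates(rates, ses, random_effects, "mixed", study.control_group)


def tgi_percent(k_control: float, k_treatment: float) -> float:
    """Percent tumor growth-rate inhibition relative to control.

    ``(k_control - k_treatment) / k_control x 100``; exceeds 100% when the
    treated tumors regress (negative k).
    """
    if k_control == 0:
        raise TumorInputError("control growth rate is zero; %TGI undefined")
    return (k_control - k_treatment) / k_control * 100.0


@dataclass(frozen=True)
class SynergyResult:
    tgi_a: float
    tgi_b: float
    tgi_combo_observed: float
    tgi_combo_bliss: float
    call: str  # synergistic | additive | sub-additive
    tolerance: float


def bliss_expected_tgi(
    tgi_a: float,
    tgi_b: float,
    tgi_combo_observed: float,
    tolerance: float = 5.0,
) -> SynergyResult:
    """Bliss-independence expectation for a combination, and the call.

    Fractional inhibitions ``f = tgi/100`` combine as
    ``f_AB = f_A + f_B - f_A f_B`` (reported x100).  Fractions above 1
    (tumor regression) are passed through unclamped with a warning, since
    the expectation loses its probabilistic reading there.  The call is
    ``synergistic`` when the observed combination beats the expectation by
    more than ``tolerance`` percentage points, ``sub-additive`` when it
    falls short by more, else ``additive``.
    """
    for v in (tgi_a, tgi_b, tgi_combo_observed):
        if not np.isfinite(v):
            raise TumorInputError("TGI inputs must be finite")
    fa, fb = tgi_a / 100.0, tgi_b / 100.0
    if fa > 1 or fb > 1:
        warnings.warn(
            "single-agent TGI exceeds 100%; Bliss expectation is not "
            "probabilistically interpretable and is reported unclamped",
            stacklevel=2,
        )
    expected = (fa + fb - fa * fb) * 100.0
    if tgi_combo_observed > expected + tolerance:
        call = "synergistic"
    elif tgi_combo_observed < expected - tolerance:
        call = "sub-additive"
    else:
        call = "additive"
    return SynergyResult(tgi_a, tgi_b, tgi_combo_observed, expected, call, tolerance)
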