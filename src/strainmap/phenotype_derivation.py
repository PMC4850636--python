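"""Strain-level phenotype values from raw behavioural measurements.

Implements the closed-form behavioural endpoints — percent maximal
possible effect (%MPE) from withdrawal latencies, percent weight change,
hyperalgesia as fraction of baseline threshold / percent decrease — and
the cumulative morphine dose-response ED50 fit.  Tolerance is the fold
change of the post- vs pre-treatment ED50.

The dose-response model is a two-parameter log-logistic (Hill) curve
with asymptotes fixed at 0 and 100 %MPE:

    %MPE(d) = 100 / (1 + (ED50 / d) ** h)

fitted by least squares over the positive doses; dose 0 anchors the
lower asymptote and is excluded from the log transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AnalgesiaMeasurement",
    "DoseResponseCurve",
    "WeightRecord",
    "OihRecord",
    "Ed50Fit",
    "Ed50FitError",
    "DEFAULT_DOSES",
    "percent_mpe",
    "fit_ed50",
    "tolerance_fold_change",
    "oih_change",
    "percent_weight_change",
    "derive_phenotypes",
    "TRAIT_NAMES",
]

#: Cumulative morphine doses (mg/kg s.c.) of the standard protocol.
DEFAULT_DOSES = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

#: The six strain-level traits produced by :func:`derive_phenotypes`.
TRAIT_NAMES = (
    "mechanical_oih",
    "thermal_oih",
    "tailflick_oih",
    "tolerance",
    "dependence",
    "weight_change",
)


class Ed50FitError(RuntimeError):
    """The dose-response fit failed; diagnostics in ``args``."""


@dataclass(frozen=True)
class AnalgesiaMeasurement:
    baseline_latency: float  # seconds
    measured_latency: float  # seconds
    cutoff_latency: float  # seconds

    def __post_init__(self) -> None:
        if not (self.cutoff_latency > self.baseline_latency > 0):
            raise ValueError(
                "need cutoff_latency > baseline_latency > 0, got "
                f"cutoff={self.cutoff_latency}, baseline={self.baseline_latency}"
            )
        if not (0 <= self.measured_latency <= self.cutoff_latency):
            raise ValueError(
                f"measured latency {self.measured_latency} outside "
                f"[0, {self.cutoff_latency}]"
            )


@dataclass
class Ed50Fit:
    ed50: float  # mg/kg
    hill_slope: float
    residual_ss: float
    n_points: int


@dataclass
class DoseResponseCurve:
    doses: tuple[float, ...]  # cumulative mg/kg, strictly increasing
    mpe: tuple[float, ...]  # %MPE per dose, clamped to [0, 100]
    ed50: float
    hill_slope: float

    def __post_init__(self) -> None:
        d = np.asarray(self.doses)
        if (np.diff(d) <= 0).any() or (d < 0).any():
            raise ValueError("doses must be non-negative, strictly increasing")
        if any(not (0 <= m <= 100) for m in self.mpe):
            raise ValueError("%MPE values must lie in [0, 100]")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")


@dataclass
class WeightRecord:
    initial_weight: float  # grams
    final_weight: float  # grams
    percent_change: float

    def __post_init__(self) -> None:
        if self.initial_weight <= 0:
            raise ValueError("initial weight must be positive")
        expected = (
            (self.final_weight - self.initial_weight) / self.initial_weight * 100
        )
        if self.percent_change != expected:
            raise ValueError("percent_change inconsistent with weights")


@dataclass
class OihRecord:
    baseline_threshold: float
    post_threshold: float
    fraction_of_baseline: float
    percent_decrease: float


def percent_mpe(m: AnalgesiaMeasurement) -> float:
    """[(measured - baseline) / (cutoff - baseline)] x 100, clamped to [0, 100]."""
    value = (
        (m.measured_latency - m.baseline_latency)
        / (m.cutoff_latency - m.baseline_latency)
        * 100.0
    )
    return min(100.0, max(0.0, value))


def _hill(d: np.ndarray, log_ed50: float, log_h: float) -> np.ndarray:
    # %MPE(d) = 100 / (1 + (ED50/d)^h), parameterised in logs to keep
    # ED50 and h positive during optimisation
    h = np.exp(log_h)
    return 100.0 / (1.0 + np.exp(h * (log_ed50 - np.log(d))))


def fit_ed50(
    curve_doses: Sequence[float], curve_mpe: Sequence[float]
) -> Ed50Fit:
    """Least-squares log-logistic fit of %MPE over positive doses.

    Raises :class:`Ed50FitError` on non-convergence, a flat curve (no
    information) or a monotonically decreasing curve (inverted).
    """
    doses = np.asarray(curve_doses, dtype=float)
    mpe = np.asarray(curve_mpe, dtype=float)
    if len(doses) != len(mpe):
        raise ValueError("doses and mpe lengths differ")
    if len(doses) < 4:
        raise ValueError("need at least 4 dose points")
    pos = doses > 0
    d, y = doses[pos], mpe[pos]
    if len(d) < 3:
        raise ValueError("need at least 3 positive doses")
    if np.ptp(mpe) == 0:
        raise Ed50FitError("all %MPE values identical: no dose information")
    if np.all(np.diff(y) <= 0) and y[0] > y[-1]:
        raise Ed50FitError("monotonically decreasing %MPE: inverted curve")
    # initial ED50: dose where the curve crosses 50 %MPE (log interpolation)
    if y.min() < 50 < y.max():
        ed50_0 = float(np.exp(np.interp(50.0, y, np.log(d))))
    else:
        ed50_0 = float(np.exp(np.mean(np.log(d))))
    p0 = (math.log(ed50_0), 0.0)
    try:
        popt, _ = curve_fit(
            _hill, d, y, p0=p0, maxfev=20000, xtol=1e-14, ftol=1e-14
        )
    except RuntimeError as exc:
        raise Ed50FitError(
            f"dose-response fit did not converge: {exc}",
            {"doses": d.tolist(), "mpe": y.tolist(), "p0": p0},
        ) from None
    ed50 = float(np.exp(popt[0]))
    hill = float(np.exp(popt[1]))
    rss = float(np.sum((y - _hill(d, *popt)) ** 2))
    return Ed50Fit(ed50=ed50, hill_slope=hill, residual_ss=rss, n_points=len(d))


def tolerance_fold_change(ed50_post: float, ed50_pre: float) -> float:
    """Fold change in morphine ED50: post / pre."""
    if ed50_post <= 0 or ed50_pre <= 0:
        raise ValueError("ED50 values must be positive")
    return ed50_post / ed50_pre


def oih_change(baseline_threshold: float, post_threshold: float) -> OihRecord:
    """Hyperalgesia as fraction of baseline and percent decrease.

    Hypoalgesia (post > baseline) gives a negative percent decrease and
    is passed through unclamped.
    """
    if baseline_threshold <= 0:
        raise ValueError("baseline threshold must be positive")
    if post_threshold < 0:
        raise ValueError("post threshold must be non-negative")
    fraction = post_threshold / baseline_threshold
    return OihRecord(
        baseline_threshold=baseline_threshold,
        post_threshold=post_threshold,
        fraction_of_baseline=fraction,
        percent_decrease=(1.0 - fraction) * 100.0,
    )


def percent_weight_change(initial: float, final: float) -> float:
    """((final - initial) / initial) x 100."""
    if initial <= 0:
        raise ValueError("initial weight must be positive")
    return (final - initial) / initial * 100.0


# ---------------------------------------------------------------------------
# long-format behavioural records -> strain x trait table
# ---------------------------------------------------------------------------

# long format columns: strain, assay, phase, dose, value
_OIH_ASSAYS = {
    "mechanical_oih": "mech_threshold",
    "thermal_oih": "thermal_hindpaw_latency",
    "tailflick_oih": "tailflick_oih_latency",
}


def derive_phenotypes(
    records: pd.DataFrame, cutoff_latency: float = 10.0
) -> pd.DataFrame:
    """Derive the six strain-level traits from long-format records.

    Expected rows per strain (columns ``strain, assay, phase, dose, value``):

    * ``tailflick_latency`` / phase ``pre``/``post`` at each cumulative
      dose (dose 0 is the baseline latency) -> ED50 fits -> ``tolerance``
      fold change,
    * ``mech_threshold``, ``thermal_hindpaw_latency``,
      ``tailflick_oih_latency`` / phase ``baseline``/``post`` -> fraction
      of baseline (the hyperalgesia traits),
    * ``weight`` / phase ``initial``/``final`` -> ``weight_change`` (%),
    * ``jumps`` -> ``dependence`` (count, pass-through).
    """
    required = {"strain", "assay", "phase", "dose", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"behaviour records missing column(s): {sorted(missing)}")
    rows = {}
    for strain, grp in records.groupby("strain", sort=True):
        traits: dict[str, float] = {}
        # hyperalgesia traits: fraction of baseline
        for trait, assay in _OIH_ASSAYS.items():
            sub = grp[grp["assay"] == assay]
            if sub.empty:
                continue
            base = float(sub.loc[sub["phase"] == "baseline", "value"].iloc[0])
            post = float(sub.loc[sub["phase"] == "post", "value"].iloc[0])
            traits[trait] = oih_change(base, post).fraction_of_baseline
        # tolerance: ED50 fold change from pre/post dose-response curves
        tf = grp[grp["assay"] == "tailflick_latency"]
        if not tf.empty:
            ed50 = {}
            for phase in ("pre", "post"):
                sub = tf[tf["phase"] == phase].sort_values("dose")
                doses = sub["dose"].to_numpy(dtype=float)
                lat = sub["value"].to_numpy(dtype=float)
                if len(doses) == 0 or doses[0] != 0:
                    raise ValueError(
                        f"strain {strain}: {phase} curve needs a dose-0 baseline"
                    )
                baseline = lat[0]
                mpe = [
                    percent_mpe(
                        AnalgesiaMeasurement(baseline, l, cutoff_latency)
                    )
                    for l in lat[1:]
                ]
                ed50[phase] = fit_ed50(doses[1:], mpe).ed50
            traits["tolerance"] = tolerance_fold_change(
                ed50["post"], ed50["pre"]
            )
        w = grp[grp["assay"] == "weight"]
        if not w.empty:
            initial = float(w.loc[w["phase"] == "initial", "value"].iloc[0])
            final = float(w.loc[w["phase"] == "final", "value"].iloc[0])
            traits["weight_change"] = percent_weight_change(initial, final)
        j = grp[grp["assay"] == "jumps"]
        if not j.empty:
            traits["dependence"] = float(j["value"].iloc[0])
        rows[strain] = traits
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "strain"
    order = [t for t in TRAIT_NAMES if t in frame.columns]
    return frame[order]
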