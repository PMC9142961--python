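"""Tumor growth and survival endpoints for xenograft therapy studies.

Tumor volume from caliper radii uses the ellipsoid model V = (4/3)π·a·b·c.
Growth rate is summarized as the doubling time ln 2 / slope from a
log-linear fit of volume against study day; animals whose tumors shrink
(slope ≤ 0) are flagged as excluded from the doubling-time summary rather
than treated as errors.  Humane-endpoint rules (volume ≥ 2 cm³,
weight-loss criteria, input flags) convert each animal's trajectory into
a survival event or a study-end censoring; Kaplan–Meier estimation and
the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .units import LN2

__all__ = [
    "GrowthFit",
    "SurvivalRecord",
    "KMCurve",
    "EndpointRules",
    "ellipsoid_volume",
    "fit_doubling_time",
    "fit_growth_cohort",
    "apply_humane_endpoints",
    "build_survival_table",
    "km_curve",
    "logrank_test",
]


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Tumor volume (mm³) from the three caliper radii (mm)."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("all radii must be positive")
    return 4.0 / 3.0 * math.pi * a * b * c


# ---------------------------------------------------------------------------
# doubling time


@dataclass
class GrowthFit:
    """Exponential growth fit for one animal."""

    animal_id: str
    v0: float                   # mm³ at day 0 of the fit scale
    rate: float                 # 1/day
    r_squared: float
    n_points: int
    included: bool
    reason: str = ""

    @property
    def doubling_time(self) -> float:
        """ln 2 / rate, days; nan for non-growing tumors."""
        return LN2 / self.rate if self.rate > 0 else math.nan


def fit_doubling_time(series: pd.DataFrame, animal_id: str | None = None) -> GrowthFit:
    """Log-linear exponential-growth fit of one animal's volume series.

    ``series`` needs columns day and either volume_mm3 or the radii
    a_mm/b_mm/c_mm.  Requires ≥ 3 strictly positive volumes.  A
    non-positive slope marks the animal excluded (tumor shrank) with the
    doubling time undefined.
    """
    if animal_id is None:
        animal_id = str(series["animal_id"].iloc[0]) if "animal_id" in series else "?"
    if "volume_mm3" in series:
        v = series["volume_mm3"].to_numpy(float)
    else:
        v = np.array([
            ellipsoid_volume(r.a_mm, r.b_mm, r.c_mm)
            for r in series.itertuples()
        ])
    t = series["day"].to_numpy(float)
    if len(v) < 3:
        raise ValueError("need at least 3 measurements to fit a growth rate")
    if np.any(v <= 0):
        raise ValueError("volumes must be strictly positive")
    slope, intercept = np.polyfit(t, np.log(v), 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((np.log(v) - pred) ** 2))
    ss_tot = float(np.sum((np.log(v) - np.log(v).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    included = slope > 0
    return GrowthFit(
        animal_id=animal_id, v0=math.exp(intercept), rate=float(slope),
        r_squared=r2, n_points=len(v), included=included,
        reason="" if included else "tumor size decreased over time",
    )


def fit_growth_cohort(tumors: pd.DataFrame) -> pd.DataFrame:
    """Doubling-time fits for every animal in a tumors table."""
    rows = []
    for (animal, group), sub in tumors.groupby(["animal_id", "group"], sort=False):
        fit = fit_doubling_time(sub, animal_id=str(animal))
        rows.append({
            "animal_id": animal, "group": group, "v0_mm3": fit.v0,
            "rate_per_day": fit.rate, "doubling_time_day": fit.doubling_time,
            "r_squared": fit.r_squared, "n_points": fit.n_points,
            "included": fit.included, "reason": fit.reason,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# humane endpoints


@dataclass
class EndpointRules:
    """Humane-endpoint thresholds and the study-end censoring day."""

    volume_mm3: float = 2000.0          # 2 cm³
    acute_weight_loss: float = 0.15     # >15% within 2 days
    acute_window_days: float = 2.0
    chronic_weight_loss: float = 0.20   # >20% vs baseline
    study_end: float = 150.0            # days post-inoculation


@dataclass
class SurvivalRecord:
    """One animal's event time and cause (or study-end censoring)."""

    animal_id: str
    time: float
    event: bool
    cause: str            # volume / ulceration / weight-loss-acute /
                          # weight-loss-chronic / clinical / study-end-censor
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("event time must be positive")
        if (self.cause == "study-end-censor") != (not self.event):
            raise ValueError("study-end-censor if and only if no event")


def _weight_crossings(days: np.ndarray, weights: np.ndarray,
                      rules: EndpointRules) -> list[tuple[float, str]]:
    """Earliest acute / chronic weight-loss crossings on a daily grid.

    Weights are linearly interpolated between weigh-ins; the acute rule
    compares each day with the interpolated weight ``acute_window_days``
    earlier.
    """
    out: list[tuple[float, str]] = []
    if len(days) < 1:
        return out
    grid = np.arange(days[0], days[-1] + 1e-9, 1.0)
    w = np.interp(grid, days, weights)
    baseline = weights[0]
    chronic = w < (1.0 - rules.chronic_weight_loss) * baseline
    if chronic.any():
        out.append((float(grid[chronic.argmax()]), "weight-loss-chronic"))
    win = rules.acute_window_days
    ref = np.interp(grid - win, days, weights)
    with np.errstate(invalid="ignore"):
        acute = (ref - w) / ref > rules.acute_weight_loss
    acute &= grid - win >= grid[0]
    if acute.any():
        out.append((float(grid[acute.argmax()]), "weight-loss-acute"))
    return out


def apply_humane_endpoints(volumes: pd.DataFrame, weights: pd.DataFrame | None,
                           rules: EndpointRules | None = None,
                           flags: pd.DataFrame | None = None,
                           animal_id: str | None = None,
                           group: str = "") -> SurvivalRecord:
    """Derive one animal's survival record from its measurement series.

    ``volumes``: columns day + volume_mm3 (or radii); ``weights``: day +
    weight_g (baseline = first recorded weight); ``flags`` (optional):
    day + cause rows for ulceration / clinical deterioration.  The
    earliest rule crossing wins; with none by study end the animal is
    censored there.
    """
    rules = rules or EndpointRules()
    if volumes is None or len(volumes) == 0:
        raise ValueError("empty volume series")
    if animal_id is None:
        animal_id = str(volumes["animal_id"].iloc[0]) if "animal_id" in volumes else "?"

    candidates: list[tuple[float, str]] = []
    vdays = volumes["day"].to_numpy(float)
    if "volume_mm3" in volumes:
        v = volumes["volume_mm3"].to_numpy(float)
    else:
        v = np.array([ellipsoid_volume(r.a_mm, r.b_mm, r.c_mm)
                      for r in volumes.itertuples()])
    over = v >= rules.volume_mm3
    if over.any():
        candidates.append((float(vdays[over.argmax()]), "volume"))

    if weights is not None and len(weights) > 0:
        candidates.extend(_weight_crossings(
            weights["day"].to_numpy(float),
            weights["weight_g"].to_numpy(float), rules))

    if flags is not None and len(flags) > 0:
        for r in flags.itertuples():
            candidates.append((float(r.day), str(r.cause)))

    candidates = [(t, c) for t, c in candidates if t <= rules.study_end]
    if not candidates:
        return SurvivalRecord(animal_id, rules.study_end, False,
                              "study-end-censor", group)
    # earliest crossing; deterministic priority on ties
    priority = {"volume": 0, "ulceration": 1, "weight-loss-acute": 2,
                "weight-loss-chronic": 3, "clinical": 4}
    t, cause = min(candidates, key=lambda tc: (tc[0], priority.get(tc[1], 9)))
    return SurvivalRecord(animal_id, t, True, cause, group)


def build_survival_table(tumors: pd.DataFrame, weights: pd.DataFrame | None = None,
                         rules: EndpointRules | None = None,
                         flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Survival records for every animal in a cohort's tables."""
    rows = []
    for (animal, group), sub in tumors.groupby(["animal_id", "group"], sort=False):
        w = weights[weights["animal_id"] == animal] if weights is not None else None
        f = flags[flags["animal_id"] == animal] if flags is not None else None
        rec = apply_humane_endpoints(sub, w, rules, f, animal_id=str(animal),
                                     group=str(group))
        rows.append({"animal_id": rec.animal_id, "group": rec.group,
                     "time": rec.time, "event": rec.event, "cause": rec.cause})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float = math.nan      # inf when never reaching S ≤ 0.5
    label: str = ""

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def median_label(self, study_end: float | None = None) -> str:
        if self.median_reached:
            return f"{self.median:g}"
        return f">{study_end:g}" if study_end is not None else "not reached"


def km_curve(records: pd.DataFrame | list[SurvivalRecord],
             label: str = "") -> KMCurve:
    """Kaplan–Meier estimate from survival records (time + event)."""
    if isinstance(records, list):
        records = pd.DataFrame([{"time": r.time, "event": r.event}
                                for r in records])
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    t = records["time"].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, records["event"].to_numpy(bool))
    surv = kmf.survival_function_
    times = surv.index.to_numpy(float)
    s = surv.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(float)
    return KMCurve(times, s, at_risk, float(kmf.median_survival_time_), label)


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame):
    """Two-sided log-rank comparison of two survival tables.

    Returns (chi-square statistic on 1 df, two-sided p).  Undefined when
    neither group has any event.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ea = group_a["event"].to_numpy(bool)
    eb = group_b["event"].to_numpy(bool)
    if not ea.any() and not eb.any():
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(
        group_a["time"].to_numpy(float), group_b["time"].to_numpy(float),
        event_observed_A=ea, event_observed_B=eb,
    )
    return float(res.test_statistic), float(res.p_value)
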