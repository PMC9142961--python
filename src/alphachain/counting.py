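"""Reduction of γ-counter records to decay-corrected %IA/g.

The method is relative: samples and aliquots of a known fraction of the
injected dose ("standards") are counted in the same run, so detector
efficiency and radioactive decay cancel.  ²²⁵Ac itself emits only weak
γ-lines; it is quantified through the 218 keV line of its daughter ²²¹Fr
once every unsupported daughter has decayed (≥ 24 h after dissection).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decay
from .decay import AC225, FR221, DecayChain
from .units import hours

__all__ = [
    "CountingRecord",
    "StandardSet",
    "EquilibriumNotReached",
    "percent_ia",
    "percent_ia_per_gram",
    "quantify_parent_delayed",
    "dilution_concentration",
    "specific_activity",
    "reduce_biodistribution",
    "summarize_biodistribution",
]

#: energy windows (keV ranges are metadata; matching is by name)
WINDOWS = {
    "Fr221": (170.0, 270.0),   # 218 keV line
    "Bi213": (380.0, 520.0),   # 440 keV line
    "Lu177": (180.0, 230.0),
}


class EquilibriumNotReached(ValueError):
    """Delayed-count record taken before the free daughters had decayed."""


@dataclass(frozen=True)
class CountingRecord:
    """One γ-counter measurement of a tissue sample."""

    sample_id: str
    counts: float
    duration: float              # min
    window: str = "Fr221"
    mass_g: float | None = None  # None for non-tissue samples
    organ: str | None = None
    animal_id: str | None = None
    start_time: float = 0.0      # min, same clock as dissection_time

    def __post_init__(self) -> None:
        if self.counts < 0:
            raise ValueError("counts must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mass_g is not None and self.mass_g <= 0:
            raise ValueError("tissue mass must be positive")


@dataclass(frozen=True)
class StandardSet:
    """Aliquots of a known fraction of the injected dose, counted with the
    samples.  Default: three aliquots of 1%."""

    aliquot_counts: tuple[float, ...]
    fraction_of_injected: float = 0.01
    duration: float | None = None  # min; needed only for rate conversions

    def __post_init__(self) -> None:
        if len(self.aliquot_counts) < 1:
            raise ValueError("need at least one standard aliquot")
        if any(c < 0 for c in self.aliquot_counts):
            raise ValueError("standard counts must be non-negative")
        if not (0.0 < self.fraction_of_injected < 1.0):
            raise ValueError("fraction of injected dose must lie in (0, 1)")

    @property
    def mean_counts(self) -> float:
        return float(np.mean(self.aliquot_counts))


def _net_counts(counts: float, background: float) -> float:
    net = counts - background
    if net < 0:
        warnings.warn("background exceeds counts; flooring at 0", stacklevel=3)
        return 0.0
    return net


def percent_ia(record: CountingRecord, standards: StandardSet,
               background_counts: float = 0.0) -> float:
    """Percent of the injected activity in the sample (%IA)."""
    std = standards.mean_counts - background_counts
    if std <= 0:
        raise ZeroDivisionError("mean standard counts are zero after background")
    net = _net_counts(record.counts, background_counts)
    return net / std * standards.fraction_of_injected * 100.0


def percent_ia_per_gram(record: CountingRecord, standards: StandardSet,
                        background_counts: float = 0.0) -> float:
    """%IA per gram of tissue.

    Requires the record and standards to come from the same counting run
    (same window and duration) so that decay cancels.
    """
    if record.mass_g is None:
        raise ValueError("record has no tissue mass")
    return percent_ia(record, standards, background_counts) / record.mass_g


def quantify_parent_delayed(record: CountingRecord, dissection_time: float,
                            standards: StandardSet,
                            chain: DecayChain | None = None,
                            min_delay: float = hours(24.0),
                            equilibrium_correction: bool = True,
                            background_counts: float = 0.0) -> float:
    """%IA of ²²⁵Ac in a sample from a delayed ²²¹Fr-window count.

    The record must start at least ``min_delay`` minutes after dissection
    so that only daughters supported by ²²⁵Ac in the sample remain.  With
    ``equilibrium_correction`` the asymptotic ratio
    A(²²¹Fr)/A(²²⁵Ac) = λ_Fr/(λ_Fr − λ_Ac) (≈ 1.0004) is divided out; when
    the standards are themselves ²²⁵Ac aliquots in equilibrium the factor
    cancels and the correction may be disabled.
    """
    delay = record.start_time - dissection_time
    if delay < min_delay:
        raise EquilibriumNotReached(
            f"delay {delay:.0f} min < required {min_delay:.0f} min: "
            "free daughters have not fully decayed"
        )
    value = percent_ia(record, standards, background_counts)
    if equilibrium_correction:
        chain = chain or decay.ac225_chain()
        value /= decay.equilibrium_ratio(chain, AC225, FR221)
    return value


# ---------------------------------------------------------------------------
# radiolabeling arithmetic


def dilution_concentration(total_activity: float, volume: float) -> float:
    """Concentration after dissolving *total_activity* MBq in *volume* µL."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return total_activity / volume


def specific_activity(activity: float, protein_mass: float) -> float:
    """Specific activity, MBq per µg of protein."""
    if protein_mass <= 0:
        raise ValueError("protein mass must be positive")
    return activity / protein_mass


# ---------------------------------------------------------------------------
# table-level reduction


def _standards_from_frame(df: pd.DataFrame) -> StandardSet:
    frac = df["fraction_of_injected"].iloc[0] if "fraction_of_injected" in df else 0.01
    return StandardSet(tuple(df["counts"]), float(frac))


def reduce_biodistribution(counts: pd.DataFrame, standards: pd.DataFrame,
                           chain: DecayChain | None = None,
                           min_delay: float = hours(24.0),
                           equilibrium_correction: bool = False) -> pd.DataFrame:
    """Reduce cohort counting tables to tidy per-animal %IA/g.

    ``counts`` rows need sample_id, animal_id, organ, timepoint_day,
    mass_g, window, start_time_min, dissection_time_min, duration_min,
    counts; ``standards`` needs timepoint_day, counts (one standards run
    per timepoint, counted simultaneously with the samples).  ²²¹Fr-window
    rows go through the delayed ²²⁵Ac quantification path.  The
    equilibrium correction defaults off because cohort standards are
    equilibrium aliquots of the injected conjugate (the factor cancels).
    """
    out = []
    for day, group in counts.groupby("timepoint_day"):
        std = _standards_from_frame(standards[standards["timepoint_day"] == day])
        for _, row in group.iterrows():
            rec = CountingRecord(
                sample_id=row["sample_id"], counts=row["counts"],
                duration=row["duration_min"], window=row["window"],
                mass_g=row["mass_g"], organ=row["organ"],
                animal_id=row["animal_id"], start_time=row["start_time_min"],
            )
            if row["window"] == "Fr221":
                pct = quantify_parent_delayed(
                    rec, row["dissection_time_min"], std, chain=chain,
                    min_delay=min_delay,
                    equilibrium_correction=equilibrium_correction,
                ) / rec.mass_g
            else:
                pct = percent_ia_per_gram(rec, std)
            out.append({
                "animal_id": rec.animal_id, "organ": rec.organ,
                "timepoint_day": day, "pct_ia_per_g": pct,
            })
    return pd.DataFrame(out)


def summarize_biodistribution(tidy: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SD of %IA/g per organ and timepoint."""
    g = tidy.groupby(["organ", "timepoint_day"])["pct_ia_per_g"]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    summary.loc[summary["n"] < 2, "sd"] = math.nan
    return summary
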