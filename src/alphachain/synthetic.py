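"""Synthetic study-data generators.

Everything the analysis consumes can be generated here with a fixed seed:
γ-counter traces of dissected organs (²²⁵Ac plus an excess or deficit of
unsupported ²¹³Bi), biodistribution cohorts with lognormal inter-animal
spread, and tumor-growth / survival cohorts with caliper noise and humane
endpoint crossings.  Ground truth is emitted alongside every table so
round-trip recovery can be tested.

The generators emulate the *statistical* structure the reduction assumes:
Poisson counting, lognormal biological spread, exponential or
piecewise-exponential tumor growth.  They do not model antibody
pharmacokinetics, immune effects, or detector spectroscopy beyond a
per-window efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay
from .decay import AC225, BI213, FR221, DecayChain
from .units import DECAYS_PER_MIN_PER_KBQ, LN2, days, hours

__all__ = [
    "CounterModel",
    "OrganTruth",
    "GroupTruth",
    "EfficacyTruth",
    "simulate_counting_trace",
    "simulate_biodistribution_cohort",
    "simulate_redistribution_scenario",
    "simulate_efficacy_cohort",
    "default_therapy_scenario",
    "bi213_trace_rate",
]


# ---------------------------------------------------------------------------
# counter


@dataclass
class CounterModel:
    """A γ-counter reduced to one efficiency per energy window.

    The relative (%IA/g) method makes the absolute efficiency cancel, but a
    simulation still needs one.  Defaults are plausible NaI well-counter
    photopeak efficiencies; the background is per window, in counts/min.
    """

    window_efficiencies: dict[str, float] = field(
        default_factory=lambda: {"Fr221": 0.25, "Bi213": 0.20, "Lu177": 0.20}
    )
    background_rate: float = 1.0
    bin_duration: float = 5.0
    trace_duration: float = 720.0

    def __post_init__(self) -> None:
        for w, eff in self.window_efficiencies.items():
            if not (0.0 < eff <= 1.0):
                raise ValueError(f"efficiency for {w} must lie in (0, 1]")
        if self.background_rate < 0:
            raise ValueError("background rate must be non-negative")
        if self.bin_duration <= 0:
            raise ValueError("bin duration must be positive")

    def efficiency(self, window: str) -> float:
        try:
            return self.window_efficiencies[window]
        except KeyError:
            raise KeyError(f"no efficiency configured for window {window!r}") from None


def _rng(seed) -> np.random.Generator:
    if not (isinstance(seed, (int, np.integer)) and not isinstance(seed, bool)):
        raise TypeError("seed must be an integer")
    return np.random.default_rng(int(seed))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal with the given arithmetic mean and coefficient of variation."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if mean == 0 or cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# counting traces


def bi213_trace_rate(A_parent_t0: float, R: float, tau,
                     counter: CounterModel, chain: DecayChain | None = None,
                     window: str = "Bi213"):
    """Expected ²¹³Bi-window count rate τ minutes after dissection.

    The sample holds parent activity ``A_parent_t0`` with daughters in
    equilibrium, plus free (unsupported) ²¹³Bi scaled by the redistribution
    ratio R = total/supported at t₀.  The free component decays with
    λ(²¹³Bi); the supported component is the −λ_parent eigenmode of the
    chain and decays exactly with λ(²²⁵Ac).  Accepts scalar or array τ;
    returns counts/min including background.
    """
    chain = chain or decay.ac225_chain()
    tau = np.asarray(tau, float)
    eff = counter.efficiency(window)
    eq = decay.equilibrium_ratio(chain, AC225, BI213)
    a_sup0 = A_parent_t0 * eq
    a_free0 = (R - 1.0) * a_sup0
    lam_bi = chain.members[chain.index(BI213)].decay_constant
    lam_parent = chain.members[0].decay_constant
    a_total = a_free0 * np.exp(-lam_bi * tau) + a_sup0 * np.exp(-lam_parent * tau)
    rate = eff * a_total * DECAYS_PER_MIN_PER_KBQ + counter.background_rate
    return rate if rate.ndim else float(rate)


def _equilibrium_state(chain: DecayChain, parent_activity: float) -> "decay.ActivityState":
    """Parent plus daughters at their asymptotic (supported) activities."""
    acts = {chain.names[0]: parent_activity}
    for name in chain.names[1:]:
        acts[name] = parent_activity * decay.equilibrium_ratio(chain, chain.names[0], name)
    return decay.ActivityState(0.0, acts)


def simulate_counting_trace(A_parent_t0: float, R: float, counter: CounterModel,
                            seed, chain: DecayChain | None = None,
                            sample_id: str = "S1",
                            delayed_start: float = hours(24.0),
                            delayed_duration: float = 10.0,
                            noiseless: bool = False) -> pd.DataFrame:
    """Continuous ²¹³Bi-window counting trace of one dissected sample.

    Emits per-bin Poisson counts over ``counter.trace_duration`` minutes
    starting at dissection (t = 0), followed by one delayed ²²¹Fr-window
    record at ``delayed_start`` (≥ 24 h by default).  Deterministic for a
    fixed seed; ``noiseless=True`` replaces Poisson draws with their
    expectations (for exact-recovery tests).
    """
    if A_parent_t0 < 0:
        raise ValueError("parent activity must be non-negative")
    if R < 0:
        raise ValueError("redistribution ratio must be non-negative")
    rng = _rng(seed)
    chain = chain or decay.ac225_chain()

    edges = np.arange(0.0, counter.trace_duration + 1e-9, counter.bin_duration)
    starts = edges[:-1]
    mids = starts + counter.bin_duration / 2.0
    mu = bi213_trace_rate(A_parent_t0, R, mids, counter, chain) * counter.bin_duration
    counts = mu if noiseless else rng.poisson(mu).astype(float)
    rows = pd.DataFrame({
        "sample_id": sample_id,
        "window": "Bi213",
        "bin_start": starts,
        "bin_duration": counter.bin_duration,
        "counts": counts,
    })

    # delayed Fr-221 record: only supported activity remains
    a_parent = decay.bateman_activities(
        chain, decay.ActivityState(0.0, {AC225: A_parent_t0}), delayed_start
    ).activity(AC225)
    a_fr = a_parent * decay.equilibrium_ratio(chain, AC225, FR221)
    mu_fr = (counter.efficiency("Fr221") * a_fr * DECAYS_PER_MIN_PER_KBQ
             + counter.background_rate) * delayed_duration
    fr_counts = mu_fr if noiseless else float(rng.poisson(mu_fr))
    delayed = pd.DataFrame({
        "sample_id": [sample_id],
        "window": ["Fr221"],
        "bin_start": [delayed_start],
        "bin_duration": [delayed_duration],
        "counts": [fr_counts],
    })
    return pd.concat([rows, delayed], ignore_index=True)


# ---------------------------------------------------------------------------
# biodistribution cohorts


@dataclass
class OrganTruth:
    """Ground truth for one organ's uptake distribution.

    ``free_daughter_ratio`` is R = total ²¹³Bi at dissection over supported
    ²¹³Bi (R > 1 excess, as in kidney; R < 1 deficit, as in blood).
    """

    organ: str
    parent_uptake: float            # %IA/g, arithmetic mean
    cv: float = 0.0
    free_daughter_ratio: float = 1.0
    mass_g: float = 1.0
    mass_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.parent_uptake < 0:
            raise ValueError("uptake must be non-negative")
        if self.free_daughter_ratio < 0:
            raise ValueError("R must be non-negative")
        if self.cv < 0 or self.mass_cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class BiodistributionSim:
    """Tables produced by :func:`simulate_biodistribution_cohort`."""

    counts: pd.DataFrame
    standards: pd.DataFrame
    truth: pd.DataFrame


def simulate_biodistribution_cohort(truths: list[OrganTruth], n_per_timepoint: int,
                                    timepoints: list[float], injected_activity: float,
                                    seed, counter: CounterModel | None = None,
                                    chain: DecayChain | None = None,
                                    delay_h: float = 24.0,
                                    count_duration: float = 10.0,
                                    n_standards: int = 3,
                                    standard_fraction: float = 0.01) -> BiodistributionSim:
    """Simulate a γ-counted biodistribution study of an ²²⁵Ac conjugate.

    Cohorts of ``n_per_timepoint`` animals are sacrificed at each timepoint
    (days post-injection); organs are counted in the delayed ²²¹Fr window
    ``delay_h`` hours after dissection, alongside ``n_standards`` aliquots
    of ``standard_fraction`` of the injected activity.  Uptake and organ
    mass vary lognormally between animals.
    """
    if not truths:
        raise ValueError("need at least one organ truth")
    if n_per_timepoint < 1:
        raise ValueError("need at least one animal per timepoint")
    if not timepoints:
        raise ValueError("need at least one timepoint")
    rng = _rng(seed)
    counter = counter or CounterModel()
    chain = chain or decay.ac225_chain()
    lam_ac = chain.members[0].decay_constant
    eq_fr = decay.equilibrium_ratio(chain, AC225, FR221)
    eff = counter.efficiency("Fr221")

    count_rows, std_rows, truth_rows = [], [], []
    animal_no = 0
    for day in timepoints:
        t_count = days(day) + hours(delay_h)
        decay_factor = math.exp(-lam_ac * t_count)
        for _ in range(n_per_timepoint):
            animal_no += 1
            animal = f"M{animal_no:03d}"
            for tr in truths:
                uptake = float(_lognormal(rng, tr.parent_uptake, tr.cv))
                mass = float(_lognormal(rng, tr.mass_g, tr.mass_cv))
                a_ac = uptake * mass / 100.0 * injected_activity * decay_factor
                mu = (eff * a_ac * eq_fr * DECAYS_PER_MIN_PER_KBQ
                      + counter.background_rate) * count_duration
                count_rows.append({
                    "sample_id": f"{animal}-{tr.organ}",
                    "animal_id": animal,
                    "organ": tr.organ,
                    "timepoint_day": day,
                    "mass_g": mass,
                    "window": "Fr221",
                    "start_time_min": t_count,
                    "dissection_time_min": days(day),
                    "duration_min": count_duration,
                    "counts": int(rng.poisson(mu)),
                })
                truth_rows.append({
                    "animal_id": animal,
                    "organ": tr.organ,
                    "timepoint_day": day,
                    "uptake_pct_ia_per_g": uptake,
                    "mass_g": mass,
                })
        a_std = standard_fraction * injected_activity * decay_factor
        mu_std = (eff * a_std * eq_fr * DECAYS_PER_MIN_PER_KBQ
                  + counter.background_rate) * count_duration
        for k in range(n_standards):
            std_rows.append({
                "timepoint_day": day,
                "aliquot": k + 1,
                "window": "Fr221",
                "start_time_min": t_count,
                "duration_min": count_duration,
                "fraction_of_injected": standard_fraction,
                "counts": int(rng.poisson(mu_std)),
            })
    return BiodistributionSim(
        counts=pd.DataFrame(count_rows),
        standards=pd.DataFrame(std_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# redistribution (free vs supported 213Bi) scenarios


@dataclass
class RedistributionSim:
    """Tables produced by :func:`simulate_redistribution_scenario`."""

    traces: pd.DataFrame          # per-bin Bi213-window counts per sample
    equilibrium: pd.DataFrame     # one late Bi213 record per sample
    standards: pd.DataFrame       # Bi213-window standards at t0 and t_eq runs
    truth: pd.DataFrame


def simulate_redistribution_scenario(truths: list[OrganTruth], n_animals: int,
                                     timepoint: float, injected_activity: float,
                                     seed, counter: CounterModel | None = None,
                                     chain: DecayChain | None = None,
                                     teq_h: float = 24.0,
                                     eq_duration: float = 10.0,
                                     n_standards: int = 3,
                                     standard_fraction: float = 0.01,
                                     noiseless: bool = False) -> RedistributionSim:
    """Simulate the t₀-vs-t_eq ²¹³Bi redistribution experiment.

    Each organ sample is counted continuously in the ²¹³Bi window for
    ``counter.trace_duration`` minutes from dissection, and once more at
    ``teq_h`` hours (equilibrium).  Standards (aliquots of the injected
    dose, daughters in equilibrium) are counted at the start of each run.
    """
    if not truths:
        raise ValueError("need at least one organ truth")
    rng = _rng(seed)
    counter = counter or CounterModel()
    chain = chain or decay.ac225_chain()
    lam_ac = chain.members[0].decay_constant
    eq_bi = decay.equilibrium_ratio(chain, AC225, BI213)
    eff = counter.efficiency("Bi213")

    t_diss = days(timepoint)
    a_inj_t0 = injected_activity * math.exp(-lam_ac * t_diss)

    trace_rows, eq_rows, truth_rows = [], [], []
    edges = np.arange(0.0, counter.trace_duration + 1e-9, counter.bin_duration)
    starts = edges[:-1]
    mids = starts + counter.bin_duration / 2.0
    for i in range(n_animals):
        animal = f"M{i + 1:03d}"
        for tr in truths:
            uptake = float(_lognormal(rng, tr.parent_uptake, tr.cv))
            mass = float(_lognormal(rng, tr.mass_g, tr.mass_cv))
            a_parent = uptake * mass / 100.0 * injected_activity * math.exp(-lam_ac * t_diss)
            sid = f"{animal}-{tr.organ}"
            mu = bi213_trace_rate(a_parent, tr.free_daughter_ratio, mids,
                                  counter, chain) * counter.bin_duration
            counts = mu if noiseless else rng.poisson(mu).astype(float)
            for s, c in zip(starts, counts):
                trace_rows.append({
                    "sample_id": sid, "animal_id": animal, "organ": tr.organ,
                    "timepoint_day": timepoint, "mass_g": mass,
                    "window": "Bi213", "bin_start": float(s),
                    "bin_duration": counter.bin_duration, "counts": float(c),
                })
            # equilibrium record: free component fully decayed
            tau_eq = hours(teq_h)
            mu_eq = bi213_trace_rate(a_parent, 1.0, tau_eq, counter, chain) * eq_duration
            c_eq = mu_eq if noiseless else float(rng.poisson(mu_eq))
            eq_rows.append({
                "sample_id": sid, "animal_id": animal, "organ": tr.organ,
                "timepoint_day": timepoint, "mass_g": mass, "window": "Bi213",
                "start_time_min": tau_eq, "dissection_time_min": 0.0,
                "duration_min": eq_duration, "counts": c_eq,
            })
            # standards are Ac aliquots with Bi in equilibrium, counted in the
            # same window, so the chain equilibrium factor cancels in %IA/g:
            # supported Bi in %IA/g equals the parent uptake.
            truth_rows.append({
                "animal_id": animal, "organ": tr.organ, "timepoint_day": timepoint,
                "uptake_pct_ia_per_g": uptake, "mass_g": mass,
                "ratio": tr.free_daughter_ratio,
                "a_supported_t0_pct_ia_per_g": uptake,
                "a_t0_pct_ia_per_g": uptake * tr.free_daughter_ratio,
                "a_free_t0_pct_ia_per_g": uptake * (tr.free_daughter_ratio - 1.0),
            })

    std_rows = []
    for run, tau in (("t0", 0.0), ("teq", hours(teq_h))):
        a_std = standard_fraction * a_inj_t0 * math.exp(-lam_ac * tau) * eq_bi
        mu_std = (eff * a_std * DECAYS_PER_MIN_PER_KBQ
                  + counter.background_rate) * eq_duration
        for k in range(n_standards):
            c = mu_std if noiseless else float(rng.poisson(mu_std))
            std_rows.append({
                "run": run, "aliquot": k + 1, "window": "Bi213",
                "start_time_min": tau, "duration_min": eq_duration,
                "fraction_of_injected": standard_fraction, "counts": c,
            })
    return RedistributionSim(
        traces=pd.DataFrame(trace_rows),
        equilibrium=pd.DataFrame(eq_rows),
        standards=pd.DataFrame(std_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# efficacy / survival cohorts


@dataclass
class GroupTruth:
    """Tumor-growth truth for one treatment group.

    ``phases`` is a list of (start_day, rate per day) change-points;
    a single positive rate is plain exponential growth, a negative rate
    followed by a positive one models shrink-then-regrow after treatment.
    """

    name: str
    initial_volume_median: float              # mm³, lognormal median
    phases: tuple[tuple[float, float], ...]
    initial_volume_cv: float = 0.45
    caliper_cv: float = 0.05


@dataclass
class EfficacyTruth:
    """Study design for a therapy cohort simulation."""

    groups: tuple[GroupTruth, ...]
    endpoint_volume: float = 2000.0            # mm³ (2 cm³)
    study_end: float = 150.0                   # days post-inoculation
    start_day: float = 21.0                    # randomization/treatment day

    def __post_init__(self) -> None:
        if self.endpoint_volume <= 0 or self.study_end <= 0:
            raise ValueError("endpoint volume and study end must be positive")
        for g in self.groups:
            if not g.phases:
                raise ValueError(f"group {g.name}: needs at least one phase")
            for start, _ in g.phases:
                if not (self.start_day <= start <= self.study_end):
                    raise ValueError(
                        f"group {g.name}: change-point day {start} outside "
                        f"[{self.start_day}, {self.study_end}]"
                    )


@dataclass
class EfficacySim:
    """Tables produced by :func:`simulate_efficacy_cohort`."""

    tumors: pd.DataFrame
    weights: pd.DataFrame
    truth: pd.DataFrame


def _measurement_days(start: float, end: float) -> np.ndarray:
    """Twice-weekly caliper schedule (alternating 3/4-day gaps)."""
    out = [start]
    step = 3.0
    while out[-1] + step <= end:
        out.append(out[-1] + step)
        step = 7.0 - step
    return np.array(out)


def _true_volume(v0: float, phases, t: float, start_day: float) -> float:
    """Piecewise-exponential volume at day t (t ≥ start_day)."""
    log_v = math.log(v0)
    bounds = [p[0] for p in phases] + [math.inf]
    for (p_start, rate), p_end in zip(phases, bounds[1:]):
        if t <= p_start:
            break
        log_v += rate * (min(t, p_end) - p_start)
    return math.exp(log_v)


def _true_crossing(v0: float, phases, start_day: float, end: float,
                   threshold: float) -> float:
    """First day the continuous trajectory reaches threshold, or nan."""
    log_t, log_thr = math.log(v0), math.log(threshold)
    if log_t >= log_thr:
        return start_day
    bounds = [p[0] for p in phases] + [end]
    for (p_start, rate), p_end in zip(phases, bounds[1:]):
        seg = p_end - p_start
        if rate > 0 and log_t + rate * seg >= log_thr:
            return p_start + (log_thr - log_t) / rate
        log_t += rate * seg
    return math.nan


def simulate_efficacy_cohort(truth: EfficacyTruth, n_per_group: int,
                             seed, baseline_weight: float = 20.4,
                             weight_sd: float = 1.2,
                             weight_cv: float = 0.01) -> EfficacySim:
    """Simulate caliper and body-weight series for a therapy study.

    Tumors follow each group's piecewise-exponential model; the three
    measured radii carry independent multiplicative lognormal noise.
    Measurements stop at the first caliper reading at or above the
    endpoint volume (the animal is removed) or at study end.  Weights are
    weekly and stable by default (weight-loss endpoints are exercised by
    constructing series directly in tests).
    """
    if n_per_group < 1:
        raise ValueError("need at least one animal per group")
    rng = _rng(seed)
    m_days = _measurement_days(truth.start_day, truth.study_end)
    w_days = np.arange(truth.start_day, truth.study_end + 1e-9, 7.0)

    tumor_rows, weight_rows, truth_rows = [], [], []
    animal_no = 0
    for g in truth.groups:
        sigma = math.sqrt(math.log1p(g.initial_volume_cv ** 2))
        first_rate = g.phases[0][1]
        for _ in range(n_per_group):
            animal_no += 1
            animal = f"A{animal_no:03d}"
            v0 = g.initial_volume_median * math.exp(rng.normal(0.0, sigma))
            for day in m_days:
                v_true = _true_volume(v0, g.phases, day, truth.start_day)
                r_true = (3.0 * v_true / (4.0 * math.pi)) ** (1.0 / 3.0)
                noise = _lognormal(rng, 1.0, g.caliper_cv, size=3) if g.caliper_cv > 0 else np.ones(3)
                a, b, c = r_true * noise
                tumor_rows.append({
                    "animal_id": animal, "group": g.name, "day": float(day),
                    "a_mm": a, "b_mm": b, "c_mm": c,
                })
                v_meas = 4.0 / 3.0 * math.pi * a * b * c
                if v_meas >= truth.endpoint_volume:
                    break
            w0 = rng.normal(baseline_weight, weight_sd)
            last_day = tumor_rows[-1]["day"]
            for day in w_days[w_days <= last_day + 7.0]:
                w = w0 * float(_lognormal(rng, 1.0, weight_cv)) if weight_cv > 0 else w0
                weight_rows.append({
                    "animal_id": animal, "group": g.name, "day": float(day),
                    "weight_g": w,
                })
            truth_rows.append({
                "animal_id": animal, "group": g.name, "true_v0_mm3": v0,
                "true_rate_per_day": first_rate,
                "true_doubling_time_day": LN2 / first_rate if first_rate > 0 else math.nan,
                "true_crossing_day": _true_crossing(
                    v0, g.phases, truth.start_day, truth.study_end,
                    truth.endpoint_volume),
            })
    return EfficacySim(
        tumors=pd.DataFrame(tumor_rows),
        weights=pd.DataFrame(weight_rows),
        truth=pd.DataFrame(truth_rows),
    )


def default_therapy_scenario() -> EfficacyTruth:
    """The packaged five-arm therapy design.

    Control and low-dose arms grow exponentially (doubling times 31.9 and
    67.8 days); the effective arms shrink after treatment and regrow slowly
    late in the study.  Randomization median volume 82.9 mm³ at day 21,
    endpoint 2 cm³, study end day 150 post-inoculation.
    """
    return EfficacyTruth(groups=(
        GroupTruth("control", 82.9, ((21.0, LN2 / 31.9),)),
        GroupTruth("ac225-5kBq", 82.9, ((21.0, LN2 / 67.8),)),
        GroupTruth("ac225-15kBq", 82.9, ((21.0, -0.040), (90.0, 0.015))),
        GroupTruth("ac225-25kBq", 82.9, ((21.0, -0.050), (100.0, 0.010))),
        GroupTruth("lu177-13MBq", 82.9, ((21.0, -0.040), (95.0, 0.012))),
    ))
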