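"""Free-vs-supported ²¹³Bi decomposition from continuous counting traces.

A dissected organ counted in the ²¹³Bi window for ~12 h shows the sum of
two components: free ²¹³Bi present at dissection (t₀), decaying with its
own 45.6-min half-life, and supported ²¹³Bi continuously regenerated by
²²⁵Ac in the sample, which follows the parent's 9.9-day decay.  Fitting
the one-phase decay model

    Y(t) = (Y0 − plateau)·e^(−k·t) + plateau

extrapolates the total activity back to t₀; a late measurement (beyond
ten ²¹³Bi half-lives) isolates the supported component.  Their difference
is the free (redistributed) ²¹³Bi — positive in organs that accumulate it
(kidney), negative where it is lost (blood).

With the parent-decay correction ON (default) the plateau term decays
with λ(²²⁵Ac) over the trace (~3.4% across 12 h); the constant-plateau
variant matches the plain one-phase-decay model of common fitting
software and is selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import decay
from .counting import CountingRecord, StandardSet
from .decay import BI213, DecayChain
from .units import LN2

__all__ = [
    "OnePhaseFit",
    "BismuthDecomposition",
    "fit_one_phase",
    "decompose_bismuth",
    "redistribution_table",
    "analyze_redistribution",
]

#: physical decay constant of 213Bi, 1/min
K_BI213 = LN2 / 45.6

#: minimum delay of the equilibrium record: ten 213Bi half-lives
MIN_EQUILIBRIUM_DELAY = 10.0 * 45.6


@dataclass
class OnePhaseFit:
    """One-phase decay fit of a ²¹³Bi-window trace, in count-rate space."""

    y0: float                     # rate at t0, counts/min
    plateau: float                # supported rate at t0, counts/min
    k: float                      # 1/min
    se_y0: float
    se_plateau: float
    se_k: float
    se_a_free: float              # SE of y0 - plateau
    rss: float                    # weighted residual sum of squares
    n_points: int
    k_fixed: bool
    ac_correction: bool
    k_flag: bool = False          # free k deviates >20% from ln2/45.6

    @property
    def a_free(self) -> float:
        """Free-component rate at t₀ (may be negative: deficit)."""
        return self.y0 - self.plateau

    @property
    def doubling_check(self) -> float:
        return self.k * 45.6 / LN2


def _design_matrix(tau: np.ndarray, k: float, lam_parent: float,
                   ac_correction: bool) -> np.ndarray:
    free = np.exp(-k * tau)
    sup = np.exp(-lam_parent * tau) if ac_correction else np.ones_like(tau)
    return np.column_stack([free, sup])


def fit_one_phase(trace: pd.DataFrame, k_mode: str = "fixed",
                  ac_correction: bool = True,
                  background_rate: float = 0.0,
                  chain: DecayChain | None = None,
                  k_flag_tolerance: float = 0.2) -> OnePhaseFit:
    """Weighted least-squares one-phase decay fit of a counting trace.

    ``trace`` needs columns bin_start, bin_duration, counts (²¹³Bi window).
    Counts are converted to rates at bin midpoints and weighted by the
    inverse Poisson variance.  ``k_mode='fixed'`` pins k at ln2/45.6 min
    (physical constant, default); ``'free'`` estimates k and flags a
    deviation beyond ``k_flag_tolerance`` from the physical value.
    """
    if k_mode not in ("fixed", "free"):
        raise ValueError("k_mode must be 'fixed' or 'free'")
    chain = chain or decay.ac225_chain()
    lam_parent = chain.members[0].decay_constant
    k_phys = chain.members[chain.index(BI213)].decay_constant

    tau = (trace["bin_start"] + trace["bin_duration"] / 2.0).to_numpy(float)
    dt = trace["bin_duration"].to_numpy(float)
    counts = trace["counts"].to_numpy(float)
    n = len(tau)
    if n < 4:
        raise ValueError("need at least 4 bins to fit")
    if tau.max() - tau.min() < 2.0 * 45.6:
        raise ValueError("trace must span at least two 213Bi half-lives")

    rate = counts / dt - background_rate
    # Poisson: var(rate) = counts / dt^2; floor at one count for empty bins
    var = np.maximum(counts, 1.0) / dt ** 2
    w = 1.0 / var

    if not counts.any():
        return OnePhaseFit(0.0, 0.0, k_phys, math.nan, math.nan, math.nan,
                           math.nan, 0.0, n, k_mode == "fixed", ac_correction)

    def linear_fit(k: float):
        X = _design_matrix(tau, k, lam_parent, ac_correction)
        Xw = X * np.sqrt(w)[:, None]
        yw = rate * np.sqrt(w)
        res = optimize.lsq_linear(Xw, yw, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
        free_c, plateau = res.x
        resid = yw - Xw @ res.x
        rss = float(resid @ resid)
        cov = np.linalg.pinv(Xw.T @ Xw)
        return free_c, plateau, rss, cov

    if k_mode == "fixed":
        k = k_phys
        free_c, plateau, rss, cov = linear_fit(k)
        se_free = math.sqrt(max(cov[0, 0], 0.0))
        se_plateau = math.sqrt(max(cov[1, 1], 0.0))
        se_y0 = math.sqrt(max(cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1], 0.0))
        return OnePhaseFit(free_c + plateau, plateau, k, se_y0, se_plateau,
                           math.nan, se_free, rss, n, True, ac_correction)

    # free-k: nonlinear profile over k, started at the physical value
    def model(t, free_c, plateau, k):
        X = _design_matrix(t, k, lam_parent, ac_correction)
        return X @ np.array([free_c, plateau])

    f0, p0, _, _ = linear_fit(k_phys)
    try:
        popt, pcov = optimize.curve_fit(
            model, tau, rate, p0=[f0, max(p0, 0.0), k_phys],
            sigma=np.sqrt(var), absolute_sigma=True,
            bounds=([-np.inf, 0.0, 1e-8], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"one-phase fit did not converge: {exc}") from exc
    free_c, plateau, k = popt
    resid = (rate - model(tau, *popt)) * np.sqrt(w)
    rss = float(resid @ resid)
    se_free = math.sqrt(max(pcov[0, 0], 0.0))
    se_plateau = math.sqrt(max(pcov[1, 1], 0.0))
    se_k = math.sqrt(max(pcov[2, 2], 0.0))
    se_y0 = math.sqrt(max(pcov[0, 0] + pcov[1, 1] + 2.0 * pcov[0, 1], 0.0))
    flag = abs(k - k_phys) / k_phys > k_flag_tolerance
    if flag:
        warnings.warn(
            f"fitted k = {k:.4g}/min deviates >{k_flag_tolerance:.0%} from "
            f"the physical ln2/45.6 = {k_phys:.4g}/min", stacklevel=2,
        )
    return OnePhaseFit(free_c + plateau, plateau, k, se_y0, se_plateau, se_k,
                       se_free, rss, n, False, ac_correction, flag)


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class BismuthDecomposition:
    """Total / supported / free ²¹³Bi at dissection, in %IA/g.

    The identity ``a_t0 = a_free + a_supported`` holds by construction;
    ``a_free`` may be negative (deficit, as seen in blood).
    """

    sample_id: str
    a_t0: float
    a_supported: float
    organ: str | None = None
    timepoint_day: float | None = None
    supported_source: str = "equilibrium"   # or "plateau"
    se_a_free: float = math.nan
    plateau_discrepant: bool = False

    @property
    def a_free(self) -> float:
        return self.a_t0 - self.a_supported

    @property
    def ratio(self) -> float:
        return self.a_t0 / self.a_supported


def _rate_to_pct_per_g(rate: float, standards: StandardSet, mass_g: float,
                       background_rate: float = 0.0) -> float:
    if standards.duration is None:
        raise ValueError("standards need a counting duration to convert rates")
    std_rate = standards.mean_counts / standards.duration - background_rate
    if std_rate <= 0:
        raise ZeroDivisionError("standard rate is zero after background")
    return rate / std_rate * standards.fraction_of_injected * 100.0 / mass_g


def decompose_bismuth(fit: OnePhaseFit, equilibrium_record: CountingRecord,
                      standards_t0: StandardSet,
                      standards_eq: StandardSet | None = None,
                      dissection_time: float = 0.0,
                      min_delay: float = MIN_EQUILIBRIUM_DELAY,
                      background_rate: float = 0.0,
                      prefer_equilibrium: bool = True) -> BismuthDecomposition:
    """Decompose ²¹³Bi at dissection into free and supported components.

    ``standards_t0`` were counted with the trace run (convert Y0 to %IA/g);
    ``standards_eq`` with the equilibrium run.  The supported level comes
    from the equilibrium record when available (decay against its own
    simultaneous standards cancels), falling back to the fitted plateau.
    """
    delay = equilibrium_record.start_time - dissection_time
    if delay < min_delay:
        raise ValueError(
            f"equilibrium record at {delay:.0f} min < {min_delay:.0f} min "
            "(ten 213Bi half-lives) after dissection"
        )
    mass = equilibrium_record.mass_g
    if mass is None:
        raise ValueError("equilibrium record needs a tissue mass")

    std_eq = standards_eq or standards_t0
    a_t0 = _rate_to_pct_per_g(fit.y0, standards_t0, mass, background_rate)
    eq_rate = equilibrium_record.counts / equilibrium_record.duration - background_rate
    a_sup_eq = _rate_to_pct_per_g(eq_rate, std_eq, mass, background_rate)
    a_sup_plateau = _rate_to_pct_per_g(fit.plateau, standards_t0, mass,
                                       background_rate)

    # propagate counting statistics: fit covariance, the equilibrium
    # record's Poisson error, and both standards runs (independent)
    def _rel_var_std(std: StandardSet) -> float:
        m = std.mean_counts
        return 1.0 / (len(std.aliquot_counts) * m) if m > 0 else 0.0

    var = 0.0
    if fit.y0:
        var += a_t0 ** 2 * ((fit.se_y0 / fit.y0) ** 2 + _rel_var_std(standards_t0))
    if equilibrium_record.counts > 0:
        var += a_sup_eq ** 2 * (1.0 / equilibrium_record.counts
                                + _rel_var_std(std_eq))
    se_a_free = math.sqrt(var) if var > 0 else math.nan

    discrepant = False
    if fit.se_plateau and not math.isnan(fit.se_plateau) and fit.plateau > 0:
        var_pct = (fit.se_plateau * a_sup_plateau / fit.plateau) ** 2
        if equilibrium_record.counts > 0:
            var_pct += a_sup_eq ** 2 * (1.0 / equilibrium_record.counts
                                        + _rel_var_std(std_eq))
        sigma_pct = math.sqrt(var_pct)
        if sigma_pct > 0 and abs(a_sup_plateau - a_sup_eq) > 3.0 * sigma_pct:
            discrepant = True
            warnings.warn(
                f"{equilibrium_record.sample_id}: fitted plateau and "
                "equilibrium record disagree by more than 3 sigma",
                stacklevel=2,
            )
    use_eq = prefer_equilibrium
    if not use_eq and fit.y0:
        # plateau-based supported shares the fit and the t0 standards
        var = (a_t0 - a_sup_plateau) ** 2 * _rel_var_std(standards_t0)
        var += (fit.se_a_free * a_t0 / fit.y0) ** 2
        se_a_free = math.sqrt(var) if var > 0 else math.nan
    return BismuthDecomposition(
        sample_id=equilibrium_record.sample_id,
        a_t0=a_t0,
        a_supported=a_sup_eq if use_eq else a_sup_plateau,
        organ=equilibrium_record.organ,
        timepoint_day=None,
        supported_source="equilibrium" if use_eq else "plateau",
        se_a_free=se_a_free,
        plateau_discrepant=discrepant,
    )


def redistribution_table(decompositions: list[BismuthDecomposition]) -> pd.DataFrame:
    """Per-organ comparison of ²¹³Bi at t₀ vs equilibrium (mean ± SD).

    Input ordering of organs is preserved; SD is reported as missing (not
    zero) for single-animal groups.
    """
    if not decompositions:
        raise ValueError("need at least one decomposition")
    rows = pd.DataFrame([{
        "organ": d.organ, "timepoint_day": d.timepoint_day,
        "a_t0": d.a_t0, "a_supported": d.a_supported,
        "a_free": d.a_free, "ratio": d.ratio,
    } for d in decompositions])
    order = rows["organ"].drop_duplicates().tolist()
    agg = rows.groupby(["organ", "timepoint_day"], dropna=False).agg(
        a_t0_mean=("a_t0", "mean"), a_t0_sd=("a_t0", "std"),
        a_supported_mean=("a_supported", "mean"), a_supported_sd=("a_supported", "std"),
        a_free_mean=("a_free", "mean"), a_free_sd=("a_free", "std"),
        ratio_mean=("ratio", "mean"), ratio_sd=("ratio", "std"),
        n=("ratio", "count"),
    ).reset_index()
    agg["organ"] = pd.Categorical(agg["organ"], categories=order, ordered=True)
    return agg.sort_values(["organ", "timepoint_day"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# table-level workflow


def analyze_redistribution(traces: pd.DataFrame, equilibrium: pd.DataFrame,
                           standards: pd.DataFrame, k_mode: str = "fixed",
                           ac_correction: bool = True,
                           background_rate: float = 0.0,
                           chain: DecayChain | None = None):
    """Fit and decompose every sample of a redistribution experiment.

    ``standards`` carries a ``run`` column ('t0' / 'teq'); see
    :class:`alphachain.synthetic.RedistributionSim` for the table schemas.
    Returns (fits, decompositions, summary table).
    """
    def std_for(run: str) -> StandardSet:
        sub = standards[standards["run"] == run]
        if sub.empty:
            raise ValueError(f"no standards for run {run!r}")
        return StandardSet(tuple(sub["counts"]),
                           float(sub["fraction_of_injected"].iloc[0]),
                           duration=float(sub["duration_min"].iloc[0]))

    std_t0, std_eq = std_for("t0"), std_for("teq")
    fits: dict[str, OnePhaseFit] = {}
    decomps: list[BismuthDecomposition] = []
    for sid, sub in traces.groupby("sample_id", sort=False):
        fit = fit_one_phase(sub, k_mode=k_mode, ac_correction=ac_correction,
                            background_rate=background_rate, chain=chain)
        fits[sid] = fit
        eq_row = equilibrium[equilibrium["sample_id"] == sid].iloc[0]
        rec = CountingRecord(
            sample_id=sid, counts=eq_row["counts"],
            duration=eq_row["duration_min"], window=eq_row["window"],
            mass_g=eq_row["mass_g"], organ=eq_row["organ"],
            animal_id=eq_row["animal_id"], start_time=eq_row["start_time_min"],
        )
        d = decompose_bismuth(fit, rec, std_t0, std_eq,
                              dissection_time=eq_row["dissection_time_min"],
                              background_rate=background_rate)
        d.timepoint_day = eq_row.get("timepoint_day")
        decomps.append(d)
    return fits, decomps, redistribution_table(decomps)
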