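"""Analytic model of serial radioactive decay chains.

The ²²⁵Ac chain (²²⁵Ac → ²²¹Fr → ²¹⁷At → ²¹³Bi → … → stable ²⁰⁹Bi) is the
packaged default.  Activities along the chain follow the closed-form
Bateman solution; for numerically degenerate chains (two decay constants
equal to within machine-level tolerance) the solver switches to a matrix
exponential, which is the exact limit of the distinct-λ formula.

²¹⁷At (t_1/2 = 32.3 ms) lives roughly seven orders of magnitude shorter
than any counting interval used in practice, so the default chain treats
it as in instantaneous equilibrium with ²²¹Fr; the full four-member chain
is also provided for validation.  ²¹³Bi's branching (²¹³Po / ²⁰⁹Tl) is
collapsed to a single effective link to the stable terminus because no
counting window downstream of ²¹³Bi is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.linalg import expm

from .units import LN2, to_minutes

__all__ = [
    "Nuclide",
    "DecayChain",
    "ActivityState",
    "EquilibriumError",
    "bateman_activities",
    "bateman_atoms",
    "supported_daughter_activity",
    "equilibrium_ratio",
    "load_chain",
    "ac225_chain",
]

#: relative λ separation below which the closed form is ill-conditioned
DEGENERATE_LAMBDA_RTOL = 1e-9


class EquilibriumError(ValueError):
    """No transient/secular equilibrium exists for the requested pair."""


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide with its half-life (stored internally in minutes)."""

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ValueError(f"{self.name}: half-life must be positive")

    @classmethod
    def from_half_life(cls, name: str, value: float, unit: str) -> "Nuclide":
        return cls(name, to_minutes(value, unit))

    @property
    def decay_constant(self) -> float:
        """λ = ln 2 / t_1/2, in 1/min."""
        return LN2 / self.half_life_min


@dataclass(frozen=True)
class DecayChain:
    """Strictly ordered parent→daughter list with per-link branching."""

    members: tuple[Nuclide, ...]
    branching: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        members = tuple(self.members)
        branching = tuple(self.branching) if self.branching else tuple(
            1.0 for _ in range(len(members) - 1)
        )
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "branching", branching)
        if len(members) < 1:
            raise ValueError("chain needs at least one member")
        names = [n.name for n in members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate nuclide in chain (cycles not allowed)")
        if len(branching) != len(members) - 1:
            raise ValueError("need one branching fraction per link")
        for b in branching:
            if not (0.0 < b <= 1.0):
                raise ValueError("branching fractions must lie in (0, 1]")

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.members]

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([n.decay_constant for n in self.members])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"{name!r} is not a member of this chain") from None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ActivityState:
    """Per-nuclide activities (kBq) at a reference time (minutes)."""

    reference_time: float
    activities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, a in self.activities.items():
            if a < 0:
                raise ValueError(f"negative activity for {name}")

    def activity(self, name: str) -> float:
        return self.activities.get(name, 0.0)


def _is_degenerate(lambdas: np.ndarray) -> bool:
    lam = np.sort(lambdas)
    gaps = np.diff(lam)
    scale = np.maximum(lam[1:], lam[:-1])
    return bool(np.any(gaps <= DEGENERATE_LAMBDA_RTOL * scale))


def _bateman_coeff_matrix(lambdas: np.ndarray, branching: np.ndarray,
                          t: float) -> np.ndarray:
    """Atoms at time t from one initial atom in each member (closed form).

    Returns T with T[j, i] = N_j(t) given N_i(0) = 1.  The final entry of
    *lambdas* may be 0 (stable terminus).  Assumes distinct lambdas.
    """
    n = len(lambdas)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            # flux product along the links i..j-1
            prod = 1.0
            for k in range(i, j):
                prod *= branching[k] * lambdas[k]
            lam = lambdas[i : j + 1]
            total = 0.0
            for idx, lam_l in enumerate(lam):
                denom = 1.0
                for m, lam_m in enumerate(lam):
                    if m != idx:
                        denom *= lam_m - lam_l
                total += math.exp(-lam_l * t) / denom
            T[j, i] = prod * total
    return T


def _transition_matrix(lambdas: np.ndarray, branching: np.ndarray,
                       t: float) -> np.ndarray:
    """Atoms transition matrix, via expm when lambdas are degenerate."""
    if _is_degenerate(lambdas):
        n = len(lambdas)
        M = np.zeros((n, n))
        for i in range(n):
            M[i, i] = -lambdas[i]
            if i + 1 < n:
                M[i + 1, i] = branching[i] * lambdas[i]
        return expm(M * t)
    return _bateman_coeff_matrix(lambdas, branching, t)


def bateman_atoms(chain: DecayChain, initial_atoms: np.ndarray,
                  elapsed: float, include_terminus: bool = True) -> np.ndarray:
    """Atom numbers of every chain member (plus the stable terminus) at
    ``elapsed`` minutes, from the closed-form Bateman solution.

    ``initial_atoms`` covers the chain members (terminus starts empty).
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    lambdas = chain.lambdas
    branching = np.asarray(chain.branching)
    if include_terminus:
        lambdas = np.append(lambdas, 0.0)
        branching = np.append(branching, 1.0)
    n0 = np.zeros(len(lambdas))
    n0[: len(initial_atoms)] = initial_atoms
    T = _transition_matrix(lambdas, branching, elapsed)
    return T @ n0


def bateman_activities(chain: DecayChain, initial: ActivityState,
                       elapsed: float) -> ActivityState:
    """Activities of every chain member after ``elapsed`` minutes.

    The initial state may omit members (treated as zero).  Works in atom
    space internally: N = A/λ, A = λN.
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    lambdas = chain.lambdas
    a0 = np.array([initial.activity(name) for name in chain.names])
    n0 = a0 / lambdas
    nt = bateman_atoms(chain, n0, elapsed, include_terminus=False)
    at = lambdas * nt
    # clip tiny negative round-off
    at = np.where(np.abs(at) < 1e-300, 0.0, at)
    return ActivityState(
        reference_time=initial.reference_time + elapsed,
        activities={name: max(float(a), 0.0) for name, a in zip(chain.names, at)},
    )


def supported_daughter_activity(chain: DecayChain, parent_activity: float,
                                daughter: str, elapsed: float,
                                parent: str | None = None) -> float:
    """Activity of *daughter* grown in from a pure-parent sample.

    Starts from ``parent_activity`` kBq of the parent alone at t = 0 and
    returns the daughter's activity after ``elapsed`` minutes.  The value
    rises monotonically toward the equilibrium level.
    """
    if parent_activity < 0:
        raise ValueError("parent activity must be non-negative")
    p = chain.index(parent) if parent is not None else 0
    d = chain.index(daughter)
    if d <= p:
        raise ValueError(f"{daughter!r} is not downstream of the parent")
    state = ActivityState(0.0, {chain.names[p]: parent_activity})
    return bateman_activities(chain, state, elapsed).activity(daughter)


def equilibrium_ratio(chain: DecayChain, parent: str, daughter: str) -> float:
    """Asymptotic activity ratio A_daughter / A_parent.

    For a single link this is λ_d / (λ_d − λ_p); for longer segments the
    per-link factors multiply (with branching).  Requires every downstream
    decay constant to exceed the parent's, otherwise no transient
    equilibrium exists and :class:`EquilibriumError` is raised.
    """
    p = chain.index(parent)
    d = chain.index(daughter)
    if d <= p:
        raise ValueError(f"{daughter!r} is not downstream of {parent!r}")
    lam = chain.lambdas
    lam_p = lam[p]
    ratio = 1.0
    for m in range(p + 1, d + 1):
        if lam[m] <= lam_p * (1.0 + DEGENERATE_LAMBDA_RTOL):
            raise EquilibriumError(
                f"no equilibrium: λ({chain.names[m]}) ≤ λ({parent})"
            )
        ratio *= chain.branching[m - 1] * lam[m] / (lam[m] - lam_p)
    return ratio


# ---------------------------------------------------------------------------
# chain definition files

def load_chain(source) -> DecayChain:
    """Load a chain from a YAML mapping (path or file-like).

    Schema::

        nuclides:
          - {name: Ac-225, half_life: 9.9, unit: day}
          - {name: Fr-221, half_life: 5.0, unit: min, branching: 1.0}

    ``branching`` on a nuclide is the fraction of the *previous* member
    decaying into it (default 1).
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    entries = raw["nuclides"]
    members = [
        Nuclide.from_half_life(e["name"], float(e["half_life"]), e["unit"])
        for e in entries
    ]
    branching = [float(e.get("branching", 1.0)) for e in entries[1:]]
    return DecayChain(tuple(members), tuple(branching))


def ac225_chain(full: bool = False) -> DecayChain:
    """The packaged ²²⁵Ac chain.

    By default ²¹⁷At is omitted (instantaneous equilibrium with ²²¹Fr);
    pass ``full=True`` for the four-member chain used in validation.
    """
    ref = resources.files("alphachain.data").joinpath("ac225_chain.yaml")
    with ref.open() as fh:
        chain = load_chain(fh)
    if full:
        return chain
    keep = [n for n in chain.members if n.name != "At-217"]
    return DecayChain(tuple(keep))


#: canonical member names of the packaged chain
AC225, FR221, AT217, BI213 = "Ac-225", "Fr-221", "At-217", "Bi-213"
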