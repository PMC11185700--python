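"""N-state chemical exchange and Bloch-McConnell machinery.

The kinetic skeleton shared by every stage of the pipeline is an
:class:`ExchangeModel`: a set of named conformational states (for KaiB:
Ground, FS, PD, Enigma) connected by first-order rate constants.  From it
we build the exchange generator (master-equation rate matrix), solve for
equilibrium populations, and — combined with per-residue NMR parameters
(:class:`SpinParams`) — assemble the full Bloch-McConnell evolution
generator used by the CEST simulator.

Conventions
-----------
* All internal rates are in s^-1.  Hour^-1 rates are accepted at the
  boundary via ``units="hr"`` and converted on entry.
* ppm -> rad/s conversion always uses an explicit nucleus Larmor
  frequency in MHz: ``d_omega = d_ppm * larmor_mhz * 2 * pi``.
* Magnetization lives in the standard augmented (3N+1)-dimensional space:
  (x, y, z) per state, state-major, plus one constant element that drives
  longitudinal recovery toward the equilibrium populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ExchangeModel",
    "SpinParams",
    "MagnetizationVector",
    "rate_matrix",
    "equilibrium_populations",
    "bloch_mcconnell_generator",
    "propagate",
    "equilibrium_magnetization",
    "two_state_from_kex",
]

SECONDS_PER_HOUR = 3600.0


def ppm_to_rad_per_s(delta_ppm: float | np.ndarray, larmor_mhz: float):
    """Angular frequency (rad/s) of a chemical-shift difference in ppm."""
    return np.asarray(delta_ppm) * larmor_mhz * 2.0 * math.pi


@dataclass(frozen=True)
class ExchangeModel:
    """Named conformational states plus pairwise first-order rate constants.

    Parameters
    ----------
    states
        Ordered state labels, e.g. ``("Ground", "FS")``.
    rates
        Mapping ``(from_state, to_state) -> rate``.  Rates are stored in
        s^-1; pass ``units="hr"`` to convert from hr^-1 on construction.

    A pair of states is *connected* iff at least one direction is > 0, and
    microscopic reversibility requires the reverse direction to be > 0 too.
    """

    states: tuple[str, ...]
    rates: Mapping[tuple[str, str], float]
    units: str = "s"

    def __post_init__(self):
        states = tuple(self.states)
        if len(set(states)) != len(states):
            raise ValueError(f"duplicate state labels in {states}")
        factor = {"s": 1.0, "hr": 1.0 / SECONDS_PER_HOUR}.get(self.units)
        if factor is None:
            raise ValueError(f"units must be 's' or 'hr', got {self.units!r}")
        rates = {}
        for (a, b), k in dict(self.rates).items():
            if a not in states or b not in states:
                raise ValueError(f"rate ({a!r}, {b!r}) references unknown state")
            if a == b:
                raise ValueError(f"self-rate ({a!r}, {a!r}) is not allowed")
            k = float(k) * factor
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"rate {a}->{b} must be finite and >= 0, got {k}")
            rates[(a, b)] = k
        for (a, b), k in rates.items():
            if k > 0 and rates.get((b, a), 0.0) == 0.0:
                raise ValueError(
                    f"rate {a}->{b} is {k} s^-1 but the reverse {b}->{a} is zero; "
                    "a reversible system needs both directions"
                )
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "units", "s")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def rate(self, a: str, b: str) -> float:
        """First-order rate constant a -> b in s^-1 (0 if absent)."""
        return self.rates.get((a, b), 0.0)

    @property
    def topology(self) -> frozenset[frozenset[str]]:
        """Connected (exchanging) state pairs."""
        return frozenset(
            frozenset((a, b)) for (a, b), k in self.rates.items() if k > 0
        )

    def connected_components(self) -> list[set[str]]:
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for pair in self.topology:
            a, b = tuple(pair)
            adj[a].add(b)
            adj[b].add(a)
        seen: set[str] = set()
        comps = []
        for s in self.states:
            if s in seen:
                continue
            stack, comp = [s], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def kex(self, a: str, b: str) -> float:
        """Exchange rate constant k_ab + k_ba for a state pair."""
        return self.rate(a, b) + self.rate(b, a)

    def scaled(self, factor: float) -> "ExchangeModel":
        """All rates multiplied by ``factor`` (e.g. a temperature surrogate)."""
        return ExchangeModel(
            self.states, {k: v * factor for k, v in self.rates.items()}
        )


def two_state_from_kex(
    major: str, minor: str, kex: float, p_minor: float
) -> ExchangeModel:
    """Two-state model from the (kex, p_b) parameterization.

    k_major->minor = p_b * kex and k_minor->major = (1 - p_b) * kex, so the
    equilibrium minor-state fraction is exactly ``p_minor``.
    """
    if not 0 < p_minor < 1:
        raise ValueError(f"p_minor must be in (0, 1), got {p_minor}")
    return ExchangeModel(
        (major, minor),
        {(major, minor): p_minor * kex, (minor, major): (1.0 - p_minor) * kex},
    )


def rate_matrix(model: ExchangeModel) -> np.ndarray:
    """Exchange generator K: K[i, j] = k_{j->i}, columns summing to zero.

    dp/dt = K p is the master equation for the state populations.
    """
    n = model.n_states
    K = np.zeros((n, n))
    for (a, b), k in model.rates.items():
        i, j = model.index(a), model.index(b)
        K[j, i] += k
        K[i, i] -= k
    return K


def equilibrium_populations(model: ExchangeModel) -> np.ndarray:
    """Stationary populations p with K p = 0, sum(p) = 1.

    Raises if the exchange graph is disconnected (naming the unreachable
    states) or if all rates are zero.
    """
    if model.n_states == 1:
        return np.array([1.0])
    if not model.topology:
        raise ValueError("all exchange rates are zero; no equilibrium defined")
    comps = model.connected_components()
    if len(comps) > 1:
        reachable = comps[0]
        unreachable = sorted(set(model.states) - reachable)
        raise ValueError(
            f"exchange graph is disconnected; states {unreachable} are not "
            f"reachable from {sorted(reachable)}"
        )
    K = rate_matrix(model)
    ns = scipy.linalg.null_space(K)
    if ns.shape[1] != 1:  # pragma: no cover - connected graphs give rank n-1
        raise ValueError(f"exchange generator has a {ns.shape[1]}-dim null space")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-12):
        raise ValueError(f"negative equilibrium population: {p}")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def _as_state_map(value, states: Sequence[str]) -> dict[str, float]:
    """Broadcast a scalar to all states, or validate a per-state mapping."""
    if isinstance(value, Mapping):
        return {s: float(v) for s, v in value.items()}
    return {s: float(value) for s in states}


@dataclass(frozen=True)
class SpinParams:
    """Per-residue, per-state NMR parameters.

    ``shifts_ppm``, ``r1``, ``r2`` map state label -> value; scalars are
    broadcast to every state named in ``shifts_ppm``.  ``larmor_mhz`` is the
    nucleus Larmor frequency used for every ppm -> rad/s conversion.
    """

    residue: str
    shifts_ppm: Mapping[str, float]
    r1: Mapping[str, float] | float
    r2: Mapping[str, float] | float
    larmor_mhz: float

    def __post_init__(self):
        shifts = {s: float(v) for s, v in dict(self.shifts_ppm).items()}
        states = list(shifts)
        r1 = _as_state_map(self.r1, states)
        r2 = _as_state_map(self.r2, states)
        for name, m in (("r1", r1), ("r2", r2)):
            for s, v in m.items():
                if v <= 0:
                    raise ValueError(f"{name}[{s!r}] must be > 0, got {v}")
        if self.larmor_mhz <= 0:
            raise ValueError(f"larmor_mhz must be > 0, got {self.larmor_mhz}")
        object.__setattr__(self, "shifts_ppm", shifts)
        object.__setattr__(self, "r1", r1)
        object.__setattr__(self, "r2", r2)

    def missing_states(self, model: ExchangeModel) -> list[str]:
        out = []
        for s in model.states:
            if s not in self.shifts_ppm or s not in self.r1 or s not in self.r2:
                out.append(s)
        return out

    def require_states(self, model: ExchangeModel) -> None:
        missing = self.missing_states(model)
        if missing:
            raise ValueError(
                f"residue {self.residue!r} lacks spin parameters for states "
                f"{missing}"
            )

    def delta_omega(self, a: str, b: str) -> float:
        """Shift difference b - a in rad/s."""
        return float(
            ppm_to_rad_per_s(self.shifts_ppm[b] - self.shifts_ppm[a], self.larmor_mhz)
        )


@dataclass
class MagnetizationVector:
    """Magnetization in the augmented (3N+1) basis: (x,y,z) per state + 1."""

    states: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = 3 * len(self.states) + 1
        if self.values.shape[-1] != expected:
            raise ValueError(
                f"expected vector of length {expected} for {len(self.states)} "
                f"states, got {self.values.shape[-1]}"
            )

    def component(self, comp: str, state: str) -> float:
        i = self.states.index(state)
        j = {"x": 0, "y": 1, "z": 2}[comp]
        return float(self.values[..., 3 * i + j])


def equilibrium_magnetization(model: ExchangeModel) -> MagnetizationVector:
    """Pure longitudinal magnetization at thermal equilibrium (z_i = p_i)."""
    p = equilibrium_populations(model)
    v = np.zeros(3 * model.n_states + 1)
    v[2::3] = p
    v[-1] = 1.0
    return MagnetizationVector(model.states, v)


def bloch_mcconnell_generator(
    model: ExchangeModel,
    spin: SpinParams,
    b1_hz: float,
    carrier_ppm: float | np.ndarray,
) -> np.ndarray:
    """Augmented Bloch-McConnell evolution generator.

    Combines, for each state i: rotating-frame precession at
    ``(shift_i - carrier) * larmor_mhz * 2*pi`` rad/s, RF nutation
    ``omega1 = 2*pi*b1_hz`` about x, autorelaxation (-R2 on x,y; -R1 on z)
    with longitudinal recovery toward the equilibrium population via the
    constant element, plus the exchange generator acting block-wise on each
    Cartesian component.

    ``carrier_ppm`` may be an array, in which case a stacked
    ``(m, 3N+1, 3N+1)`` array of generators is returned (one per offset).
    """
    spin.require_states(model)
    n = model.n_states
    dim = 3 * n + 1
    p_eq = equilibrium_populations(model)
    K = rate_matrix(model)
    omega1 = 2.0 * math.pi * b1_hz

    carriers = np.atleast_1d(np.asarray(carrier_ppm, dtype=float))
    m = carriers.shape[0]
    G = np.zeros((m, dim, dim))
    # exchange acts identically on x, y and z of every state
    G[:, : 3 * n : 3, : 3 * n : 3] = K
    G[:, 1 : 3 * n : 3, 1 : 3 * n : 3] = K
    G[:, 2 : 3 * n : 3, 2 : 3 * n : 3] = K
    for i, s in enumerate(model.states):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        dw = ppm_to_rad_per_s(spin.shifts_ppm[s] - carriers, spin.larmor_mhz)
        G[:, x, x] += -spin.r2[s]
        G[:, y, y] += -spin.r2[s]
        G[:, z, z] += -spin.r1[s]
        G[:, x, y] += -dw
        G[:, y, x] += dw
        G[:, y, z] += -omega1
        G[:, z, y] += omega1
        G[:, z, -1] = spin.r1[s] * p_eq[i]
    if np.isscalar(carrier_ppm) or np.ndim(carrier_ppm) == 0:
        return G[0]
    return G


def propagate(
    generator: np.ndarray,
    duration_s: float,
    initial: MagnetizationVector | np.ndarray,
) -> MagnetizationVector | np.ndarray:
    """Apply expm(generator * duration) to the initial magnetization.

    ``generator`` may be a single (d, d) matrix or a stacked (m, d, d)
    array; stacked generators are exponentiated in one batched call.
    The constant element of the augmented basis is preserved at its input
    value because its generator row is identically zero.
    """
    if duration_s < 0:
        raise ValueError(f"duration must be >= 0, got {duration_s}")
    G = np.asarray(generator)
    if not np.all(np.isfinite(G)):
        raise ValueError("generator contains non-finite entries")
    vec = initial.values if isinstance(initial, MagnetizationVector) else np.asarray(initial)
    if duration_s == 0:
        out = np.broadcast_to(vec, G.shape[:-2] + vec.shape).copy()
    else:
        U = scipy.linalg.expm(G * duration_s)
        out = U @ vec
    if isinstance(initial, MagnetizationVector):
        return MagnetizationVector(initial.states, out)
    return out
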