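"""Free-energy landscape assembly from populations and rates.

State free energies come from Boltzmann inversion of populations relative
to a reference state (Ground by default); barrier heights come from the
Eyring equation k = kappa * (kB T / h) * exp(-dG'/RT) with the
transmission coefficient kappa assumed to be 1.  Populations measured by
CEST (which cannot see the FS state) are reconciled with the real-time
Ground/FS split by preserving each source's ratios to Ground.  Because
absolute free energies at different temperatures share no common zero, a
constant offset (default 2 kcal/mol) is added to the cold-temperature
landscape so that no barrier decreases on cooling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "KB_SI",
    "H_SI",
    "PeakVolumeTable",
    "LandscapeResult",
    "populations_from_volumes",
    "reconcile_populations",
    "state_free_energy",
    "eyring_barrier",
    "rate_from_barrier",
    "apply_cold_offset",
    "assemble_landscape",
    "celsius_to_kelvin",
]

logger = logging.getLogger(__name__)

# CODATA physical constants (6 significant figures where not exact)
R_KCAL = 1.98720e-3  # gas constant, kcal / (mol K)
KB_SI = 1.380649e-23  # Boltzmann constant, J / K (exact)
H_SI = 6.62607e-34  # Planck constant, J s


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass
class PeakVolumeTable:
    """Long-format (residue, state, temperature, volume) records."""

    data: pd.DataFrame
    states: tuple[str, ...] = ("Ground", "FS", "PD")

    def __post_init__(self):
        required = {"residue", "state", "temperature_c", "volume"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"volume table missing columns {sorted(missing)}")
        if (self.data["volume"] < 0).any():
            raise ValueError("volumes must be >= 0")


def populations_from_volumes(
    table: PeakVolumeTable | pd.DataFrame,
    states: Sequence[str] = ("Ground", "FS", "PD"),
) -> pd.DataFrame:
    """Per-temperature state populations from per-residue volume shares.

    A residue contributes at a temperature only when all states in
    ``states`` have a volume entry there; its populations are its volumes
    normalized to unit sum.  Returns per temperature and state the mean and
    SD over contributing residues.  Temperatures with no complete residue
    are omitted with a warning.
    """
    df = table.data if isinstance(table, PeakVolumeTable) else table
    states = tuple(states)
    rows = []
    for t_c, group in df.groupby("temperature_c"):
        wide = group.pivot_table(
            index="residue", columns="state", values="volume", aggfunc="first"
        )
        have = [s for s in states if s in wide.columns]
        complete = wide.dropna(subset=list(states)) if len(have) == len(states) else wide.iloc[:0]
        if complete.empty:
            warnings.warn(
                f"no residue has all states {states} at {t_c} C; temperature omitted"
            )
            continue
        vols = complete[list(states)].to_numpy(dtype=float)
        pops = vols / vols.sum(axis=1, keepdims=True)
        for j, s in enumerate(states):
            rows.append(
                {
                    "temperature_c": float(t_c),
                    "state": s,
                    "population": float(pops[:, j].mean()),
                    "sd": float(pops[:, j].std(ddof=1)) if pops.shape[0] > 1 else 0.0,
                    "n_residues": int(pops.shape[0]),
                }
            )
    if not rows:
        raise ValueError("no temperature had a complete residue")
    return pd.DataFrame(rows)


def reconcile_populations(
    cest_populations: Mapping[str, float],
    realtime_ground_fs: Mapping[str, float] | tuple[float, float],
) -> dict[str, float]:
    """Merge CEST and real-time populations into a four-state vector.

    CEST sees {Enigma, Ground, PD} but not FS; real-time NMR measures the
    Ground/FS split.  The merged vector preserves the Enigma/Ground and
    PD/Ground ratios from CEST and the FS/Ground ratio from real-time, and
    renormalizes all four states to unit sum.
    """
    if not isinstance(realtime_ground_fs, Mapping):
        realtime_ground_fs = {
            "Ground": realtime_ground_fs[0],
            "FS": realtime_ground_fs[1],
        }
    g_cest = cest_populations.get("Ground", 0.0)
    g_rt = realtime_ground_fs.get("Ground", 0.0)
    if g_cest <= 0 or g_rt <= 0:
        raise ValueError("Ground population must be > 0 in both sources")
    ratios = {"Ground": 1.0}
    for s, p in cest_populations.items():
        if s != "Ground":
            ratios[s] = p / g_cest
    ratios["FS"] = realtime_ground_fs.get("FS", 0.0) / g_rt
    total = sum(ratios.values())
    return {s: v / total for s, v in ratios.items()}


def state_free_energy(p_state: float, p_reference: float, t_kelvin: float) -> float:
    """Boltzmann free energy -R T ln(p / p_ref) in kcal/mol."""
    if p_state <= 0 or p_reference <= 0:
        raise ValueError("populations must be > 0")
    return -R_KCAL * t_kelvin * math.log(p_state / p_reference)


def eyring_barrier(k_per_s: float, t_kelvin: float, kappa: float = 1.0) -> float:
    """Activation free energy dG' = -R T ln(k h / (kappa kB T)), kcal/mol."""
    if k_per_s <= 0:
        raise ValueError(f"rate must be > 0, got {k_per_s}")
    if t_kelvin <= 0 or kappa <= 0:
        raise ValueError("temperature and kappa must be > 0")
    return -R_KCAL * t_kelvin * math.log(k_per_s * H_SI / (kappa * KB_SI * t_kelvin))


def rate_from_barrier(dg_kcal: float, t_kelvin: float, kappa: float = 1.0) -> float:
    """Eyring rate k = kappa (kB T / h) exp(-dG'/RT) in s^-1."""
    if t_kelvin <= 0:
        raise ValueError("temperature must be > 0")
    return kappa * (KB_SI * t_kelvin / H_SI) * math.exp(-dg_kcal / (R_KCAL * t_kelvin))


@dataclass
class LandscapeResult:
    """Free energies (kcal/mol) of states and barriers at one temperature."""

    temperature_k: float
    reference_state: str
    state_dg: dict[str, float]
    barriers: dict[tuple[str, str], float]
    kappa: float = 1.0
    provenance: dict = field(default_factory=dict)
    offset_applied: float = 0.0

    def __post_init__(self):
        # the reference state sits at offset_applied (0 before any cold offset)
        for v in list(self.state_dg.values()) + list(self.barriers.values()):
            if not np.isfinite(v):
                raise ValueError("landscape contains non-finite energies")

    def transition_state_levels(self) -> dict[tuple[str, str], float]:
        """Absolute transition-state levels dG(a) + dG'(a->b), for diagrams."""
        return {
            (a, b): self.state_dg.get(a, 0.0) + v
            for (a, b), v in self.barriers.items()
        }

    def shifted(self, offset: float) -> "LandscapeResult":
        return LandscapeResult(
            temperature_k=self.temperature_k,
            reference_state=self.reference_state,
            state_dg={s: v + offset for s, v in self.state_dg.items()},
            barriers={k: v + offset for k, v in self.barriers.items()},
            kappa=self.kappa,
            provenance=dict(self.provenance),
            offset_applied=self.offset_applied + offset,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": "state",
                "label": s,
                "dg_kcal": v,
                "provenance": self.provenance.get(s, ""),
            }
            for s, v in self.state_dg.items()
        ]
        rows += [
            {
                "kind": "barrier",
                "label": f"{a}->{b}",
                "dg_kcal": v,
                "provenance": self.provenance.get((a, b), ""),
            }
            for (a, b), v in self.barriers.items()
        ]
        return pd.DataFrame(rows)


def apply_cold_offset(
    landscape_cold: LandscapeResult,
    landscape_warm: LandscapeResult,
    offset_kcal: float = 2.0,
) -> LandscapeResult:
    """Add a constant offset to every cold-temperature free energy.

    Absolute free energies at two temperatures share no common zero; the
    offset (default 2 kcal/mol) enforces the physical requirement that an
    absolute barrier height cannot decrease with temperature.  If a shared
    barrier is still lower at the colder temperature afterwards, a warning
    is raised.
    """
    adjusted = landscape_cold.shifted(offset_kcal)
    warm_levels = landscape_warm.transition_state_levels()
    cold_levels = adjusted.transition_state_levels()
    for key, warm_val in warm_levels.items():
        cold_val = cold_levels.get(key)
        if cold_val is not None and cold_val < warm_val - 1e-9:
            warnings.warn(
                f"barrier {key[0]}->{key[1]} is still lower at "
                f"{adjusted.temperature_k:.1f} K ({cold_val:.2f}) than at "
                f"{landscape_warm.temperature_k:.1f} K ({warm_val:.2f}) after the "
                f"{offset_kcal} kcal/mol offset"
            )
    return adjusted


def assemble_landscape(
    populations_by_temp: Mapping[float, Mapping[str, float]],
    rates_by_temp: Mapping[float, Mapping[tuple[str, str], float]],
    reference_state: str = "Ground",
    kappa: float = 1.0,
    cold_offset_kcal: float = 2.0,
    provenance: Mapping | None = None,
) -> dict[float, LandscapeResult]:
    """Build per-temperature landscapes and apply the cold offset.

    Parameters
    ----------
    populations_by_temp
        temperature (C) -> state -> population (sum ~ 1; reconciled
        beforehand with :func:`reconcile_populations` when populations come
        from both CEST and real-time sources).
    rates_by_temp
        temperature (C) -> (from_state, to_state) -> rate in s^-1.
        Transitions without a measured rate are simply absent.
    cold_offset_kcal
        Added to every landscape colder than the warmest one.
    """
    provenance = dict(provenance or {})
    results: dict[float, LandscapeResult] = {}
    for t_c, pops in populations_by_temp.items():
        t_k = celsius_to_kelvin(t_c)
        p_ref = pops.get(reference_state, 0.0)
        if p_ref <= 0:
            raise ValueError(
                f"missing {reference_state} population at {t_c} C"
            )
        state_dg = {
            s: state_free_energy(p, p_ref, t_k) for s, p in pops.items() if p > 0
        }
        barriers = {}
        for (a, b), k in rates_by_temp.get(t_c, {}).items():
            if k is None or k <= 0:
                logger.info("no rate for %s->%s at %s C; barrier omitted", a, b, t_c)
                continue
            # activation energy measured from the departing state a
            barriers[(a, b)] = eyring_barrier(k, t_k, kappa)
        results[t_c] = LandscapeResult(
            temperature_k=t_k,
            reference_state=reference_state,
            state_dg=state_dg,
            barriers=barriers,
            kappa=kappa,
            provenance=provenance.get(t_c, {}),
        )
    if len(results) >= 2 and cold_offset_kcal:
        warmest = max(results)
        for t_c in list(results):
            if t_c != warmest:
                results[t_c] = apply_cold_offset(
                    results[t_c], results[warmest], cold_offset_kcal
                )
    return results


def plot_landscape(results: Mapping[float, LandscapeResult], ax=None):
    """Level diagram of state energies and barriers per temperature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, (t_c, ls) in enumerate(sorted(results.items())):
        xs = np.arange(len(ls.state_dg))
        for x, (s, dg) in zip(xs, ls.state_dg.items()):
            ax.hlines(dg, x - 0.3 + i * 0.05, x + 0.3 + i * 0.05,
                      label=f"{s} ({t_c} C)" if i == 0 else None)
            ax.annotate(s, (x, dg), textcoords="offset points", xytext=(0, 4))
    ax.set_ylabel("free energy (kcal/mol)")
    ax.set_xticks([])
    return ax
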