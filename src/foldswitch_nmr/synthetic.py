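"""Synthetic-data generation for every pipeline stage.

Generates pseudo-3D peak-intensity time courses, 15N/13C CEST profiles,
CPMG dispersion curves, and per-temperature peak-volume tables with the
statistical structure the analysis assumes: exponential relaxation toward
equilibrium for real-time data, Bloch-McConnell profiles with additive
Gaussian noise for CEST, echo-train simulation for CPMG, and
multiplicative noise on volume shares.

The KaiB fixtures encode the study conditions of the fold-switching
system: Ground <-> FS interconversion at 0.09 / 0.36 hr^-1 at 20 C
(accelerated to 0.24 / 0.98 hr^-1 by the prolyl isomerase CypA),
Ground <-> Enigma exchange with kex = 173 s^-1 and a 7-8% Enigma
population, Ground <-> PD exchange near 2 s^-1 with a PD population of 3%
at 20 C rising to 75% at 4 C, CEST acquisition at B1 = 10 or 20 Hz with
Trelax = 0.5 or 0.4 s over 104-135 ppm (15N) in 25 Hz steps, and
constant-time CPMG with T = 60 ms and n_cyc = 0-60 with duplicates at
0, 30 and 60.

Every generator is a pure function of (fixture, options, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cest import CESTProfile, simulate_cest_profile
from .cpmg import CPMGProfile, r2eff_from_intensity, simulate_cpmg
from .exchange import ExchangeModel, SpinParams, two_state_from_kex
from .landscape import PeakVolumeTable
from .realtime import TimeCourse, _ground_fraction

__all__ = [
    "AcquisitionSpec",
    "ScenarioFixture",
    "SCENARIOS",
    "kaib_fixture",
    "gen_tjump",
    "gen_cest",
    "gen_cpmg",
    "gen_volume_table",
]

# Larmor frequencies (MHz) on an 800 MHz (1H) spectrometer
N15_LARMOR_800 = 81.08
C13_LARMOR_800 = 201.16

DEADTIME_HR = 7.0 / 60.0  # spectrometer re-shim/acquisition deadtime after the jump


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition parameters for one experiment kind."""

    kind: str  # "realtime" | "cest" | "cpmg"
    b1_hz: float | tuple[float, ...] | None = None
    trelax_s: float | tuple[float, ...] | None = None
    offsets_ppm: tuple[float, ...] | None = None
    tct_s: float | None = None
    n_cyc: tuple[int, ...] | None = None
    duplicate_n_cyc: tuple[int, ...] = ()
    times_hr: tuple[float, ...] | None = None
    deadtime_hr: float = DEADTIME_HR
    larmor_mhz: float | None = None

    def __post_init__(self):
        if self.kind not in ("realtime", "cest", "cpmg"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        for name in ("offsets_ppm", "times_hr"):
            grid = getattr(self, name)
            if grid is not None and np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.kind == "cest":
            if self.trelax_s is None or np.any(np.asarray(self.trelax_s) <= 0):
                raise ValueError("cest acquisition needs trelax_s > 0")
            n_b1 = np.size(self.b1_hz)
            if n_b1 != np.size(self.trelax_s):
                raise ValueError("b1_hz and trelax_s must pair up")
        if self.kind == "cpmg" and (self.tct_s is None or self.tct_s <= 0):
            raise ValueError("cpmg acquisition needs tct_s > 0")

    def cest_fields(self) -> list[tuple[float, float]]:
        """(B1 Hz, Trelax s) pairs; a single-field spec yields one pair."""
        b1s = np.atleast_1d(np.asarray(self.b1_hz, dtype=float))
        trs = np.atleast_1d(np.asarray(self.trelax_s, dtype=float))
        return list(zip(b1s.tolist(), trs.tolist()))


@dataclass(frozen=True)
class ScenarioFixture:
    """A fully specified study condition: kinetics, spins, acquisition."""

    name: str
    model: ExchangeModel | None
    spins: tuple[SpinParams, ...]
    acquisition: AcquisitionSpec | None
    noise: float
    p_ground_start: float | None = None  # pre-jump Ground fraction (realtime)
    population_table: pd.DataFrame | None = None  # volumes scenario


def _offsets(start_ppm, stop_ppm, step_hz, larmor_mhz):
    step = step_hz / larmor_mhz
    n = int(math.floor((stop_ppm - start_ppm) / step)) + 1
    return tuple(start_ppm + step * np.arange(n))


def _cest_15n_spins(larmor, r2_ground=10.0, r2_pd=6.0, r1=1.3):
    """Backbone 15N spins for the three-state Enigma-Ground-PD chain.

    The first residue mirrors Asn84: Ground 119.5 ppm with the Enigma dip
    at 125.2 ppm and the PD dip at 122.3 ppm; the rest spread the shift
    differences over the observable window.
    """
    table = [
        # (residue, ground, enigma, pd)
        ("N84", 119.5, 125.2, 122.3),
        ("res2", 112.0, 116.5, 110.0),
        ("res3", 124.0, 120.5, 127.0),
        ("res4", 117.0, 113.0, 119.8),
        ("res5", 128.5, 132.0, 125.5),
        ("res6", 109.5, 113.5, 107.5),
        ("res7", 121.5, 126.8, 118.0),
        ("res8", 115.5, 111.0, 113.2),
        ("res9", 126.5, 129.5, 130.5),
        ("res10", 110.8, 108.0, 114.5),
        ("res11", 122.8, 119.0, 125.9),
    ]
    spins = []
    for residue, g, e, p in table:
        spins.append(
            SpinParams(
                residue=residue,
                shifts_ppm={"Ground": g, "Enigma": e, "PD": p},
                r1=r1,
                r2={"Ground": r2_ground, "Enigma": r2_ground, "PD": r2_pd},
                larmor_mhz=larmor,
            )
        )
    return tuple(spins)


def _methyl_spins(larmor):
    """Methyl 13C spins with minor-state shift differences of 0.5-4 ppm."""
    table = [
        ("L82", 19.0, 4.0),
        ("V81", 16.5, 3.2),
        ("L85", 21.5, 2.4),
        ("I54", 12.5, 1.7),
        ("I57", 14.8, 1.0),
        ("I72", 18.0, 0.5),
    ]
    spins = []
    for residue, g, dw in table:
        spins.append(
            SpinParams(
                residue=residue,
                shifts_ppm={"Ground": g, "Enigma": g + dw},
                r1=1.0,
                r2={"Ground": 10.0, "Enigma": 10.0},
                larmor_mhz=larmor,
            )
        )
    return tuple(spins)


def _chain_model(p_e, p_pd, k_ge, k_gpd):
    """Enigma <-> Ground <-> PD chain with prescribed populations.

    Reverse rates follow detailed balance: k_eg = k_ge * p_G / p_E and
    k_pdg = k_gpd * p_G / p_PD.
    """
    p_g = 1.0 - p_e - p_pd
    return ExchangeModel(
        ("Ground", "Enigma", "PD"),
        {
            ("Ground", "Enigma"): k_ge,
            ("Enigma", "Ground"): k_ge * p_g / p_e,
            ("Ground", "PD"): k_gpd,
            ("PD", "Ground"): k_gpd * p_g / p_pd,
        },
    )


def _volume_population_table():
    """Per-temperature Ground/FS/PD population triplets.

    4 C and 10 C PD levels (75% and 30%) are the anchored values; the FS
    share is held in the observed 10-20% band and Ground takes the rest.
    """
    rows = [
        (4.0, 0.15, 0.10, 0.75),
        (10.0, 0.55, 0.15, 0.30),
        (20.0, 0.80, 0.17, 0.03),
    ]
    return pd.DataFrame(
        rows, columns=["temperature_c", "Ground", "FS", "PD"]
    )


def _build_scenarios() -> dict[str, ScenarioFixture]:
    scenarios = {}

    times = tuple(DEADTIME_HR + np.linspace(0.0, 24.0, 20))
    scenarios["tjump_20C"] = ScenarioFixture(
        name="tjump_20C",
        model=ExchangeModel(
            ("Ground", "FS"),
            {("Ground", "FS"): 0.09, ("FS", "Ground"): 0.36},
            units="hr",
        ),
        spins=(),
        acquisition=AcquisitionSpec(kind="realtime", times_hr=times),
        noise=0.02,
        p_ground_start=0.60,
    )
    times_cypa = tuple(DEADTIME_HR + np.linspace(0.0, 10.0, 20))
    scenarios["tjump_cypa_20C"] = ScenarioFixture(
        name="tjump_cypa_20C",
        model=ExchangeModel(
            ("Ground", "FS"),
            {("Ground", "FS"): 0.24, ("FS", "Ground"): 0.98},
            units="hr",
        ),
        spins=(),
        acquisition=AcquisitionSpec(kind="realtime", times_hr=times_cypa),
        noise=0.02,
        p_ground_start=0.60,
    )

    offsets_15n = _offsets(104.0, 135.0, 25.0, N15_LARMOR_800)
    # the backbone 15N CEST experiments pair a 10 Hz B1 with a 500 ms
    # relaxation delay and a 20 Hz B1 with 400 ms; fitting both fields
    # jointly is what separates minor-state R2 from the exchange rates
    scenarios["cest15N_20C"] = ScenarioFixture(
        name="cest15N_20C",
        model=_chain_model(p_e=0.08, p_pd=0.03, k_ge=12.0, k_gpd=2.0),
        spins=_cest_15n_spins(N15_LARMOR_800),
        acquisition=AcquisitionSpec(
            kind="cest",
            b1_hz=(10.0, 20.0),
            trelax_s=(0.5, 0.4),
            offsets_ppm=offsets_15n,
            larmor_mhz=N15_LARMOR_800,
        ),
        noise=0.01,
    )
    scenarios["cest15N_4C"] = ScenarioFixture(
        name="cest15N_4C",
        model=_chain_model(p_e=0.02, p_pd=0.75, k_ge=12.0, k_gpd=2.0),
        spins=_cest_15n_spins(N15_LARMOR_800, r2_ground=14.0, r2_pd=8.0),
        acquisition=AcquisitionSpec(
            kind="cest",
            b1_hz=(10.0, 20.0),
            trelax_s=(0.5, 0.4),
            offsets_ppm=offsets_15n,
            larmor_mhz=N15_LARMOR_800,
        ),
        noise=0.01,
    )

    offsets_13c = _offsets(8.0, 25.0, 40.0, C13_LARMOR_800)
    scenarios["methyl_cest_20C"] = ScenarioFixture(
        name="methyl_cest_20C",
        model=two_state_from_kex("Ground", "Enigma", kex=173.0, p_minor=0.07),
        spins=_methyl_spins(C13_LARMOR_800),
        acquisition=AcquisitionSpec(
            kind="cest",
            b1_hz=20.0,
            trelax_s=0.4,
            offsets_ppm=offsets_13c,
            larmor_mhz=C13_LARMOR_800,
        ),
        noise=0.01,
    )

    cpmg_spins = tuple(
        SpinParams(
            residue=res,
            shifts_ppm={"Ground": 120.0, "Enigma": 120.0 + dw},
            r1=1.3,
            r2={"Ground": 12.0, "Enigma": 12.0},
            larmor_mhz=N15_LARMOR_800,
        )
        for res, dw in [("res_dw2", 2.0), ("res_dw3", 3.0), ("res_dw4", 4.0)]
    )
    scenarios["cpmg_enigma_25C"] = ScenarioFixture(
        name="cpmg_enigma_25C",
        model=two_state_from_kex("Ground", "Enigma", kex=173.0, p_minor=0.07),
        spins=cpmg_spins,
        acquisition=AcquisitionSpec(
            kind="cpmg",
            tct_s=0.060,
            n_cyc=tuple(range(0, 61)),
            duplicate_n_cyc=(0, 30, 60),
            larmor_mhz=N15_LARMOR_800,
        ),
        noise=0.005,
    )

    scenarios["volumes_by_temperature"] = ScenarioFixture(
        name="volumes_by_temperature",
        model=None,
        spins=(),
        acquisition=None,
        noise=0.05,
        population_table=_volume_population_table(),
    )
    return scenarios


SCENARIOS = _build_scenarios()


def kaib_fixture(scenario_name: str) -> ScenarioFixture:
    """Deterministic, fully populated fixture for a named scenario."""
    try:
        return SCENARIOS[scenario_name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_name!r}; valid names: "
            f"{sorted(SCENARIOS)}"
        ) from None


def gen_tjump(
    fixture: ScenarioFixture,
    n_ground_peaks: int,
    n_fs_peaks: int,
    times_hr: Sequence[float] | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
    below_threshold_frac: float = 0.0,
) -> list[TimeCourse]:
    """Synthetic temperature-jump peak-intensity time courses.

    Each Ground peak j has I_j(t) = A_j * p_G(t) and each FS peak
    A_j * (1 - p_G(t)), where p_G relaxes from the pre-jump equilibrium
    ``fixture.p_ground_start`` to the post-jump equilibrium with observed
    rate k_f + k_r, plus Gaussian noise sigma = noise_frac * A_j.
    Amplitudes are drawn so the fitted peak amplitude clears the 4e5
    intensity filter; ``below_threshold_frac`` optionally adds a fraction
    of deliberately weak peaks to exercise the filter.
    """
    if fixture.acquisition is None or fixture.acquisition.kind != "realtime":
        raise ValueError(f"fixture {fixture.name!r} is not a realtime scenario")
    t = np.asarray(
        times_hr if times_hr is not None else fixture.acquisition.times_hr,
        dtype=float,
    )
    if t.size == 0:
        raise ValueError("empty time grid")
    k_f = fixture.model.rate("Ground", "FS") * 3600.0  # back to hr^-1
    k_r = fixture.model.rate("FS", "Ground") * 3600.0
    p0 = fixture.p_ground_start
    rng = np.random.default_rng(seed)

    p_g = _ground_fraction(t, k_f, k_r, p0)
    out = []
    for state, n_peaks in (("Ground", n_ground_peaks), ("FS", n_fs_peaks)):
        p = p_g if state == "Ground" else 1.0 - p_g
        n_below = int(round(below_threshold_frac * n_peaks))
        for j in range(n_peaks):
            if j < n_peaks - n_below:
                amp = rng.uniform(1.2e6, 6e6)
            else:
                amp = rng.uniform(1e5, 4e5)
            sigma = noise_frac * amp if noise_frac > 0 else 1e-6 * amp
            noise = rng.normal(size=t.size) * sigma if noise_frac > 0 else 0.0
            out.append(
                TimeCourse(
                    peak_id=f"{state.lower()}_{j:03d}",
                    state=state,
                    times_hr=t,
                    intensities=amp * p + noise,
                    sigma=sigma,
                )
            )
    return out


def _select_spins(fixture: ScenarioFixture, residues) -> list[SpinParams]:
    if residues is None:
        return list(fixture.spins)
    if isinstance(residues, int):
        if residues > len(fixture.spins):
            raise ValueError(
                f"fixture {fixture.name!r} has only {len(fixture.spins)} residues"
            )
        return list(fixture.spins[:residues])
    by_id = {s.residue: s for s in fixture.spins}
    missing = [r for r in residues if r not in by_id]
    if missing:
        raise ValueError(
            f"residues {missing} lack spin parameters in fixture {fixture.name!r}"
        )
    return [by_id[r] for r in residues]


def gen_cest(
    fixture: ScenarioFixture,
    residues: int | Sequence[str] | None = None,
    noise_abs: float = 0.01,
    seed: int = 0,
) -> list[CESTProfile]:
    """Synthetic CEST profiles: Bloch-McConnell simulation + Gaussian noise.

    ``noise_abs`` is the absolute i.i.d. sigma on I/I0 (the reference
    normalization is exact).  ``residues`` may be a count, a list of
    residue ids, or None for all fixture residues.
    """
    if fixture.acquisition is None or fixture.acquisition.kind != "cest":
        raise ValueError(f"fixture {fixture.name!r} is not a cest scenario")
    acq = fixture.acquisition
    spins = _select_spins(fixture, residues)
    rng = np.random.default_rng(seed)
    profiles = []
    for spin in spins:
        for b1, trelax in acq.cest_fields():
            clean = simulate_cest_profile(
                fixture.model,
                spin,
                b1,
                trelax,
                np.asarray(acq.offsets_ppm),
            )
            noisy = clean.intensity + (
                rng.normal(size=clean.intensity.size) * noise_abs
                if noise_abs > 0
                else 0.0
            )
            profiles.append(
                CESTProfile(
                    residue=spin.residue,
                    b1_hz=b1,
                    trelax_s=trelax,
                    offsets_ppm=clean.offsets_ppm,
                    intensity=np.clip(noisy, -0.1, 1.2),
                    sigma=np.full_like(noisy, noise_abs if noise_abs > 0 else 1e-6),
                    larmor_mhz=spin.larmor_mhz,
                    observed_state=clean.observed_state,
                )
            )
    return profiles


def gen_cpmg(
    fixture: ScenarioFixture,
    residues: int | Sequence[str] | None = None,
    noise_abs: float = 0.005,
    seed: int = 0,
) -> list[CPMGProfile]:
    """Synthetic CPMG dispersion curves with duplicate-point uncertainties.

    ``noise_abs`` is the sigma on the intensity ratio I/I0; it is applied
    to the simulated ratios and propagated to R2eff.  Duplicate points are
    generated at the fixture's duplicate n_cyc values (0 is the reference
    and carries no R2eff point); per-point sigma is the larger of the
    noise-propagated and duplicate-difference estimates where duplicates
    exist.
    """
    if fixture.acquisition is None or fixture.acquisition.kind != "cpmg":
        raise ValueError(f"fixture {fixture.name!r} is not a cpmg scenario")
    acq = fixture.acquisition
    spins = _select_spins(fixture, residues)
    rng = np.random.default_rng(seed)
    out = []
    for spin in spins:
        clean = simulate_cpmg(fixture.model, spin, acq.tct_s, acq.n_cyc)
        nus, r2s, sigmas = [], [], []
        dup_values: dict[float, list[float]] = {}
        for nu, r2 in zip(clean.nu_hz, clean.r2eff):
            n_rep = 2 if round(nu * acq.tct_s) in acq.duplicate_n_cyc else 1
            for _ in range(n_rep):
                ratio = math.exp(-r2 * acq.tct_s)
                noisy_ratio = ratio + (
                    rng.normal() * noise_abs if noise_abs > 0 else 0.0
                )
                r2_noisy = r2eff_from_intensity(max(noisy_ratio, 1e-9), 1.0, acq.tct_s)
                sigma_pt = (noise_abs if noise_abs > 0 else 1e-9) / (ratio * acq.tct_s)
                nus.append(nu)
                r2s.append(r2_noisy)
                sigmas.append(sigma_pt)
                dup_values.setdefault(nu, []).append(r2_noisy)
        nus = np.asarray(nus)
        r2s = np.asarray(r2s)
        sigmas = np.asarray(sigmas)
        # max rule: noise-based vs duplicate-based uncertainty
        for nu, vals in dup_values.items():
            if len(vals) == 2:
                dup_sigma = abs(vals[0] - vals[1]) / math.sqrt(2.0)
                mask = nus == nu
                sigmas[mask] = np.maximum(sigmas[mask], dup_sigma)
        out.append(
            CPMGProfile(
                residue=spin.residue,
                nu_hz=nus,
                r2eff=r2s,
                sigma=sigmas,
                tct_s=acq.tct_s,
                duplicates={
                    nu: vals for nu, vals in dup_values.items() if len(vals) > 1
                },
            )
        )
    return out


def gen_volume_table(
    fixture: ScenarioFixture,
    n_residues: int = 11,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> PeakVolumeTable:
    """Synthetic per-temperature peak-volume table for three states.

    Per residue and temperature, volume = scale_r * p_state * (1 + eps)
    with eps ~ N(0, noise_frac); scale_r is a per-residue overall signal
    level.  Populations in the fixture table must sum to 1.
    """
    if fixture.population_table is None:
        raise ValueError(f"fixture {fixture.name!r} has no population table")
    pops = fixture.population_table
    states = [c for c in pops.columns if c != "temperature_c"]
    sums = pops[states].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"fixture populations do not sum to 1: {sums.tolist()}")
    rng = np.random.default_rng(seed)
    scales = rng.uniform(0.5, 2.0, size=n_residues)
    rows = []
    for _, row in pops.iterrows():
        for r in range(n_residues):
            for s in states:
                eps = rng.normal() * noise_frac if noise_frac > 0 else 0.0
                rows.append(
                    {
                        "residue": f"res{r:02d}",
                        "state": s,
                        "temperature_c": float(row["temperature_c"]),
                        "volume": max(scales[r] * row[s] * (1.0 + eps), 0.0),
                    }
                )
    return PeakVolumeTable(pd.DataFrame(rows), states=tuple(states))
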