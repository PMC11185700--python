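"""Delimited-table I/O, run configuration, and the end-to-end pipeline.

All pipeline inputs and outputs are plain delimited text (comma or tab,
sniffed against the expected header) so that synthetic and real peak
tables are interchangeable.  A RunConfig (YAML) declares which stages to
run; ``run_pipeline`` executes simulate -> fit -> landscape and writes
JSON results plus a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cest, cpmg, landscape as landscape_mod, realtime, synthetic

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "timecourses_to_frame",
    "frame_to_timecourses",
    "cest_profiles_to_frame",
    "frame_to_cest_profiles",
    "cpmg_profiles_to_frame",
    "frame_to_cpmg_profiles",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "realtime": ["peak_id", "state", "time_hr", "intensity", "sigma"],
    "cest": ["residue", "offset_ppm", "intensity_ratio", "sigma"],
    "cpmg": ["residue", "nu_hz", "r2eff", "sigma"],
    "volumes": ["residue", "state", "temperature_c", "volume"],
}

_NUMERIC = {
    "time_hr", "intensity", "sigma", "offset_ppm", "intensity_ratio",
    "nu_hz", "r2eff", "temperature_c", "volume",
}


def _sniff_delimiter(header_line: str, columns: Sequence[str]) -> str:
    """Pick comma or tab by which one reproduces the expected header."""
    for delim, name in ((",", "comma"), ("\t", "tab")):
        fields = [f.strip() for f in header_line.rstrip("\n").split(delim)]
        if set(columns) <= set(fields):
            logger.info("table dialect: %s-delimited (header match)", name)
            return delim
    raise ValueError(
        f"header {header_line.strip()!r} does not contain the required "
        f"columns {list(columns)} with either comma or tab delimiters"
    )


def read_table(path: str | Path, schema: str | Sequence[str]) -> pd.DataFrame:
    """Read and validate a delimited table against a schema.

    ``schema`` is a schema name from :data:`SCHEMAS` or an explicit column
    list.  Errors name the offending column and 1-based data row.
    """
    columns = SCHEMAS[schema] if isinstance(schema, str) else list(schema)
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header, columns)
    df = pd.read_csv(path, sep=delim)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in columns:
        if col not in _NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at data row {row}"
            )
        df[col] = coerced
    key_cols = {
        "cest": ["residue", "offset_ppm"],
        "realtime": ["peak_id", "time_hr"],
    }
    if isinstance(schema, str) and schema in key_cols:
        keys = key_cols[schema]
        if schema == "cest" and "b1_hz" in df.columns:
            keys = keys + ["b1_hz"]
        dup = df.duplicated(subset=keys)
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise ValueError(
                f"{path}: duplicate {tuple(key_cols[schema])} key at data row {row}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


# -- converters between record frames and domain objects --------------------


def timecourses_to_frame(timecourses) -> pd.DataFrame:
    rows = []
    for tc in timecourses:
        for t, i in zip(tc.times_hr, tc.intensities):
            rows.append(
                {"peak_id": tc.peak_id, "state": tc.state, "time_hr": t,
                 "intensity": i, "sigma": tc.sigma}
            )
    return pd.DataFrame(rows)


def frame_to_timecourses(df: pd.DataFrame) -> list[realtime.TimeCourse]:
    out = []
    for (peak, state), g in df.groupby(["peak_id", "state"], sort=False):
        g = g.sort_values("time_hr")
        out.append(
            realtime.TimeCourse(
                peak_id=str(peak),
                state=str(state),
                times_hr=g["time_hr"].to_numpy(),
                intensities=g["intensity"].to_numpy(),
                sigma=float(g["sigma"].iloc[0]),
            )
        )
    return out


def cest_profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for o, i, s in zip(p.offsets_ppm, p.intensity, p.sigma):
            rows.append(
                {"residue": p.residue, "offset_ppm": o, "intensity_ratio": i,
                 "sigma": s, "b1_hz": p.b1_hz, "trelax_s": p.trelax_s}
            )
    return pd.DataFrame(rows)


def frame_to_cest_profiles(
    df: pd.DataFrame,
    b1_hz: float | None,
    trelax_s: float | None,
    larmor_mhz: float,
    observed_state: str = "Ground",
) -> list[cest.CESTProfile]:
    """Reassemble profiles; per-row b1_hz/trelax_s columns take precedence
    over the scalars (needed for multi-field acquisitions)."""
    out = []
    keys = ["residue"] + [c for c in ("b1_hz", "trelax_s") if c in df.columns]
    for key, g in df.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        g = g.sort_values("offset_ppm")
        out.append(
            cest.CESTProfile(
                residue=str(key[0]),
                b1_hz=float(key[1]) if "b1_hz" in df.columns else b1_hz,
                trelax_s=float(g["trelax_s"].iloc[0])
                if "trelax_s" in df.columns
                else trelax_s,
                offsets_ppm=g["offset_ppm"].to_numpy(),
                intensity=g["intensity_ratio"].to_numpy(),
                sigma=g["sigma"].to_numpy(),
                larmor_mhz=larmor_mhz,
                observed_state=observed_state,
            )
        )
    return out


def cpmg_profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for nu, r2, s in zip(p.nu_hz, p.r2eff, p.sigma):
            rows.append(
                {"residue": p.residue, "nu_hz": nu, "r2eff": r2, "sigma": s,
                 "temperature_c": p.temperature_c}
            )
    return pd.DataFrame(rows)


def frame_to_cpmg_profiles(df: pd.DataFrame, tct_s: float) -> list[cpmg.CPMGProfile]:
    out = []
    for res, g in df.groupby("residue", sort=False):
        temp = g["temperature_c"].iloc[0] if "temperature_c" in g else None
        out.append(
            cpmg.CPMGProfile(
                residue=str(res),
                nu_hz=g["nu_hz"].to_numpy(),
                r2eff=g["r2eff"].to_numpy(),
                sigma=g["sigma"].to_numpy(),
                tct_s=tct_s,
                temperature_c=None if pd.isna(temp) else float(temp),
            )
        )
    return out


# -- run configuration and pipeline -----------------------------------------


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML on disk).

    ``stages`` maps stage names (simulate, fit_realtime, fit_cest,
    analyze_cpmg, landscape) to their option dicts.  A single ``seed``
    feeds every stochastic stage through named substreams.
    """

    stages: dict[str, dict]
    seed: int
    output_dir: Path
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "stages" not in raw:
            raise ValueError(f"{path}: config must define a 'stages' mapping")
        if not raw["stages"]:
            raise ValueError(f"{path}: no stages enabled")
        if "seed" not in raw:
            raise ValueError(f"{path}: a seed is mandatory")
        for key in ("input", "path"):
            for stage_opts in raw["stages"].values():
                p = (stage_opts or {}).get(key)
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"{path}: referenced path {p} not found")
        return cls(
            stages={k: dict(v or {}) for k, v in raw["stages"].items()},
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "results")),
            schema_version=int(raw.get("schema_version", 1)),
        )


def _substream(seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from the config seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write JSON results + provenance.

    Stage order: simulate -> fit_realtime -> fit_cest -> analyze_cpmg ->
    landscape.  Each stage's outputs land under ``config.output_dir``;
    failures abort with the stage name while earlier outputs persist.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"schema_version": config.schema_version, "seed": config.seed}
    provenance: dict = {"stages": {}, "seed": config.seed}
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            opts = config.stages[stage]
            scenario = opts.get("scenario", "tjump_20C")
            fixture = synthetic.kaib_fixture(scenario)
            sub = _substream(config.seed, stage)
            kind = fixture.acquisition.kind if fixture.acquisition else "volumes"
            if kind == "realtime":
                tcs = synthetic.gen_tjump(
                    fixture,
                    opts.get("n_ground_peaks", 45),
                    opts.get("n_fs_peaks", 37),
                    noise_frac=opts.get("noise_frac", fixture.noise),
                    seed=sub,
                )
                write_table(timecourses_to_frame(tcs), out_dir / "simulated_realtime.csv")
            elif kind == "cest":
                profiles = synthetic.gen_cest(
                    fixture, noise_abs=opts.get("noise_abs", fixture.noise), seed=sub
                )
                write_table(cest_profiles_to_frame(profiles), out_dir / "simulated_cest.csv")
            elif kind == "cpmg":
                profiles = synthetic.gen_cpmg(
                    fixture, noise_abs=opts.get("noise_abs", fixture.noise), seed=sub
                )
                write_table(cpmg_profiles_to_frame(profiles), out_dir / "simulated_cpmg.csv")
            else:
                table = synthetic.gen_volume_table(
                    fixture, noise_frac=opts.get("noise_frac", fixture.noise), seed=sub
                )
                write_table(table.data, out_dir / "simulated_volumes.csv")
            results[stage] = {"scenario": scenario, "kind": kind}
            provenance["stages"][stage] = {"seed": sub, "options": opts}

        if "fit_realtime" in config.stages:
            stage = "fit_realtime"
            opts = config.stages[stage]
            path = opts.get("input", out_dir / "simulated_realtime.csv")
            df = read_table(path, "realtime")
            tcs = frame_to_timecourses(df)
            if opts.get("filter", True):
                tcs = realtime.filter_peaks(
                    tcs, opts.get("amplitude_threshold", realtime.AMPLITUDE_THRESHOLD)
                )
            fit = realtime.fit_global_rates(tcs)
            boot = realtime.bootstrap_rates(
                tcs,
                n_iterations=opts.get("bootstrap_n", 200),
                seed=_substream(config.seed, stage),
            )
            results[stage] = {
                "k_forward_hr": fit.k_forward,
                "k_reverse_hr": fit.k_reverse,
                "p0": fit.p0,
                "redchi2": fit.redchi2,
                "n_ground": fit.n_ground,
                "n_fs": fit.n_fs,
                "se_k_forward": boot.se_k_forward,
                "se_k_reverse": boot.se_k_reverse,
                "lifetime_forward_hr": realtime.lifetime(fit.k_forward),
                "lifetime_reverse_hr": realtime.lifetime(fit.k_reverse),
                "equilibrium_ground": fit.equilibrium_ground,
            }
            provenance["stages"][stage] = {
                "input": str(path), "sha256": _file_hash(path),
            }

        if "fit_cest" in config.stages:
            stage = "fit_cest"
            opts = config.stages[stage]
            path = opts.get("input", out_dir / "simulated_cest.csv")
            df = read_table(path, "cest")
            scenario = opts.get("scenario", "methyl_cest_20C")
            fixture = synthetic.kaib_fixture(scenario)
            acq = fixture.acquisition
            b1_fb, tr_fb = acq.cest_fields()[0]
            profiles = frame_to_cest_profiles(df, b1_fb, tr_fb, acq.larmor_mhz)
            constraints = opts.get("constraints")
            fit = cest.fit_cest_global(
                profiles, fixture.model, constraints=constraints,
                n_starts=opts.get("n_starts", 1),
            )
            results[stage] = {
                "topology": fit.topology,
                "populations": fit.populations,
                "kex": {f"{a}-{b}": v for (a, b), v in fit.kex.items()},
                "rates": {f"{a}->{b}": v for (a, b), v in fit.rates.items()},
                "redchi2": fit.redchi2,
            }
            provenance["stages"][stage] = {
                "input": str(path), "sha256": _file_hash(path),
            }

        if "analyze_cpmg" in config.stages:
            stage = "analyze_cpmg"
            opts = config.stages[stage]
            path = opts.get("input", out_dir / "simulated_cpmg.csv")
            df = read_table(path, "cpmg")
            profiles = frame_to_cpmg_profiles(df, opts.get("tct_s", 0.060))
            rex = {p.residue: cpmg.estimate_rex(p) for p in profiles}
            results[stage] = {
                "rex": {r: {"value": v, "sigma": s} for r, (v, s) in rex.items()}
            }
            provenance["stages"][stage] = {
                "input": str(path), "sha256": _file_hash(path),
            }

        if "landscape" in config.stages:
            stage = "landscape"
            opts = config.stages[stage]
            pops = {
                float(t): dict(p) for t, p in opts.get("populations", {}).items()
            }
            rates = {
                float(t): {tuple(k.split("->")): v for k, v in r.items()}
                for t, r in opts.get("rates", {}).items()
            }
            scapes = landscape_mod.assemble_landscape(
                pops, rates,
                cold_offset_kcal=opts.get("cold_offset_kcal", 2.0),
            )
            results[stage] = {
                str(t): {
                    "temperature_k": ls.temperature_k,
                    "state_dg_kcal": ls.state_dg,
                    "barriers_kcal": {f"{a}->{b}": v for (a, b), v in ls.barriers.items()},
                    "offset_applied": ls.offset_applied,
                }
                for t, ls in scapes.items()
            }
            provenance["stages"][stage] = {"options": opts}
    except Exception as err:
        (out_dir / "results.json").write_text(json.dumps(results, indent=2, default=float))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out_dir / "results.json").write_text(json.dumps(results, indent=2, default=float))
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str)
    )
    return results


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
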