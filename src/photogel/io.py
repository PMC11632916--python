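"""Format readers/writers shared by all stages.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row.
Sweep CSVs carry ``time_s,g_prime_pa,g_double_prime_pa`` with the light
schedule in a YAML sidecar (``<file>.yaml``) or passed explicitly.  Reports
are versioned JSON including config and seed so identical inputs produce
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import TimeSweep, TranswellAssay

SWEEP_COLUMNS = ["time_s", "g_prime_pa", "g_double_prime_pa"]
READINGS_COLUMNS = ["time_h", "rfu"]


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".yaml")
    if side.exists():
        with open(side) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def read_sweep_csv(path, light_on: float | None = None,
                   light_off: float | None = None) -> TimeSweep:
    """Read one replicate's time sweep; light schedule from arguments or a
    ``<file>.csv.yaml`` sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in SWEEP_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    meta = _sidecar(path)
    light_on = light_on if light_on is not None else meta.get("light_on")
    light_off = light_off if light_off is not None else meta.get("light_off")
    if light_on is None or light_off is None:
        raise ValueError(f"{path.name}: light_on/light_off not given and no sidecar found")
    return TimeSweep(
        t=df["time_s"].to_numpy(float),
        g_prime=df["g_prime_pa"].to_numpy(float),
        g_double_prime=df["g_double_prime_pa"].to_numpy(float),
        light_on=float(light_on), light_off=float(light_off),
        replicate_id=path.stem,
    )


def write_sweep_csv(sweep: TimeSweep, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": sweep.t,
        "g_prime_pa": sweep.g_prime,
        "g_double_prime_pa": sweep.g_double_prime,
    }).to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump({"light_on": float(sweep.light_on),
                        "light_off": float(sweep.light_off),
                        "replicate_id": sweep.replicate_id}, fh)
    return path


def read_readings_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in READINGS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    if not df["time_h"].is_monotonic_increasing:
        raise ValueError(f"{path.name}: time_h must be increasing")
    return df


def assay_from_files(readings_path, config: dict) -> TranswellAssay:
    """Build an assay from a readings CSV plus a geometry/standard config.

    ``config`` keys: area, v_acceptor, c_donor0, dilution, standard_csv
    (path to a ``concentration_mg_ml,rfu`` table).
    """
    df = read_readings_csv(readings_path)
    std = pd.read_csv(config["standard_csv"])
    return TranswellAssay(
        times=df["time_h"].to_numpy(float),
        readings=df["rfu"].to_numpy(float),
        dilution=float(config.get("dilution", 25.0)),
        area=float(config["area"]),
        v_acceptor=float(config["v_acceptor"]),
        c_donor0=float(config["c_donor0"]),
        standard_concentrations=std["concentration_mg_ml"].to_numpy(float),
        standard_readings=std["rfu"].to_numpy(float),
        group_label=Path(readings_path).stem,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results, path, config: dict | None = None,
                 seed: int | None = None) -> Path:
    """Versioned JSON report; stable key order so identical inputs give
    byte-identical files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema": "photogel-report/1",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
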