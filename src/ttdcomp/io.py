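"""Readers, writers, dataset summaries and run configuration.

Detection tables are long-format CSV with a required header
``station_id,species_id,time_days,censored[,cause]`` — one row per
station x species.  Mass tables are ``resource_id,time_days,wet_mass_g``.
Parsing is strict: malformed rows abort with row-numbered messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DetectionRecord, TTDDataset
from .decay import MassRecord

__all__ = [
    "read_detections",
    "write_detections",
    "read_masses",
    "write_masses",
    "summarize_dataset",
    "format_summary",
    "RunConfig",
]

_DETECTION_COLS = ["station_id", "species_id", "time_days", "censored"]
_MASS_COLS = ["resource_id", "time_days", "wet_mass_g"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_detections(path, allow_ties: bool = False) -> TTDDataset:
    """Load and validate a long-format detection CSV.

    Enforces positive finite times, binary censoring flags, one record per
    (station, species) pair and the one-winner-per-station invariant; row
    numbers in error messages count the header as row 1.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "species_id": str},
                     float_precision="round_trip")
    _require_columns(df, _DETECTION_COLS, path)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        censored = getattr(row, "censored")
        if censored not in (0, 1, "0", "1"):
            raise ValueError(
                f"{path}:row {pos}: censored must be 0 or 1, got {censored!r}"
            )
        time = getattr(row, "time_days")
        try:
            time = float(time)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:row {pos}: time_days must be numeric, got {time!r}"
            ) from None
        if not np.isfinite(time) or time <= 0:
            raise ValueError(
                f"{path}:row {pos}: time_days must be finite and > 0, got {time}"
            )
        cause = getattr(row, "cause", None)
        if cause is not None and (pd.isna(cause) or cause == ""):
            cause = None
        records.append(
            DetectionRecord(
                station_id=str(getattr(row, "station_id")),
                species_id=str(getattr(row, "species_id")),
                time=time,
                censored=int(censored),
                cause=cause,
            )
        )
    return TTDDataset(records, allow_ties=allow_ties)


def write_detections(dataset: TTDDataset, path) -> None:
    """Write a dataset back to the long-format CSV (round-trips exactly)."""
    rows = [
        {
            "station_id": r.station_id,
            "species_id": r.species_id,
            # repr keeps every bit of the double so read-back is exact
            "time_days": repr(r.time),
            "censored": r.censored,
            "cause": r.cause if r.cause is not None else "",
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_masses(path) -> list[MassRecord]:
    """Load a wet-mass monitoring CSV into mass records."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"resource_id": str},
                     float_precision="round_trip")
    _require_columns(df, _MASS_COLS, path)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MassRecord(
                    resource_id=str(row.resource_id),
                    time=float(row.time_days),
                    value=float(row.wet_mass_g),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:row {pos}: {exc}") from None
    if not records:
        raise ValueError(f"{path}: no mass records")
    return records


def write_masses(records: Iterable[MassRecord], path) -> None:
    pd.DataFrame(
        [
            {"resource_id": r.resource_id, "time_days": repr(r.time),
             "wet_mass_g": repr(r.value)}
            for r in records
        ]
    ).to_csv(path, index=False)


def summarize_dataset(dataset: TTDDataset) -> pd.DataFrame:
    """Per-species detection summary over K monitored stations.

    Columns: number of first detections, that count as a percentage of all K
    stations (one decimal place), and the number of censored records.  The
    table's ``attrs`` carry K and the count/percentage of stations where no
    species was detected.
    """
    k = dataset.n_stations
    rows = []
    for s in dataset.species:
        recs = dataset.records_for(s)
        n_first = sum(1 for r in recs if r.censored == 0)
        rows.append(
            {
                "species_id": s,
                "n_first_detections": n_first,
                "pct_stations": round(100.0 * n_first / k, 1),
                "n_censored": len(recs) - n_first,
            }
        )
    df = pd.DataFrame(rows).set_index("species_id")
    n_detected = int(df["n_first_detections"].sum())
    df.attrs["n_stations"] = k
    df.attrs["n_no_detection"] = k - n_detected
    df.attrs["pct_no_detection"] = round(100.0 * (k - n_detected) / k, 1)
    return df


def format_summary(dataset: TTDDataset) -> str:
    """Plain-text version of the detection summary."""
    df = summarize_dataset(dataset)
    lines = [f"K = {df.attrs['n_stations']} monitored stations"]
    for s, row in df.iterrows():
        lines.append(
            f"  {s}: first detection at {int(row.n_first_detections)} stations "
            f"({row.pct_stations}%), censored at {int(row.n_censored)}"
        )
    lines.append(
        f"  no detection: {df.attrs['n_no_detection']} stations "
        f"({df.attrs['pct_no_detection']}%)"
    )
    return "\n".join(lines)


def _parse_v(v) -> float:
    if isinstance(v, str) and v.strip().lower() in ("inf", "infinity"):
        return float("inf")
    v = float(v)
    if v <= 0:
        raise ValueError(f"v must be positive or 'inf', got {v}")
    return v


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, loadable from a YAML file.

    Minimal example::

        detections: detections.csv
        masses: masses.csv          # optional
        output_dir: out
        family: [exponential, lognormal]   # a list triggers WAIC comparison
        v: inf
        mcmc: {chains: 5, iterations: 5000, warmup: 2000, seed: 1}
        metrics:
          pairs: [[fox, raccoon_dog], [raccoon_dog, fox]]
          names: [cii, pfc, ufc, redundancy, allocation]
          nsim: 10000
    """

    detections: str
    output_dir: str
    family: str | list[str] = "exponential"
    masses: str | None = None
    v: float = float("inf")
    priors: dict = field(default_factory=dict)
    chains: int = 5
    iterations: int = 5000
    warmup: int = 2000
    seed: int = 0
    metric_pairs: list[tuple[str, str]] = field(default_factory=list)
    metric_names: list[str] = field(default_factory=lambda: ["cii", "pfc", "ufc"])
    nsim: int = 10000
    allow_nonconverged: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        mcmc = raw.get("mcmc", {})
        metrics = raw.get("metrics", {})
        cfg = cls(
            detections=str(raw["detections"]),
            output_dir=str(raw.get("output_dir", "ttdcomp_out")),
            family=raw.get("family", "exponential"),
            masses=str(raw["masses"]) if raw.get("masses") else None,
            v=_parse_v(raw.get("v", "inf")),
            priors=raw.get("priors", {}) or {},
            chains=int(mcmc.get("chains", 5)),
            iterations=int(mcmc.get("iterations", 5000)),
            warmup=int(mcmc.get("warmup", 2000)),
            seed=int(mcmc.get("seed", 0)),
            metric_pairs=[tuple(p) for p in metrics.get("pairs", [])],
            metric_names=list(metrics.get("names", ["cii", "pfc", "ufc"])),
            nsim=int(metrics.get("nsim", 10000)),
            allow_nonconverged=bool(raw.get("allow_nonconverged", False)),
        )
        base = path.parent
        cfg.detections = str((base / cfg.detections).resolve())
        if cfg.masses:
            cfg.masses = str((base / cfg.masses).resolve())
        if not Path(cfg.detections).exists():
            raise FileNotFoundError(f"detections file not found: {cfg.detections}")
        if cfg.masses and not Path(cfg.masses).exists():
            raise FileNotFoundError(f"masses file not found: {cfg.masses}")
        if cfg.warmup >= cfg.iterations:
            raise ValueError("mcmc.warmup must be smaller than mcmc.iterations")
        return cfg
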