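"""Synthetic data generators and Monte-Carlo oracles.

Generates camera-trap TTD datasets from the model's own generative process
(independent per-species occupancy, latent first-detection times, competitive
censoring by the earliest visitor, optional camera-failure clock and survey
end) and decaying wet-mass series with gamma noise.  Also provides
event-counting Monte-Carlo estimates of the competition/redundancy/allocation
metrics, implemented with arithmetic independent of the quadrature code path,
so the two can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DetectionRecord, SpeciesModel, TTDDataset
from .decay import GompertzDecay, MassRecord, gompertz_mean
from .metrics import AnalysisWindow

__all__ = [
    "SimulationScenario",
    "simulate_ttd",
    "OracleEstimate",
    "mc_metric_oracle",
    "simulate_decay",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Study design for a synthetic camera-trap survey.

    ``camera_failure_rate`` is the per-day hazard of an independent
    exponential failure clock (0 = cameras never fail); monitoring at a
    station ends at min(failure time, survey length) unless a species
    detects the resource first.
    """

    n_stations: int
    species_models: Mapping[str, SpeciesModel]
    survey_length: float = np.inf
    camera_failure_rate: float = 0.0
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    seed: int = 0

    def __post_init__(self):
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if not self.survey_length > 0:
            raise ValueError("survey_length must be > 0")
        if self.camera_failure_rate < 0:
            raise ValueError("camera_failure_rate must be >= 0")
        if not self.species_models:
            raise ValueError("at least one species model is required")


def simulate_ttd(scenario: SimulationScenario) -> tuple[TTDDataset, pd.DataFrame]:
    """Simulate one survey; returns the dataset and the latent truth table.

    Per station each species is occupied with its psi independently; occupied
    species draw latent first-detection times from their distributions.  The
    earliest occupied species' time, if it beats camera failure and survey
    end, is recorded uncensored; every other species is censored at that same
    moment.  The truth table carries the latent occupancy and times.
    """
    rng = np.random.default_rng(int(scenario.seed))
    species = list(scenario.species_models)
    n_sp = len(species)
    k = scenario.n_stations
    width = max(3, len(str(k)))
    stations = [f"st{i:0{width}d}" for i in range(1, k + 1)]

    z = np.empty((k, n_sp), dtype=bool)
    t_latent = np.full((k, n_sp), np.inf)
    for j, s in enumerate(species):
        model = scenario.species_models[s]
        z[:, j] = rng.random(k) < model.psi
        n_occ = int(z[:, j].sum())
        if n_occ:
            t_latent[z[:, j], j] = model.ttd.rvs(n_occ, rng)

    if scenario.camera_failure_rate > 0:
        t_fail = rng.exponential(1.0 / scenario.camera_failure_rate, size=k)
    else:
        t_fail = np.full(k, np.inf)
    t_end = np.minimum(t_fail, scenario.survey_length)

    t_first = t_latent.min(axis=1)
    winner = t_latent.argmin(axis=1)
    detected = np.isfinite(t_first) & (t_first <= t_end)

    records = []
    truth_rows = []
    for i in range(k):
        if detected[i]:
            obs_time, win = float(t_first[i]), int(winner[i])
        else:
            if not np.isfinite(t_end[i]):
                raise ValueError(
                    f"station {stations[i]} was never visited and the survey "
                    "never ends; set a finite survey_length or failure rate"
                )
            obs_time, win = float(t_end[i]), -1
        end_cause = "camera_failure" if t_fail[i] < scenario.survey_length else "survey_end"
        for j, s in enumerate(species):
            if j == win:
                records.append(
                    DetectionRecord(stations[i], s, obs_time, 0, cause=None)
                )
            else:
                cause = "rival_detection" if win >= 0 else end_cause
                records.append(
                    DetectionRecord(stations[i], s, obs_time, 1, cause=cause)
                )
            truth_rows.append(
                {
                    "station_id": stations[i],
                    "species_id": s,
                    "occupied": bool(z[i, j]),
                    "latent_time": float(t_latent[i, j]),
                    "observed_time": obs_time,
                    "censored": int(j != win),
                }
            )
    return TTDDataset(records), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class OracleEstimate:
    value: float
    se: float


def mc_metric_oracle(
    models: Mapping[str, SpeciesModel],
    window=AnalysisWindow(),
    decay: GompertzDecay | None = None,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> dict[str, OracleEstimate]:
    """Brute-force event-counting estimates of the pairwise metrics.

    The first species in ``models`` is the focal A, the second the rival B
    (any further species join the ``cii_all_rivals`` extension: the
    probability that *some* rival, occupied, beats A within the window).
    Returns estimates with Monte-Carlo standard errors; e.g. the competition
    index is the mean of 1[B occupied] * 1[T_B < T_A <= v].
    """
    if len(models) < 2:
        raise ValueError("oracle needs a focal and at least one rival species")
    if n_draws < 1000:
        raise ValueError("use at least 1000 draws")
    window = AnalysisWindow(window) if not isinstance(window, AnalysisWindow) else window
    rng = np.random.default_rng(int(seed))
    names = list(models)
    z = {}
    t = {}
    for s in names:
        m = models[s]
        z[s] = rng.random(n_draws) < m.psi
        t[s] = m.ttd.rvs(n_draws, rng)

    a, b = names[0], names[1]
    in_window_a = t[a] <= window.v
    ind_a = z[a] & in_window_a
    ind_b = z[b] & (t[b] <= window.v)
    beaten = z[b] & (t[b] < t[a])

    def est(x) -> OracleEstimate:
        x = np.asarray(x, dtype=float)
        return OracleEstimate(
            float(x.mean()), float(x.std(ddof=1) / np.sqrt(n_draws))
        )

    out = {
        "cii": est(beaten & in_window_a),
        "pfc": est(ind_a),
        "ufc": est(ind_a & ~ind_b),
        "redundancy": est(ind_a & ind_b),
    }
    any_rival = np.zeros(n_draws, dtype=bool)
    for s in names[1:]:
        any_rival |= z[s] & (t[s] < t[a])
    out["cii_all_rivals"] = est(any_rival & in_window_a)
    if decay is not None:
        vals = np.where(
            ind_a & ~beaten, gompertz_mean(t[a], decay), 0.0
        )
        out["allocation"] = est(vals)
    return out


def simulate_decay(
    n_resources: int,
    params: GompertzDecay,
    schedule: Sequence[float],
    seed: int = 0,
    initial_mass_mean: float = 5000.0,
    initial_mass_cv: float = 0.2,
) -> list[MassRecord]:
    """Simulate wet-mass monitoring series for ``n_resources`` resource units.

    Each unit gets a lognormal initial mass (grams), recorded exactly at day
    0 (the placement weighing that later proportions are normalized by); at
    every later scheduled day the observed mass is the initial mass times a
    Gamma(d, d/g(t)) proportion, so the expected proportion is exactly g(t).
    """
    schedule = sorted(float(x) for x in schedule)
    if not schedule:
        raise ValueError("schedule must be nonempty")
    if schedule[0] != 0.0:
        raise ValueError("schedule must include day 0 (the baseline measurement)")
    if n_resources < 1:
        raise ValueError("n_resources must be >= 1")
    rng = np.random.default_rng(int(seed))
    sigma = np.sqrt(np.log1p(initial_mass_cv**2))
    mu = np.log(initial_mass_mean) - sigma**2 / 2.0
    records = []
    width = max(2, len(str(n_resources)))
    for i in range(1, n_resources + 1):
        rid = f"carcass{i:0{width}d}"
        m0 = float(rng.lognormal(mu, sigma))
        for day in schedule:
            if day == 0.0:
                records.append(MassRecord(rid, day, m0))
                continue
            g = gompertz_mean(day, params)
            prop = rng.gamma(shape=params.dispersion, scale=g / params.dispersion)
            records.append(MassRecord(rid, day, m0 * prop))
    return records
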