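"""Domain types and censored likelihoods for time-to-detection (TTD) occupancy models.

A monitoring station is a fresh, ephemeral resource (an artificial nest, a
carcass) placed in front of a camera trap.  For each focal species the record
at a station is either the elapsed time to the species' first detection of the
resource (uncensored) or the time at which observation of that species ended
without a detection (censored: a rival consumed the resource first, the camera
failed, or the survey ended).  The likelihood mixes occupancy -- the species
may simply be absent -- with a parametric first-detection time distribution:

    L_k = [psi * f(t_k)]^(1-c_k) * [1 - psi + psi * S(t_k)]^(c_k)

where ``psi`` is the occupancy probability, ``f`` the detection-time density,
``S = 1 - F`` its survival function and ``c_k`` the censoring indicator.
Species factors multiply under the assumption that detection of the resource
is independent across species; a rival's use enters only through censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import scipy.stats as st

__all__ = [
    "FAMILIES",
    "TimeDistribution",
    "DetectionRecord",
    "TTDDataset",
    "SpeciesModel",
    "density_cdf_survival",
    "hazard",
    "species_station_loglik",
    "joint_loglik",
]


# family name -> (ordered parameter names, scipy.stats distribution, arg mapper)
# The arg mapper turns our natural parameters into scipy's (shape..., scale).
def _expon_args(rate: float) -> tuple:
    return ((), 1.0 / rate)


def _gamma_args(shape: float, rate: float) -> tuple:
    return ((shape,), 1.0 / rate)


def _lognorm_args(mu, sigma) -> tuple:
    # array-friendly: also used vectorized over posterior draws
    return ((sigma,), np.exp(mu))


def _weibull_args(shape: float, scale: float) -> tuple:
    return ((shape,), scale)


FAMILIES: dict[str, tuple[tuple[str, ...], st.rv_continuous, Callable]] = {
    "exponential": (("rate",), st.expon, _expon_args),
    "gamma": (("shape", "rate"), st.gamma, _gamma_args),
    "lognormal": (("mu", "sigma"), st.lognorm, _lognorm_args),
    "weibull": (("shape", "scale"), st.weibull_min, _weibull_args),
}


@dataclass(frozen=True)
class TimeDistribution:
    """Parametric first-detection time distribution on (0, inf).

    Parameters are the field-standard ones: ``exponential`` by rate (per day),
    ``gamma`` by shape and rate, ``lognormal`` by (mu, sigma) of log-days,
    ``weibull`` by shape and scale (days).
    """

    family: str
    params: tuple[float, ...]

    def __init__(self, family: str, *params: float, **named: float):
        if family not in FAMILIES:
            raise ValueError(
                f"unknown family {family!r}; choose from {sorted(FAMILIES)}"
            )
        names = FAMILIES[family][0]
        if named:
            if params:
                raise ValueError("pass parameters positionally or by name, not both")
            try:
                params = tuple(float(named.pop(n)) for n in names)
            except KeyError as exc:
                raise ValueError(f"{family} requires parameters {names}") from exc
            if named:
                raise ValueError(f"unexpected parameters {sorted(named)} for {family}")
        params = tuple(float(p) for p in params)
        if len(params) != len(names):
            raise ValueError(f"{family} requires parameters {names}, got {params}")
        for name, value in zip(names, params):
            if not np.isfinite(value):
                raise ValueError(f"{family} parameter {name} must be finite")
            if name != "mu" and value <= 0:
                raise ValueError(f"{family} parameter {name} must be > 0, got {value}")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "params", params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return FAMILIES[self.family][0]

    def _dist_args(self) -> tuple[st.rv_continuous, tuple, float]:
        _, dist, mapper = FAMILIES[self.family]
        shapes, scale = mapper(*self.params)
        return dist, shapes, scale

    def pdf(self, t):
        t = _check_nonneg_time(t)
        dist, shapes, scale = self._dist_args()
        return dist.pdf(t, *shapes, scale=scale)

    def logpdf(self, t):
        t = _check_nonneg_time(t)
        dist, shapes, scale = self._dist_args()
        return dist.logpdf(t, *shapes, scale=scale)

    def cdf(self, t):
        t = _check_nonneg_time(t)
        dist, shapes, scale = self._dist_args()
        return dist.cdf(t, *shapes, scale=scale)

    def sf(self, t):
        t = _check_nonneg_time(t)
        dist, shapes, scale = self._dist_args()
        return dist.sf(t, *shapes, scale=scale)

    def logsf(self, t):
        t = _check_nonneg_time(t)
        dist, shapes, scale = self._dist_args()
        return dist.logsf(t, *shapes, scale=scale)

    def hazard(self, t):
        """Instantaneous detection rate f(t)/S(t), computed on the log scale.

        Stable far into the right tail, where both f and S underflow.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("hazard requires t > 0")
        out = np.exp(self.logpdf(t) - self.logsf(t))
        return out if out.shape else float(out)

    def ppf(self, q):
        dist, shapes, scale = self._dist_args()
        return dist.ppf(q, *shapes, scale=scale)

    def mean(self) -> float:
        dist, shapes, scale = self._dist_args()
        return float(dist.mean(*shapes, scale=scale))

    def rvs(self, size, rng: np.random.Generator):
        dist, shapes, scale = self._dist_args()
        return dist.rvs(*shapes, scale=scale, size=size, random_state=rng)

    def __repr__(self) -> str:  # TimeDistribution('weibull', shape=1.2, scale=3)
        kv = ", ".join(f"{n}={p:g}" for n, p in zip(self.param_names, self.params))
        return f"TimeDistribution({self.family!r}, {kv})"


def _check_nonneg_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t if t.shape else float(t)


def density_cdf_survival(dist: TimeDistribution, t):
    """Return ``(f(t), F(t), S(t))`` for a detection-time distribution.

    Vectorizes over ``t``; ``S = 1 - F`` is the probability that the first
    detection has not yet occurred by ``t``.
    """
    return dist.pdf(t), dist.cdf(t), dist.sf(t)


def hazard(dist: TimeDistribution, t):
    """Instantaneous detection rate f(t)/S(t); constant for the exponential."""
    return dist.hazard(t)


@dataclass(frozen=True)
class DetectionRecord:
    """One station x species observation.

    ``censored = 0`` means the species' first detection was observed at
    ``time`` (days); ``censored = 1`` means observation of this species ended
    at ``time`` without a detection (rival used the resource, camera failed,
    or monitoring ended).  ``cause`` is optional reporting metadata and never
    enters the likelihood.
    """

    station_id: str
    species_id: str
    time: float
    censored: int
    cause: str | None = None

    def __post_init__(self):
        t = float(self.time)
        if not np.isfinite(t) or t <= 0:
            raise ValueError(
                f"record ({self.station_id}, {self.species_id}): "
                f"time must be finite and > 0, got {self.time!r}"
            )
        object.__setattr__(self, "time", t)
        if self.censored not in (0, 1):
            raise ValueError(
                f"record ({self.station_id}, {self.species_id}): "
                f"censored must be 0 or 1, got {self.censored!r}"
            )
        object.__setattr__(self, "censored", int(self.censored))


class TTDDataset:
    """Validated collection of detection records.

    Holds exactly one record per (station, species) pair and enforces the
    competitive-censoring structure: at most one species per station can be
    uncensored, because the first use of an ephemeral resource censors every
    rival at that moment.
    """

    def __init__(self, records: Iterable[DetectionRecord], allow_ties: bool = False):
        records = tuple(records)
        if not records:
            raise ValueError("dataset must contain at least one record")
        seen: set[tuple[str, str]] = set()
        winners: dict[str, str] = {}
        for rec in records:
            key = (rec.station_id, rec.species_id)
            if key in seen:
                raise ValueError(f"duplicate record for station/species {key}")
            seen.add(key)
            if rec.censored == 0:
                if rec.station_id in winners:
                    msg = (
                        f"station {rec.station_id!r} has more than one uncensored "
                        f"species ({winners[rec.station_id]!r} and "
                        f"{rec.species_id!r}); a first detection censors all rivals"
                    )
                    if not allow_ties:
                        raise ValueError(msg)
                    # simultaneous detection in one camera event: keep both as
                    # detected; the continuous-time model gives ties measure 0
                    warnings.warn(msg + " (kept as a simultaneous detection)",
                                  stacklevel=2)
                winners[rec.station_id] = rec.species_id
        self.records = records
        self.stations = tuple(dict.fromkeys(r.station_id for r in records))
        self.species = tuple(dict.fromkeys(r.species_id for r in records))
        by_station: dict[str, set[str]] = {s: set() for s in self.stations}
        for rec in records:
            by_station[rec.station_id].add(rec.species_id)
        full = set(self.species)
        for station, sp in by_station.items():
            if sp != full:
                missing = sorted(full - sp)
                raise ValueError(
                    f"station {station!r} is missing records for species {missing}; "
                    "each analyzed species needs one record per station"
                )

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def records_for(self, species_id: str) -> tuple[DetectionRecord, ...]:
        if species_id not in self.species:
            raise KeyError(f"unknown species {species_id!r}")
        return tuple(r for r in self.records if r.species_id == species_id)

    def times_by_censoring(self, species_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (uncensored times, censored times) arrays for one species."""
        recs = self.records_for(species_id)
        t_obs = np.array([r.time for r in recs if r.censored == 0], dtype=float)
        t_cen = np.array([r.time for r in recs if r.censored == 1], dtype=float)
        return t_obs, t_cen

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return (
            f"TTDDataset(K={self.n_stations} stations, "
            f"species={list(self.species)}, n={len(self.records)} records)"
        )


@dataclass(frozen=True)
class SpeciesModel:
    """Occupancy probability psi plus a detection-time distribution."""

    psi: float
    ttd: TimeDistribution

    def __post_init__(self):
        psi = float(self.psi)
        if not 0.0 <= psi <= 1.0:
            raise ValueError(f"psi must lie in [0, 1], got {psi}")
        object.__setattr__(self, "psi", psi)


def censored_mixture_logterm(psi, logsf):
    """log(1 - psi + psi * S(t)) from log S(t), computed stably.

    The censored-record likelihood is a two-part mixture: the station is
    unoccupied (1 - psi) or occupied but not yet visited (psi * S).  Exact
    zero (psi = 1 and S = 0) yields -inf, which is a legitimate likelihood.
    """
    psi = np.asarray(psi, dtype=float)
    logsf = np.asarray(logsf, dtype=float)
    with np.errstate(divide="ignore"):
        # log1p(-psi * (1 - S)) is exact for small psi*(1-S) and degrades
        # gracefully to -inf at the boundary.
        return np.log1p(-psi * -np.expm1(logsf))


def species_station_loglik(record: DetectionRecord, model: SpeciesModel) -> float:
    """Log-likelihood contribution of one record under one species' model."""
    if record.censored == 0:
        with np.errstate(divide="ignore"):
            return float(np.log(model.psi) + model.ttd.logpdf(record.time))
    return float(censored_mixture_logterm(model.psi, model.ttd.logsf(record.time)))


def joint_loglik(
    dataset: TTDDataset, models: Mapping[str, SpeciesModel]
) -> float:
    """Total log-likelihood of the dataset under per-species models.

    Species factorize (independent detection), so the joint log-likelihood is
    the sum of each species' single-species log-likelihood over its records;
    any number of competing species is supported.
    """
    missing = [s for s in dataset.species if s not in models]
    if missing:
        raise KeyError(f"no model supplied for species {missing}")
    total = 0.0
    for species in dataset.species:
        model = models[species]
        t_obs, t_cen = dataset.times_by_censoring(species)
        if t_obs.size:
            with np.errstate(divide="ignore"):
                total += t_obs.size * np.log(model.psi)
            total += float(np.sum(model.ttd.logpdf(t_obs)))
        if t_cen.size:
            total += float(
                np.sum(censored_mixture_logterm(model.psi, model.ttd.logsf(t_cen)))
            )
    return float(total)
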