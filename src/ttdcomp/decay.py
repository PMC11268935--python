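"""Gompertz decay of resource value with multiplicative gamma error.

Carcass wet mass (or any resource-value proxy) drops sigmoidally from its
initial value toward an equilibrium fraction as decomposition proceeds.  The
expected remaining proportion at time t (days) is the decreasing Gompertz

    g(t) = 1 - (1 - gamma) * exp(-exp(-beta * (t - alpha)))

with inflexion at ``alpha`` (days), slope parameter ``beta`` (per day) and
asymptote ``gamma`` in (0, 1).  Observed proportions y = mass(t)/mass(0) are
modeled as y ~ Gamma(shape = d, rate = d / g(t)) so that E[y] = g(t) and the
dispersion d controls the multiplicative measurement/biological noise.

The fitted curve is the g(t) that the resource-allocation integral and the
predictive remaining-mass histogram consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special as sp
import scipy.stats as st

from . import _mcmc
from .inference import PosteriorSamples

__all__ = [
    "MassRecord",
    "GompertzDecay",
    "gompertz_mean",
    "mass_proportions",
    "fit_decay",
    "decay_from_posterior",
    "DecayCurveSet",
    "hazard_overlay",
]

_PARAM_NAMES = ("alpha", "beta", "gamma", "dispersion")


@dataclass(frozen=True)
class MassRecord:
    """One wet-mass (or other value) measurement of one resource unit."""

    resource_id: str
    time: float
    value: float

    def __post_init__(self):
        t, v = float(self.time), float(self.value)
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"resource {self.resource_id!r}: time must be >= 0")
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"resource {self.resource_id!r}: value must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)


@dataclass(frozen=True)
class GompertzDecay:
    """Parameters of the decreasing Gompertz decay curve plus gamma dispersion."""

    alpha: float
    beta: float
    gamma_asymptote: float
    dispersion: float

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0.0 < self.gamma_asymptote < 1.0:
            raise ValueError("gamma_asymptote must lie in (0, 1)")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")

    def __call__(self, t):
        return gompertz_mean(t, self)


def gompertz_mean(t, params: GompertzDecay):
    """Expected remaining-value proportion g(t); decreases from 1 to gamma."""
    t = np.asarray(t, dtype=float)
    g = 1.0 - (1.0 - params.gamma_asymptote) * np.exp(
        -np.exp(-params.beta * (t - params.alpha))
    )
    return g if g.shape else float(g)


def mass_proportions(
    records: Iterable[MassRecord],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Normalize each resource's masses by its baseline (earliest) measurement.

    Returns (times, proportions, resource_id per row) for the non-baseline
    rows; baseline rows are identically 1 by construction and carry no
    information about the decay, so they are excluded from the likelihood.
    Resources whose earliest measurement is not at day 0 are dropped with a
    warning (no usable initial-value reference).
    """
    by_resource: dict[str, list[MassRecord]] = {}
    for rec in records:
        by_resource.setdefault(rec.resource_id, []).append(rec)
    times, props, ids = [], [], []
    for rid, recs in by_resource.items():
        recs = sorted(recs, key=lambda r: r.time)
        if recs[0].time > 0:
            warnings.warn(
                f"resource {rid!r} has no day-0 baseline measurement "
                f"(earliest at t={recs[0].time}); excluded",
                stacklevel=2,
            )
            continue
        baseline = recs[0].value
        if baseline <= 0:
            warnings.warn(
                f"resource {rid!r} has nonpositive baseline mass; excluded",
                stacklevel=2,
            )
            continue
        for rec in recs[1:]:
            times.append(rec.time)
            props.append(rec.value / baseline)
            ids.append(rid)
    if not times:
        raise ValueError("no usable mass records after normalization")
    return np.asarray(times), np.asarray(props), ids


# default priors: inflexion time ~ Normal(0, 50) days, slope ~ half-Normal(5)
# per day, asymptote ~ Uniform(0, 1), dispersion ~ half-Normal(100) (gamma
# shape of order 10-100 corresponds to 10-30% multiplicative noise)
def _default_decay_priors() -> dict[str, object]:
    return {
        "alpha": st.norm(0.0, 50.0),
        "beta": st.halfnorm(scale=5.0),
        "gamma": st.uniform(0.0, 1.0),
        "dispersion": st.halfnorm(scale=100.0),
    }


class _DecayModel:
    """Unconstrained posterior: (alpha, log beta, logit gamma, log dispersion)."""

    def __init__(self, t, y, priors: Mapping[str, object]):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.priors = priors
        if np.allclose(self.y, self.y[0]):
            warnings.warn(
                "all mass proportions are identical; the asymptote gamma is "
                "unidentified",
                stacklevel=3,
            )

    @staticmethod
    def to_natural(x: np.ndarray) -> tuple[float, float, float, float]:
        return (x[0], np.exp(x[1]), sp.expit(x[2]), np.exp(x[3]))

    def log_posterior(self, x: np.ndarray) -> float:
        alpha, beta, gam, disp = self.to_natural(x)
        lp = float(self.priors["alpha"].logpdf(alpha))
        lp += float(self.priors["beta"].logpdf(beta)) + x[1]
        lp += float(self.priors["gamma"].logpdf(gam)) + float(
            np.log(gam) + np.log1p(-gam)
        )
        lp += float(self.priors["dispersion"].logpdf(disp)) + x[3]
        if not np.isfinite(lp):
            return -np.inf
        lp += float(np.sum(self.pointwise(alpha, beta, gam, disp)))
        return lp if np.isfinite(lp) else -np.inf

    def pointwise(self, alpha, beta, gam, disp):
        g = 1.0 - (1.0 - gam) * np.exp(-np.exp(-beta * (self.t - alpha)))
        # y ~ Gamma(shape=disp, rate=disp/g): mean g, squared CV 1/disp
        rate = disp / g
        with np.errstate(divide="ignore", invalid="ignore"):
            return (
                disp * np.log(rate)
                - sp.gammaln(disp)
                + (disp - 1.0) * np.log(self.y)
                - rate * self.y
            )

    def initial_points(self, n_chains: int, rng: np.random.Generator) -> np.ndarray:
        t, y = self.t, self.y
        late = y[t >= np.quantile(t, 0.8)]
        gam0 = float(np.clip(np.mean(late) if late.size else y.min(), 0.02, 0.9))
        alpha0 = float(np.median(t))
        x0 = np.array([alpha0, np.log(0.3), sp.logit(gam0), np.log(20.0)])
        return x0 + 0.2 * rng.standard_normal((n_chains, 4))


def fit_decay(
    data: Iterable[MassRecord],
    priors: Mapping[str, object] | None = None,
    chains: int = 5,
    iterations: int = 5000,
    warmup: int = 2000,
    seed: int = 0,
) -> PosteriorSamples:
    """Sample the posterior of the Gompertz decay parameters.

    ``data`` is normalized per resource by its day-0 mass (see
    ``mass_proportions``); the likelihood is the gamma observation model on
    the resulting proportions, pooled across resources.
    """
    priors = dict(priors) if priors is not None else _default_decay_priors()
    t, y, ids = mass_proportions(data)
    if np.unique(t).size < 2:
        raise ValueError("need measurements at >= 2 distinct times beyond baseline")
    model = _DecayModel(t, y, priors)
    ss = np.random.SeedSequence(int(seed))
    init_ss, chain_ss = ss.spawn(2)
    rng_init = np.random.default_rng(init_ss)
    x0s = model.initial_points(chains, rng_init)
    for c in range(chains):
        tries = 0
        while not np.isfinite(model.log_posterior(x0s[c])) and tries < 50:
            x0s[c] = model.initial_points(1, rng_init)[0]
            tries += 1
    draws_u, acc = _mcmc.run_chains(
        model.log_posterior, x0s, iterations, warmup, chain_ss
    )
    n_chains, n_kept, _ = draws_u.shape
    flat_u = draws_u.reshape(-1, 4)
    flat_nat = np.column_stack(
        [flat_u[:, 0], np.exp(flat_u[:, 1]), sp.expit(flat_u[:, 2]), np.exp(flat_u[:, 3])]
    )
    pointwise = np.empty((flat_u.shape[0], t.size))
    for i in range(flat_u.shape[0]):
        pointwise[i] = model.pointwise(*model.to_natural(flat_u[i]))
    return PosteriorSamples(
        draws=flat_nat.reshape(n_chains, n_kept, 4),
        parameter_names=list(_PARAM_NAMES),
        pointwise_loglik=pointwise.reshape(n_chains, n_kept, -1),
        meta={
            "model": "gompertz_decay",
            "n_observations": int(t.size),
            "n_resources": len(set(ids)),
            "seed": int(seed),
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "acceptance_rates": acc.tolist(),
        },
    )


@dataclass
class DecayCurveSet:
    """Median-parameter curve plus per-draw curves from a decay posterior."""

    median_params: GompertzDecay
    param_draws: np.ndarray  # (n_draws, 4): alpha, beta, gamma, dispersion

    def median(self, t):
        """g(t) at the posterior medians (point curve for reports)."""
        return gompertz_mean(t, self.median_params)

    def curves(self, t_grid) -> np.ndarray:
        """Matrix of g(t_grid) per posterior draw, shape (n_draws, len(grid))."""
        t = np.asarray(t_grid, dtype=float)[None, :]
        a = self.param_draws[:, 0][:, None]
        b = self.param_draws[:, 1][:, None]
        g = self.param_draws[:, 2][:, None]
        return 1.0 - (1.0 - g) * np.exp(-np.exp(-b * (t - a)))

    def band(self, t_grid, level: float = 0.95) -> pd.DataFrame:
        """Median curve and central credible band on a grid."""
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.curves(t_grid), [0.5, lo, 1.0 - lo], axis=0)
        return pd.DataFrame(
            {"t": np.asarray(t_grid, dtype=float),
             "g_median": q[0], "g_low": q[1], "g_high": q[2]}
        )


def decay_from_posterior(post: PosteriorSamples) -> DecayCurveSet:
    """Wrap a decay posterior as callable curves for metric propagation."""
    draws = np.column_stack([post.get(name) for name in _PARAM_NAMES])
    med = np.median(draws, axis=0)
    params = GompertzDecay(
        alpha=float(med[0]), beta=float(med[1]),
        gamma_asymptote=float(med[2]), dispersion=float(med[3]),
    )
    return DecayCurveSet(median_params=params, param_draws=draws)


def hazard_overlay(
    curves: DecayCurveSet,
    dists: Mapping[str, "TimeDistribution"],
    t_grid,
) -> pd.DataFrame:
    """One table pairing the decay band with each species' detection hazard.

    Reproduces the standard report figure: remaining-mass curve (with 95%
    band) and, on the same time axis, the hazard of the selected TTD family
    per species.
    """
    df = curves.band(t_grid)
    t = np.asarray(t_grid, dtype=float)
    pos = t > 0
    for name, dist in dists.items():
        col = np.full(t.shape, np.nan)
        if pos.any():
            col[pos] = dist.hazard(t[pos])
        df[f"hazard_{name}"] = col  # hazard undefined at t = 0
    return df
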