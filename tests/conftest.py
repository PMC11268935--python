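import numpy as np
import pytest

import ttdcomp as tc


@pytest.fixture(scope="session")
def exp_pair_truth():
    """Known two-species exponential generating model (focal A, rival B)."""
    return {
        "A": tc.SpeciesModel(0.6, tc.TimeDistribution("exponential", rate=0.4)),
        "B": tc.SpeciesModel(0.4, tc.TimeDistribution("exponential", rate=0.2)),
    }


@pytest.fixture(scope="session")
def exp_pair_dataset(exp_pair_truth):
    scenario = tc.SimulationScenario(
        n_stations=300,
        species_models=exp_pair_truth,
        survey_length=60.0,
        seed=11,
    )
    dataset, truth = tc.simulate_ttd(scenario)
    return dataset, truth


@pytest.fixture(scope="session")
def exp_pair_posterior(exp_pair_dataset):
    """One moderately long fit of the exponential pair, reused across tests."""
    dataset, _ = exp_pair_dataset
    return tc.fit_ttd(
        dataset, "exponential", chains=3, iterations=1500, warmup=600, seed=5
    )


@pytest.fixture(scope="session")
def decay_truth():
    return tc.GompertzDecay(alpha=8.0, beta=0.5, gamma_asymptote=0.25, dispersion=50.0)


@pytest.fixture(scope="session")
def decay_posterior(decay_truth):
    """Fit of a 21-carcass, 30-day simulated wet-mass study."""
    masses = tc.simulate_decay(21, decay_truth, schedule=range(0, 31), seed=3)
    return tc.fit_decay(masses, chains=3, iterations=2000, warmup=800, seed=7)


def build_count_dataset(n_winners: dict[str, int], n_stations: int,
                        censor_time: float = 14.0) -> tc.TTDDataset:
    """Dataset with prescribed first-detection counts per species.

    Winners get an arbitrary positive detection time; every rival is censored
    at that same moment; stations with no winner are censored at
    ``censor_time`` for all species.  Only the counts matter for summaries.
    """
    species = list(n_winners)
    records = []
    station = 0
    for winner, count in n_winners.items():
        for _ in range(count):
            station += 1
            sid = f"st{station:03d}"
            t = 1.0 + 0.1 * station
            for s in species:
                records.append(
                    tc.DetectionRecord(sid, s, t, 0 if s == winner else 1)
                )
    while station < n_stations:
        station += 1
        sid = f"st{station:03d}"
        for s in species:
            records.append(tc.DetectionRecord(sid, s, censor_time, 1))
    return tc.TTDDataset(records)


@pytest.fixture(scope="session")
def nest_case_dataset():
    """32 artificial nests: 15 taken by squirrels, 5 by crows, 12 untouched."""
    return build_count_dataset({"squirrel": 15, "crow": 5}, n_stations=32)


@pytest.fixture(scope="session")
def carcass_case_dataset():
    """69 carcasses: 37 found first by foxes, 15 by raccoon dogs."""
    return build_count_dataset({"fox": 37, "raccoon_dog": 15}, n_stations=69,
                               censor_time=60.0)
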