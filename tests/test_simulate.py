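"""Individual-based simulator: known-truth checks of every pipeline stage."""

import dataclasses

import numpy as np
import pytest

import sealdisp as sd
from sealdisp.ingest import ConfigurationError
from sealdisp.simulate import SimTruth, simulate_population, study_like_truth

from conftest import AN, PB


def small_truth(**kwargs):
    base = dict(
        colonies=(AN, PB),
        birth_years=tuple(range(2000, 2005)),
        sigma=dict.fromkeys((AN, PB), 0.9),
        rho=dict.fromkeys((AN, PB), 0.878),
        delta={AN: 0.7, PB: 0.21},
        mu_by_cohort={AN: (0.08,) * 5, PB: (0.16,) * 5},
        epsilon=dict.fromkeys((AN, PB), 0.007),
        n_tagged_by_cohort={c: (150,) * 5 for c in (AN, PB)},
        juvenile_survival=dict.fromkeys((AN, PB), 0.8),
        seed=0,
    )
    base.update(kwargs)
    return SimTruth(**base)


class TestSimulatePopulation:
    def test_bit_reproducible_for_fixed_seed(self):
        a, _ = simulate_population(small_truth())
        b, _ = simulate_population(small_truth())
        assert a == b

    def test_different_seed_differs(self):
        a, _ = simulate_population(small_truth())
        b, _ = simulate_population(small_truth(seed=1))
        assert a != b

    def test_perfect_observation_counts_every_breeder(self):
        truth = small_truth(
            sigma=dict.fromkeys((AN, PB), 1.0),
            rho=dict.fromkeys((AN, PB), 1.0),
            delta=dict.fromkeys((AN, PB), 1.0),
            epsilon=dict.fromkeys((AN, PB), 0.0),
            juvenile_survival=dict.fromkeys((AN, PB), 1.0),
            mu_by_cohort={AN: (0.1,) * 5, PB: (0.1,) * 5},
        )
        records, totals = simulate_population(truth)
        table = sd.tally_cohorts(records, totals, colonies=truth.colonies)
        # nobody dies, detection is certain: every tagged female breeds and is seen
        assert (table.counts["breeding"] == table.counts["tagged"]).all()
        frac = table.totals()["emigrant"] / table.totals()["breeding"]
        for c in truth.colonies:
            assert frac[c] == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / 750))

    def test_zero_dispersal_means_zero_emigrants(self):
        # adult movement must be off too: a female first detected after an
        # adult move would otherwise be tallied as a natal emigrant
        truth = small_truth(
            mu_by_cohort={AN: (0.0,) * 5, PB: (0.0,) * 5},
            epsilon=dict.fromkeys((AN, PB), 0.0),
        )
        records, totals = simulate_population(truth)
        table = sd.tally_cohorts(records, totals, colonies=truth.colonies)
        assert (table.counts["emigrant"] == 0).all()

    def test_zero_adult_dispersal_means_zero_movers(self):
        truth = small_truth(epsilon=dict.fromkeys((AN, PB), 0.0))
        records, _ = simulate_population(truth)
        reapp = sd.tally_reappearance(records, 2012, colonies=truth.colonies)
        assert sd.tally_adult_dispersal(reapp)[1] == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            small_truth(delta={AN: 1.4, PB: 0.2})

    def test_horizon_must_cover_first_breeding(self):
        with pytest.raises(ConfigurationError):
            simulate_population(small_truth(), final_year=2006)


@pytest.fixture(scope="module")
def calibration_run():
    """A larger single-parameter-set run used by several closed-form checks."""
    truth = small_truth(
        birth_years=tuple(range(2000, 2008)),
        mu_by_cohort={AN: (0.0,) * 8, PB: (0.0,) * 8},
        epsilon=dict.fromkeys((AN, PB), 0.0),
        delta={AN: 0.6, PB: 0.6},
        n_tagged_by_cohort={c: (2500,) * 8 for c in (AN, PB)},
        juvenile_survival=dict.fromkeys((AN, PB), 0.9),
        seed=99,
    )
    records, totals = simulate_population(truth, final_year=2020)
    return truth, records, totals


class TestClosedFormOracles:
    def test_age_distribution_recovers_return_rate(self, calibration_run):
        truth, records, _ = calibration_run
        ages = sd.tally_ages(records, colonies=truth.colonies, max_birth_year=2006)
        for colony in truth.colonies:
            fit = sd.fit_return_rate(ages, colony, a_min=4, a_max=12)
            assert abs(fit.slope_mean - truth.tau(colony)) < 3 * fit.slope_se + 0.01

    def test_reappearance_matches_delta_times_tau(self, calibration_run):
        truth, records, _ = calibration_run
        reapp = sd.tally_reappearance(records, 2020, colonies=truth.colonies)
        for colony in truth.colonies:
            successes, trials = reapp.pi_counts(colony)
            expected = truth.delta[colony] * truth.tau(colony)
            se = np.sqrt(expected * (1 - expected) / trials)
            assert abs(successes / trials - expected) < 3 * se

    def test_lifetime_detection_matches_closed_form(self, calibration_run):
        # same seed with delta=1 replays identical survival trajectories, so
        # the ever-breeding population is known exactly
        truth, records, _ = calibration_run
        perfect = dataclasses.replace(truth, delta=dict.fromkeys((AN, PB), 1.0))
        all_records, _ = simulate_population(perfect, final_year=2020)
        breeders = {r.animal_id for r in all_records}
        seen = {r.animal_id for r in records}
        assert seen <= breeders
        for colony in truth.colonies:
            pool = [a for a in breeders if a.startswith(colony)]
            frac = len({a for a in seen if a.startswith(colony)}) / len(pool)
            closed = sd.lifetime_detection(
                np.array([truth.delta[colony]]), np.array([truth.tau(colony)])
            )[0]
            se = np.sqrt(closed * (1 - closed) / len(pool))
            # right-truncation at the horizon loses a little lifetime exposure
            assert abs(frac - closed) < 3 * se + 0.01


class TestDetectionBiasPhenomenon:
    def test_naive_rate_toward_well_observed_colony_is_inflated(self):
        # equal 10% true dispersal both ways but unequal annual detection
        # (the study's 0.70 vs 0.21): the naive rate from the poorly-observed
        # colony is biased up and the ratio correction removes the bias
        truth = small_truth(
            birth_years=tuple(range(2000, 2006)),
            delta={AN: 0.70, PB: 0.21},
            mu_by_cohort={AN: (0.1,) * 6, PB: (0.1,) * 6},
            epsilon=dict.fromkeys((AN, PB), 0.0),
            n_tagged_by_cohort={c: (2000,) * 6 for c in (AN, PB)},
            juvenile_survival=dict.fromkeys((AN, PB), 0.9),
            seed=7,
        )
        records, totals = simulate_population(truth, final_year=2018)
        table = sd.tally_cohorts(records, totals, colonies=truth.colonies)
        tot = table.totals()
        naive_pb = sd.naive_dispersal(tot.loc[PB, "emigrant"], tot.loc[PB, "resident"])
        assert naive_pb > 0.13  # inflated toward the well-observed colony
        big = {
            c: sd.lifetime_detection(
                np.array([truth.delta[c]]), np.array([truth.tau(c)])
            )[0]
            for c in truth.colonies
        }
        corrected = sd.corrected_dispersal_point(
            tot.loc[PB, "emigrant"], tot.loc[PB, "resident"], big[AN] / big[PB]
        )
        assert abs(corrected - 0.1) < abs(naive_pb - 0.1)
        assert corrected == pytest.approx(0.1, abs=0.02)


class TestStudyLikeTruth:
    def test_scale_matches_study(self):
        truth = study_like_truth(seed=3)
        records, totals = simulate_population(truth)
        table = sd.tally_cohorts(records, totals, colonies=truth.colonies)
        tot = table.totals()
        assert tot.loc[AN, "tagged"] == 4104
        # tagged-to-breeder ratios near the study's 14.6% and 18.8%
        assert tot.loc[AN, "breeding"] / 4104 == pytest.approx(0.146, abs=0.04)
        assert tot.loc[PB, "breeding"] / 2484 == pytest.approx(0.188, abs=0.05)
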