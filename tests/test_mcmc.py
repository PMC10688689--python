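"""Dispersal correction algebra and the hierarchical Metropolis sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sealdisp as sd
from sealdisp.ingest import InsufficientDataError
from sealdisp.mcmc import (
    DispersalModelConfig,
    DispersalPosterior,
    corrected_dispersal_point,
    fit_dispersal,
    loglik_counts,
    loglik_hyper,
    naive_dispersal,
    predict_observed,
    run_sampler,
    summarize,
)

from conftest import AN, PB


class TestPointFormulas:
    def test_observed_ratios_from_study_totals(self):
        assert naive_dispersal(35, 566) == pytest.approx(0.0582, abs=5e-4)
        assert naive_dispersal(124, 344) == pytest.approx(0.265, abs=5e-4)
        assert naive_dispersal(0, 7) == 0.0

    def test_worked_bias_example_restores_truth(self):
        # unequal lifetime detection (0.5 vs 0.8) distorts a true 10% rate to
        # 6.5% and 15%; the ratio correction restores 0.10 in both directions
        assert naive_dispersal(5, 72) == pytest.approx(0.065, abs=5e-4)
        assert naive_dispersal(8, 45) == pytest.approx(0.15, abs=1e-3)
        assert corrected_dispersal_point(5, 72, 0.625) == pytest.approx(0.10)
        assert corrected_dispersal_point(8, 45, 1.6) == pytest.approx(0.10)

    def test_unit_ratio_is_no_correction(self):
        assert corrected_dispersal_point(7, 13, 1.0) == naive_dispersal(7, 13)

    def test_zero_breeders_error(self):
        with pytest.raises(InsufficientDataError):
            naive_dispersal(0, 0)

    def test_predicted_count_examples(self):
        assert predict_observed(53, 0.10, 1.6) == pytest.approx(8.0)
        assert predict_observed(100, 0.0, 2.0) == 0.0
        assert predict_observed(80, 0.3, 1.0) == pytest.approx(24.0)

    @settings(max_examples=250, derandomize=True)
    @given(
        B=st.floats(1.0, 1e4),
        mu=st.floats(1e-3, 0.999),
        ratio=st.floats(0.05, 20.0),
    )
    def test_correction_inverts_prediction_exactly(self, B, mu, ratio):
        b = predict_observed(B, mu, ratio)
        back = corrected_dispersal_point(b, B - b, ratio)
        assert back == pytest.approx(mu, rel=1e-9)


class TestLikelihoods:
    def test_poisson_logpmf_matches_scipy(self):
        for k in range(0, 21):
            for lam in (0.5, 1.0, 3.0, 10.0):
                assert loglik_counts(k, lam) == pytest.approx(
                    stats.poisson.logpmf(k, lam), rel=1e-12
                )
        assert loglik_counts(3, 3.0) == pytest.approx(
            float(stats.poisson.logpmf(3, 3.0))
        )

    def test_zero_zero_convention_and_errors(self):
        assert loglik_counts(0, 0.0) == 0.0
        assert loglik_counts(1, 0.0) == -np.inf
        with pytest.raises(ValueError):
            loglik_counts(-1, 1.0)
        with pytest.raises(ValueError):
            loglik_counts(2, -0.5)

    def test_hyper_density_matches_scipy_product(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(0.2, 0.05, size=3)
        val = loglik_hyper(mu, theta=0.2, sigma=0.07)
        assert val == pytest.approx(
            stats.norm.logpdf(mu, 0.2, 0.07).sum(), rel=1e-12
        )

    def test_centered_rates_give_peak_density(self):
        val = loglik_hyper(np.full(17, 0.3), theta=0.3, sigma=0.1)
        assert val == pytest.approx(17 * stats.norm.logpdf(0.0, 0.0, 0.1))

    def test_trend_with_zero_slope_equals_constant(self):
        mu = np.linspace(0.1, 0.4, 17)
        years = np.arange(1994, 2011)
        a = loglik_hyper(mu, theta=0.25, sigma=0.1)
        b = loglik_hyper(
            mu, sigma=0.1, variant="trend", nu=0.0, eta=0.25, years=years
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        assert loglik_hyper(np.ones(3) * 0.2, 0.2, 0.0) == -np.inf


def single_cohort_table(B, b, year=2000):
    import pandas as pd
    from sealdisp.ingest import CohortDispersalTable

    frame = pd.DataFrame(
        [(year, PB, B + 10, B, B - b, b)],
        columns=[
            "birth_year",
            "birth_colony",
            "tagged",
            "breeding",
            "resident",
            "emigrant",
        ],
    ).set_index(["birth_year", "birth_colony"])
    return CohortDispersalTable(counts=frame, colonies=(AN, PB))


class TestSampler:
    def test_single_cohort_matches_grid_integration(self):
        # non-hierarchical, fixed detection ratio: the sampler must agree with
        # direct quadrature of Poisson likelihood x flat prior
        B, b, r = 53, 8, 1.6
        grid = np.linspace(5e-4, 1 - 5e-4, 1000)
        pred = B * grid * r / (1 - grid * (1 - r))
        post = np.exp(b * np.log(pred) - pred)
        post /= post.sum()
        oracle_mean = float((grid * post).sum())
        cfg = DispersalModelConfig(
            n_steps=20_000, burn_in=4_000, seed=5, hierarchical=False
        )
        out = run_sampler(single_cohort_table(B, b), PB, np.array([r]), cfg)
        assert out.mu.shape == (16_000, 1)
        assert out.mu[:, 0].mean() == pytest.approx(oracle_mean, abs=0.01)

    def test_flat_fit_recovers_naive_ratio_at_unit_ratio(self):
        cfg = DispersalModelConfig(
            n_steps=12_000, burn_in=2_000, seed=6, hierarchical=False
        )
        out = run_sampler(single_cohort_table(2000, 500), PB, np.array([1.0]), cfg)
        assert out.mu[:, 0].mean() == pytest.approx(0.25, abs=0.01)

    def test_all_zero_counts_concentrate_near_zero(self, study_table):
        import pandas as pd
        from sealdisp.ingest import CohortDispersalTable

        counts = study_table.counts.copy()
        counts["resident"] = counts["breeding"]
        counts["emigrant"] = 0
        table = CohortDispersalTable(counts=counts, colonies=study_table.colonies)
        cfg = DispersalModelConfig(n_steps=4000, burn_in=1000, seed=7)
        out = run_sampler(table, AN, np.array([1.0]), cfg)
        assert summarize(out).table.loc["theta", "mean"] < 0.02

    def test_summarize_known_gaussian_chain(self):
        rng = np.random.default_rng(8)
        chain = rng.normal(0.2, 0.05, size=40_000)
        post = DispersalPosterior(
            origin=PB,
            dest=AN,
            years=np.array([2000]),
            mu=chain[:, None],
            hyper={},
            ratio_index=np.zeros(chain.size, dtype=int),
            accept_rate={"mu_2000": 0.3},
            config=DispersalModelConfig(seed=0),
        )
        table = summarize(post).table
        assert table.loc["mu_2000", "mean"] == pytest.approx(0.2, abs=3 * 0.05 / 200)
        assert table.loc["mu_2000", "ci_low"] == pytest.approx(
            0.2 - 1.96 * 0.05, abs=0.002
        )

    def test_summarize_constant_chain_zero_width(self):
        post = DispersalPosterior(
            origin=PB,
            dest=AN,
            years=np.array([2000]),
            mu=np.full((100, 1), 0.3),
            hyper={},
            ratio_index=np.zeros(100, dtype=int),
            accept_rate={},
            config=DispersalModelConfig(seed=0),
        )
        row = summarize(post).table.loc["mu_2000"]
        assert row["mean"] == row["ci_low"] == row["ci_high"] == 0.3

    def test_summarize_empty_chain_errors(self):
        post = DispersalPosterior(
            origin=PB,
            dest=AN,
            years=np.array([2000]),
            mu=np.empty((0, 1)),
            hyper={},
            ratio_index=np.empty(0, dtype=int),
            accept_rate={},
            config=DispersalModelConfig(seed=0),
        )
        with pytest.raises(ValueError):
            summarize(post)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DispersalModelConfig(n_steps=100, burn_in=100)
        with pytest.raises(ValueError):
            DispersalModelConfig(variant="quadratic")


@pytest.fixture(scope="module")
def study_fits(study_table, study_detection):
    cfg = DispersalModelConfig(seed=11)
    pb = fit_dispersal(
        study_table, PB, study_detection.ratio_draws(AN, PB), cfg, n_chains=2
    )
    an = fit_dispersal(
        study_table, AN, study_detection.ratio_draws(PB, AN), cfg, n_chains=2
    )
    return pb, an


class TestStudyFit:
    def test_acceptance_rates_in_healthy_band(self, study_fits):
        for post in study_fits:
            rates = np.array(list(post.accept_rate.values()))
            assert ((rates > 0.1) & (rates < 0.6)).all()

    def test_chains_stay_in_support(self, study_fits):
        for post in study_fits:
            assert ((post.mu > 0) & (post.mu < 1)).all()
            assert (post.hyper["sigma"] > 0).all()

    def test_zero_emigrant_cohort_is_shrunk_not_zero(self, study_fits):
        pb, _ = study_fits
        table = summarize(pb).table
        naive_max = 18 / 32  # largest observed annual ratio (2000 cohort)
        for year in (1997, 2004):  # cohorts with 0 observed emigrants
            m = table.loc[f"mu_{year}", "mean"]
            assert 0.0 < m < naive_max

    def test_northward_exceeds_southward(self, study_fits):
        pb, an = study_fits
        n = min(pb.hyper["theta"].size, an.hyper["theta"].size)
        p = (pb.hyper["theta"][:n] > an.hyper["theta"][:n]).mean()
        assert p > 0.95

    def test_seed_invariance_within_posterior_error(
        self, study_table, study_detection
    ):
        means = []
        for seed in (21, 22):
            cfg = DispersalModelConfig(seed=seed)
            post = fit_dispersal(
                study_table, PB, study_detection.ratio_draws(AN, PB), cfg
            )
            means.append(post.hyper["theta"].mean())
        chain_sd = float(
            fit_dispersal(
                study_table,
                PB,
                study_detection.ratio_draws(AN, PB),
                DispersalModelConfig(seed=23),
            ).hyper["theta"].std()
        )
        assert abs(means[0] - means[1]) < chain_sd
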